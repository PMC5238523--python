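"""De-regressed proofs (DRP) from EBVs, with parent-average removal.

An EBV is a shrunken predictor; using it directly as a pseudo-phenotype
double-counts pedigree information and under-disperses the signal.
De-regression undoes the shrinkage and removes the parent-average (PA)
contribution, leaving a record that carries only the individual's own
information together with a reliability r2_DRP.  The mixed model then weights
each record's residual by R_ii = (1 - r2_DRP) / r2_DRP.

The full method partitions the information content of an EBV between the PA
and the individual via the effective-record equations: with
lambda = (1 - h2)/h2, the unknown contents Z'Z_PA and Z'Z_i solve

    lambda * (Z'Z_i  + 2*lambda) / det = 0.5 - r2_PA
    lambda * (Z'Z_PA + 4*lambda) / det = 1   - r2_EBV
    det = (Z'Z_PA + 4*lambda) * (Z'Z_i + 2*lambda) - 4*lambda**2

whose closed form is implemented below.  The de-regressed proof is the
individual's information equation solved for its record, and its reliability
is Z'Z_i / (Z'Z_i + lambda).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import PedigreeTable

__all__ = [
    "parent_average",
    "deregress",
    "reliability_weights",
    "RELIABILITY_CAP",
]

#: Single authority for the reliability cap (a reliability of 1 would give an
#: infinite-precision record and a zero residual weight).
RELIABILITY_CAP = 0.999


def parent_average(ebv_table: pd.DataFrame, pedigree: PedigreeTable) -> pd.DataFrame:
    """Parent averages and their reliabilities.

    ``ebv_table`` columns: id, value (EBV), reliability.  Unknown parents (or
    parents without an EBV) contribute EBV 0 with reliability 0, so PA =
    (EBV_sire + EBV_dam)/2 and r2_PA = (r2_sire + r2_dam)/4.
    """
    ebv = dict(zip(ebv_table["id"].astype(str), ebv_table["value"]))
    rel = dict(zip(ebv_table["id"].astype(str), ebv_table["reliability"]))
    rows = []
    for iid in ebv_table["id"].astype(str):
        sire, dam = pedigree.parents_of(iid)
        e_s, r_s = (ebv.get(sire, 0.0), rel.get(sire, 0.0)) if sire else (0.0, 0.0)
        e_d, r_d = (ebv.get(dam, 0.0), rel.get(dam, 0.0)) if dam else (0.0, 0.0)
        rows.append((iid, (e_s + e_d) / 2.0, (r_s + r_d) / 4.0))
    return pd.DataFrame(rows, columns=["id", "pa", "r2_pa"])


def _garrick_contents(r2_ebv, r2_pa, lam):
    """Effective record contents (Z'Z_PA, Z'Z_i) for given reliabilities."""
    alpha = 1.0 / (0.5 - r2_pa)
    delta = (0.5 - r2_pa) / (1.0 - r2_ebv)
    zpz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(alpha**2 + 16.0 / delta)
    zpz_i = delta * zpz_pa + 2.0 * lam * (2.0 * delta - 1.0)
    return zpz_pa, zpz_i


def deregress(
    ebv,
    r2_ebv,
    pa=None,
    r2_pa=None,
    h2: float | None = None,
    method: str = "garrick",
    ids=None,
    trait: str = "trait",
) -> pd.DataFrame:
    """De-regress EBVs; returns a DRP table (id, drp, reliability, trait, method).

    ``simple``: DRP = EBV / r2_EBV with r2_DRP = r2_EBV (no PA removal;
    transparent fallback used by synthetic shortcuts).  ``garrick``: the
    information-partitioning method described in the module docstring; needs
    ``pa``, ``r2_pa`` and the trait heritability ``h2``.
    """
    ebv = np.asarray(ebv, dtype=float)
    r2_ebv = np.minimum(np.asarray(r2_ebv, dtype=float), RELIABILITY_CAP)
    if (r2_ebv <= 0).any():
        raise ValueError("EBV reliabilities must be positive")
    if ids is None:
        ids = np.arange(len(ebv)).astype(str)

    if method == "simple":
        drp = ebv / r2_ebv
        r2_drp = r2_ebv
    elif method == "garrick":
        if pa is None or r2_pa is None or h2 is None:
            raise ValueError("garrick mode needs pa, r2_pa and h2")
        if not 0 < h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        pa = np.asarray(pa, dtype=float)
        r2_pa = np.asarray(r2_pa, dtype=float)
        if (r2_ebv <= r2_pa).any():
            bad = np.asarray(ids)[r2_ebv <= r2_pa][0]
            raise ValueError(
                f"r2_EBV <= r2_PA for individual {bad}: no individual information"
            )
        lam = (1.0 - h2) / h2
        _, zpz_i = _garrick_contents(r2_ebv, r2_pa, lam)
        if (zpz_i <= 0).any():
            bad = np.asarray(ids)[zpz_i <= 0][0]
            raise ValueError(f"non-positive own-information content for {bad}")
        drp = (-2.0 * lam * pa + (zpz_i + 2.0 * lam) * ebv) / zpz_i
        r2_drp = zpz_i / (zpz_i + lam)
    else:
        raise ValueError(f"unknown de-regression method {method!r}")

    r2_drp = np.minimum(r2_drp, RELIABILITY_CAP)
    return pd.DataFrame(
        {
            "id": np.asarray(ids).astype(str),
            "drp": drp,
            "reliability": r2_drp,
            "trait": trait,
            "method": method,
        }
    )


def reliability_weights(drp_table: pd.DataFrame) -> np.ndarray:
    """Residual weights R_ii = (1 - r2_DRP) / r2_DRP per record."""
    r2 = np.minimum(np.asarray(drp_table["reliability"], dtype=float), RELIABILITY_CAP)
    if (r2 <= 0).any():
        raise ValueError("DRP reliabilities must be positive")
    return (1.0 - r2) / r2
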