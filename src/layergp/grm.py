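"""Genomic relationship matrices with per-SNP weights.

The common construction is G = M D M' / (2 * sum_i p_i (1 - p_i)), where M
holds genotypes corrected by twice the second-allele frequency (0-2p, 1-2p,
2-2p) and D is a diagonal matrix of SNP weights.  Identity weights give the
classical VanRaden matrix G_I; -log10 P weights from a GWAS give G_P; squared
RRBLUP effects give G_S; and the trait-architecture blend G_z = w*S + (1-w)*G_I
mixes a matrix S built from the top fraction of SNPs by absolute effect into
G_I.  All weight vectors are divided by their mean so weighted matrices stay
on the scale of G_I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenotypePanel

__all__ = [
    "CenteredGenotypes",
    "WeightVector",
    "GRM",
    "center_genotypes",
    "compute_weights",
    "build_grm",
    "build_architecture_matrix",
    "blend_blupga",
]

WEIGHT_MODES = ("identity", "neglog10p", "squared_effect")


@dataclass
class CenteredGenotypes:
    """Frequency-centered genotype codes and the VanRaden scaling constant.

    M columns are dosage - 2 p_i with p_i taken from the panel the object was
    built from ("the current dataset"); c = 2 * sum p_i (1 - p_i) over the
    columns present.
    """

    M: np.ndarray  # n x m
    p: np.ndarray  # per-column allele frequency
    c: float
    individual_ids: np.ndarray
    snp_indices: np.ndarray  # indices into the source panel

    @property
    def n_snps(self) -> int:
        return self.M.shape[1]

    def rows(self, idx) -> np.ndarray:
        return self.M[idx]


@dataclass
class WeightVector:
    """Diagonal of D.  After normalization mean(w) == 1."""

    values: np.ndarray
    mode: str
    normalized: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("SNP weights must be non-negative")


@dataclass
class GRM:
    """A realized relationship matrix with its construction recipe."""

    values: np.ndarray
    individual_ids: np.ndarray
    recipe: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, sym_tol=1e-10, rowsum_tol=1e-8, eig_tol=-1e-8) -> None:
        """Check symmetry, zero row sums and positive semidefiniteness."""
        a = self.values
        asym = np.abs(a - a.T).max()
        if asym > sym_tol:
            raise ValueError(f"GRM asymmetry {asym:.3g} exceeds {sym_tol}")
        rs = np.abs(a.sum(axis=1)).max()
        if rs > rowsum_tol * max(1.0, np.abs(a).max()) * self.n:
            raise ValueError(f"GRM row sums deviate from zero by {rs:.3g}")
        w = np.linalg.eigvalsh((a + a.T) / 2)
        if w.min() < eig_tol * max(1.0, w.max()):
            raise ValueError(f"GRM minimum eigenvalue {w.min():.3g} below tolerance")


def center_genotypes(
    panel: GenotypePanel, snp_subset=None, allele_freq=None
) -> CenteredGenotypes:
    """Center dosages by twice the current-data allele frequency.

    ``snp_subset`` may be a boolean mask or index array over the panel's SNPs;
    the scaling constant c is computed over the subset only.  ``allele_freq``
    overrides the frequencies (they default to the panel's own, i.e. the
    current dataset; pass frequencies from a reference panel to keep several
    panels on one scale).
    """
    dosage = panel.dosage
    if np.isnan(dosage).any():
        raise ValueError("missing genotypes present; filter or impute first")
    if snp_subset is None:
        idx = np.arange(panel.n_snps)
    else:
        snp_subset = np.asarray(snp_subset)
        idx = np.where(snp_subset)[0] if snp_subset.dtype == bool else snp_subset
    if len(idx) == 0:
        raise ValueError("SNP subset selects zero SNPs")
    p = (panel.allele_freq if allele_freq is None else np.asarray(allele_freq))[idx]
    M = dosage[:, idx] - 2.0 * p
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c <= 0:
        raise ValueError("scaling constant 2*sum(p(1-p)) is zero: all SNPs monomorphic")
    return CenteredGenotypes(
        M=M, p=p, c=c, individual_ids=panel.individual_ids, snp_indices=idx
    )


def compute_weights(
    mode: str, values=None, m: int | None = None, p_floor: float | None = None
) -> WeightVector:
    """Build a per-SNP weight vector and mean-normalize it.

    identity: all ones (``m`` required).  neglog10p: ``values`` are p-values
    in (0, 1]; weights -log10(p).  A p-value of 0 is fatal unless ``p_floor``
    is given, in which case p-values are floored there first.  squared_effect:
    ``values`` are SNP effects; weights are their squares.
    """
    if mode == "identity":
        if m is None:
            m = len(values) if values is not None else None
        if not m:
            raise ValueError("identity weights need the number of SNPs")
        return WeightVector(np.ones(m), mode="identity")
    values = np.asarray(values, dtype=float)
    if mode == "neglog10p":
        if p_floor is not None:
            values = np.maximum(values, p_floor)
        if (values <= 0).any():
            raise ValueError("p-value of 0 gives an infinite weight; floor it first")
        if (values > 1).any():
            raise ValueError("p-values must lie in (0, 1]")
        raw = -np.log10(values)
    elif mode == "squared_effect":
        if not np.isfinite(values).all():
            raise ValueError("SNP effects must be finite")
        raw = values**2
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    mean = raw.mean()
    if mean <= 0:
        raise ValueError("all weights are zero; cannot normalize")
    return WeightVector(raw / mean, mode=mode)


def build_grm(cg: CenteredGenotypes, w: WeightVector | None = None) -> GRM:
    """G = M diag(w) M' / c."""
    if w is None:
        w = compute_weights("identity", m=cg.n_snps)
    if len(w.values) != cg.n_snps:
        raise ValueError(
            f"weight length {len(w.values)} != number of SNPs {cg.n_snps}"
        )
    G = (cg.M * w.values) @ cg.M.T / cg.c
    G = (G + G.T) / 2.0  # enforce exact symmetry against rounding
    return GRM(
        values=G,
        individual_ids=cg.individual_ids,
        recipe={"weight_mode": w.mode, "n_snps": cg.n_snps},
    )


def top_effect_subset(effects: np.ndarray, top_pct: float) -> np.ndarray:
    """Indices of the ceil(top_pct% * m) SNPs with the largest |effect|,
    ties broken by ascending SNP index."""
    effects = np.asarray(effects, dtype=float)
    m = len(effects)
    if not 0 < top_pct <= 100:
        raise ValueError("top_pct must lie in (0, 100]")
    k = int(np.ceil(top_pct / 100.0 * m))
    if k < 1:
        raise ValueError("top% selects fewer than one SNP")
    order = np.lexsort((np.arange(m), -np.abs(effects)))
    return np.sort(order[:k])


def build_architecture_matrix(
    panel: GenotypePanel,
    effects: np.ndarray,
    top_pct: float,
    snp_subset=None,
    allele_freq=None,
) -> GRM:
    """The S matrix of the architecture blend: squared-effect-weighted G over
    the top% SNPs by |effect|.

    ``effects`` align with the panel's SNPs (or with ``snp_subset`` if given).
    Weights are normalized within the selected subset and the denominator c is
    2*sum p(1-p) over the subset, keeping S on the expectation scale of G_I.
    """
    if snp_subset is not None:
        snp_subset = np.asarray(snp_subset)
        base = np.where(snp_subset)[0] if snp_subset.dtype == bool else snp_subset
    else:
        base = np.arange(panel.n_snps)
    if len(effects) != len(base):
        raise ValueError("effects length must match the SNP (subset) count")
    local = top_effect_subset(effects, top_pct)
    cg = center_genotypes(panel, snp_subset=base[local], allele_freq=allele_freq)
    w = compute_weights("squared_effect", np.asarray(effects)[local])
    S = build_grm(cg, w)
    S.recipe.update({"matrix": "S", "top_pct": top_pct, "n_selected": len(local)})
    return S


def blend_blupga(G_I: GRM, S: GRM, omega: float) -> GRM:
    """G_z = omega * S + (1 - omega) * G_I (identical individual order required)."""
    if not 0 <= omega <= 1:
        raise ValueError("omega must lie in [0, 1]")
    if not np.array_equal(G_I.individual_ids.astype(str), S.individual_ids.astype(str)):
        raise ValueError("individual ID order differs between G_I and S")
    Gz = omega * S.values + (1.0 - omega) * G_I.values
    return GRM(
        values=Gz,
        individual_ids=G_I.individual_ids,
        recipe={
            "matrix": "G_z",
            "omega": omega,
            "top_pct": S.recipe.get("top_pct"),
        },
    )
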