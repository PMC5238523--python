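"""SNP and individual quality control, genic classification, MAF summaries.

Filtering follows the order: individuals first (call rate), then per-SNP
statistics are recomputed on the retained cohort and the SNP criteria are
applied (minor allele frequency, call rate, imputation quality, and removal
of monomorphic SNPs).  Classification assigns each SNP exactly one of nine
categories: the eight genic classes or intergenic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FEATURE_CLASSES, INTERGENIC, AnnotationSet, GenotypePanel

__all__ = [
    "FilterReport",
    "compute_maf",
    "filter_panel",
    "classify_genic",
    "maf_bin_summary",
]

#: Precedence when a SNP overlaps several feature classes (highest first).
CLASS_PRECEDENCE = ("exon", "splicing", "ncRNA", "UTR5", "UTR3", "intron",
                    "upstream", "downstream")


@dataclass
class FilterReport:
    """Bookkeeping of a filtering pass."""

    n_snps_in: int
    n_snps_out: int
    n_ind_in: int
    n_ind_out: int
    removed: dict = field(default_factory=dict)  # criterion -> count (with overlaps)
    overlap: dict = field(default_factory=dict)  # (criterion, criterion) -> count
    rsq_skipped: bool = False

    def to_dict(self) -> dict:
        return {
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "n_ind_in": self.n_ind_in,
            "n_ind_out": self.n_ind_out,
            "removed": dict(self.removed),
            "overlap": {f"{a}&{b}": v for (a, b), v in self.overlap.items()},
            "rsq_skipped": self.rsq_skipped,
        }


def compute_maf(panel: GenotypePanel):
    """Per-SNP minor allele frequency from non-missing dosages.

    Returns (maf, monomorphic) where SNPs with every genotype missing get
    NaN MAF and are flagged monomorphic.
    """
    p = panel.allele_freq
    maf = np.minimum(p, 1.0 - p)
    mono = ~(maf > 0)  # includes NaN (all-missing) and fixed SNPs
    return maf, mono


def filter_panel(
    panel: GenotypePanel,
    maf_min: float = 0.005,
    snp_call_min: float = 0.97,
    ind_call_min: float = 0.95,
    rsq_min: float = 0.8,
    drop_sex_chroms: bool = False,
    sex_chroms: tuple = ("Z", "W", "X", "Y", "chrZ", "chrW", "chrX", "chrY"),
):
    """Apply the standard panel filters; returns (panel, FilterReport).

    Removal is strict at the boundary: a SNP is removed if MAF < ``maf_min``
    or call rate < ``snp_call_min`` or Rsq < ``rsq_min``; monomorphic SNPs
    are always removed.  The report counts removals per criterion including
    overlaps between criteria.
    """
    n_ind_in, n_snps_in = panel.n_individuals, panel.n_snps

    keep_ind = panel.call_rate_ind >= ind_call_min
    panel = panel.subset(ind_mask=keep_ind)

    maf, mono = compute_maf(panel)
    fails = {}
    with np.errstate(invalid="ignore"):
        fails["maf"] = (maf < maf_min) & ~mono
    fails["monomorphic"] = mono
    fails["snp_call_rate"] = panel.call_rate_snp < snp_call_min
    rsq_skipped = panel.rsq is None
    if not rsq_skipped:
        fails["rsq"] = np.nan_to_num(panel.rsq, nan=0.0) < rsq_min
    if drop_sex_chroms:
        fails["sex_chrom"] = panel.snp_map["chrom"].isin(sex_chroms).to_numpy()

    any_fail = np.zeros(panel.n_snps, dtype=bool)
    for mask in fails.values():
        any_fail |= mask
    report = FilterReport(
        n_snps_in=n_snps_in,
        n_snps_out=int((~any_fail).sum()),
        n_ind_in=n_ind_in,
        n_ind_out=panel.n_individuals,
        removed={k: int(v.sum()) for k, v in fails.items()},
        overlap={
            (a, b): int((fails[a] & fails[b]).sum())
            for i, a in enumerate(fails)
            for b in list(fails)[i + 1 :]
        },
        rsq_skipped=rsq_skipped,
    )
    if report.n_snps_out == 0:
        raise ValueError(f"all SNPs removed by filtering: {report.to_dict()}")
    return panel.subset(snp_mask=~any_fail), report


def _merged_intervals(annotation: AnnotationSet, chrom: str, feature: str):
    df = annotation.intervals
    sel = df[(df["chrom"] == chrom) & (df["feature"] == feature)]
    if sel.empty:
        return None
    iv = sel.sort_values("start")[["start", "end"]].to_numpy(dtype=np.int64)
    merged = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append(np.array([s, e]))
    return np.asarray(merged)


def classify_genic(panel: GenotypePanel, annotation: AnnotationSet) -> GenotypePanel:
    """Assign each SNP one of the nine categories; returns a new panel.

    When a SNP overlaps several classes the winner is chosen by
    ``CLASS_PRECEDENCE``; SNPs on chromosomes absent from the annotation are
    intergenic (with a warning).
    """
    cat = np.full(panel.n_snps, INTERGENIC, dtype=object)
    chroms = panel.snp_map["chrom"].to_numpy()
    pos = panel.snp_map["pos"].to_numpy(dtype=np.int64)
    ann_chroms = set(annotation.intervals["chrom"]) if len(annotation) else set()
    for chrom in pd.unique(chroms):
        on = np.where(chroms == chrom)[0]
        if chrom not in ann_chroms:
            warnings.warn(f"chromosome {chrom!r} absent from annotation; "
                          f"{len(on)} SNPs classified intergenic")
            continue
        unassigned = np.ones(len(on), dtype=bool)
        for feature in CLASS_PRECEDENCE:
            if not unassigned.any():
                break
            merged = _merged_intervals(annotation, chrom, feature)
            if merged is None:
                continue
            idx = np.searchsorted(merged[:, 0], pos[on], side="right") - 1
            inside = (idx >= 0) & (pos[on] <= merged[np.clip(idx, 0, None), 1])
            hit = inside & unassigned
            cat[on[hit]] = feature
            unassigned &= ~inside
    out = panel.subset()
    out.category = cat
    return out


def category_counts(panel: GenotypePanel) -> pd.Series:
    order = list(CLASS_PRECEDENCE) + [INTERGENIC]
    counts = pd.Series(panel.category).value_counts()
    return counts.reindex(order, fill_value=0)


def maf_bin_summary(panel: GenotypePanel, bin_width: float = 0.02) -> pd.DataFrame:
    """Counts and percentages of polymorphic SNPs per half-open MAF bin
    (lower, upper], with bins tiling (0, 0.5]."""
    maf, mono = compute_maf(panel)
    maf = maf[~mono]
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    if len(maf) == 0:
        return pd.DataFrame(columns=["bin_low", "bin_high", "count", "percent"])
    # half-open (low, high]: subtract a hair below the value before digitizing
    idx = np.ceil(maf / bin_width - 1e-12).astype(int) - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "percent": 100.0 * counts / counts.sum(),
        }
    )
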