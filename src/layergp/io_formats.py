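"""Readers and writers for the formats the pipeline touches.

Genotypes come in as VCF (GT hard calls by default, DS dosages on request) or
as a simple tab-separated dosage matrix; annotation as GFF3 or BED; phenotype,
pedigree and relationship-matrix tables as plain text.  All coordinates are
held 1-based inclusive internally (the VCF/GFF3 convention); BED input is
converted at the boundary.  Missing genotypes are held as NaN in the float
dosage matrix and are only legal before filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "PedigreeTable",
    "AnnotationSet",
    "FEATURE_CLASSES",
    "read_genotypes",
    "write_dosage_tsv",
    "read_annotation",
    "read_grm",
    "write_grm",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
]

#: The eight genic feature classes; everything else is intergenic.
FEATURE_CLASSES = (
    "exon",
    "splicing",
    "ncRNA",
    "UTR5",
    "UTR3",
    "intron",
    "upstream",
    "downstream",
)

INTERGENIC = "intergenic"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenotypePanel:
    """An individuals x SNPs dosage matrix with its SNP map.

    Attributes
    ----------
    individual_ids : ndarray of str, length n
    snp_ids : ndarray of str, length m
    dosage : ndarray (n, m) of float
        Counts of the second (ALT) allele in [0, 2]; NaN marks a missing call.
    snp_map : DataFrame with columns chrom, pos, ref, alt (pos 1-based).
    rsq : optional per-SNP imputation quality in [0, 1].
    category : optional per-SNP annotation class (one of the eight genic
        classes or ``"intergenic"``).
    """

    individual_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray
    snp_map: pd.DataFrame
    rsq: np.ndarray | None = None
    category: np.ndarray | None = None
    n_skipped_multiallelic: int = 0

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        for name, ids in (("individual", self.individual_ids), ("SNP", self.snp_ids)):
            uniq, counts = np.unique(ids.astype(str), return_counts=True)
            if (counts > 1).any():
                raise FormatError(f"duplicated {name} ID: {uniq[counts > 1][0]}")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency p_i of the second allele, from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def call_rate_snp(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    @property
    def call_rate_ind(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def subset(self, ind_mask=None, snp_mask=None) -> "GenotypePanel":
        """Return a new panel restricted to the given individuals / SNPs."""
        ind_mask = slice(None) if ind_mask is None else np.asarray(ind_mask)
        snp_mask = slice(None) if snp_mask is None else np.asarray(snp_mask)
        sub = lambda a: None if a is None else a[snp_mask]
        return GenotypePanel(
            individual_ids=self.individual_ids[ind_mask],
            snp_ids=self.snp_ids[snp_mask],
            dosage=self.dosage[ind_mask][:, snp_mask],
            snp_map=self.snp_map.iloc[snp_mask].reset_index(drop=True)
            if not isinstance(snp_mask, slice)
            else self.snp_map,
            rsq=sub(self.rsq),
            category=sub(self.category),
            n_skipped_multiallelic=self.n_skipped_multiallelic,
        )

    @property
    def genic(self) -> np.ndarray:
        """Boolean mask of SNPs in any of the eight genic classes."""
        if self.category is None:
            raise ValueError("panel has no annotation categories; run classify_genic")
        return np.asarray(self.category) != INTERGENIC


@dataclass
class PedigreeTable:
    """Pedigree links with generation labels.

    ``table`` columns: id, sire, dam, generation.  Unknown parents are pd.NA /
    empty.  Validated to be acyclic with parents in earlier generations.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table.copy()
        t["id"] = t["id"].astype(str)
        for col in ("sire", "dam"):
            t[col] = t[col].astype("string")
            t.loc[t[col].isin(["0", "", "NA", "."]), col] = pd.NA
        t["generation"] = t["generation"].astype(int)
        gen = dict(zip(t["id"], t["generation"]))
        for _, row in t.iterrows():
            for parent in (row["sire"], row["dam"]):
                if pd.notna(parent) and parent in gen:
                    if gen[parent] >= row["generation"]:
                        raise FormatError(
                            f"pedigree not generation-ordered (possible cycle) at "
                            f"{row['id']} <- {parent}"
                        )
        self.table = t.reset_index(drop=True)

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        row = self.table.loc[self.table["id"] == iid]
        if row.empty:
            return (None, None)
        s, d = row.iloc[0]["sire"], row.iloc[0]["dam"]
        return (None if pd.isna(s) else s, None if pd.isna(d) else d)

    @property
    def generations(self) -> pd.Series:
        return self.table.set_index("id")["generation"]


@dataclass
class AnnotationSet:
    """Intervals (chrom, start, end, feature), 1-based inclusive."""

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "feature"])
    )

    def __post_init__(self):
        df = self.intervals
        if len(df):
            bad = ~df["feature"].isin(FEATURE_CLASSES)
            if bad.any():
                raise FormatError(f"unknown feature class: {df.loc[bad, 'feature'].iloc[0]}")
            if (df["start"] > df["end"]).any():
                raise FormatError("annotation interval with start > end")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str = "vcf", use_ds: bool = False) -> GenotypePanel:
    """Read a genotype panel from ``vcf`` or ``dosage_tsv``.

    VCF: biallelic records only; multiallelic records are skipped and counted
    in ``panel.n_skipped_multiallelic``.  GT hard calls map to dosages 0/1/2;
    with ``use_ds=True`` the DS field is used where present.  A per-SNP R2/RSQ
    INFO field, if present, populates ``panel.rsq``.
    """
    if format == "vcf":
        return _read_vcf(str(path), use_ds=use_ds)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str, use_ds: bool) -> GenotypePanel:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    snp_ids, rows, mapping, rsqs = [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ds = None
        if use_ds:
            try:
                ds = v.format("DS")
            except KeyError:
                ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(v.genotypes, dtype=object)
            dose = np.empty(len(samples))
            for j, g in enumerate(gts):
                a, b = g[0], g[1]
                dose[j] = np.nan if (a < 0 or b < 0) else float(a + b)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        snp_ids.append(vid)
        rows.append(dose)
        mapping.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        rsqs.append(v.INFO.get("R2", v.INFO.get("RSQ", np.nan)))
    snp_map = pd.DataFrame(mapping, columns=["chrom", "pos", "ref", "alt"])
    rsq = np.asarray(rsqs, dtype=float)
    return GenotypePanel(
        individual_ids=np.asarray(samples, dtype=object),
        snp_ids=np.asarray(snp_ids, dtype=object),
        dosage=np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0)),
        snp_map=snp_map,
        rsq=None if np.isnan(rsq).all() else rsq,
        n_skipped_multiallelic=n_multi,
    )


def _read_dosage_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    extra = [c for c in ("rsq", "category") if c in df.columns]
    ind_cols = [c for c in df.columns if c not in meta_cols + extra]
    if not set(meta_cols) <= set(df.columns):
        raise FormatError(f"dosage_tsv requires columns {meta_cols}")
    return GenotypePanel(
        individual_ids=np.asarray(ind_cols, dtype=object),
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        dosage=df[ind_cols].to_numpy(dtype=float).T,
        snp_map=df[["chrom", "pos", "ref", "alt"]].copy(),
        rsq=df["rsq"].to_numpy(dtype=float) if "rsq" in extra else None,
        category=df["category"].to_numpy(dtype=object) if "category" in extra else None,
    )


def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    df = panel.snp_map.copy()
    df.insert(0, "snp_id", panel.snp_ids)
    if panel.rsq is not None:
        df["rsq"] = panel.rsq
    if panel.category is not None:
        df["category"] = panel.category
    dose = pd.DataFrame(
        panel.dosage.T, columns=[str(i) for i in panel.individual_ids]
    )
    pd.concat([df, dose], axis=1).to_csv(path, sep="\t", index=False,
                                         float_format="%.17g")


# ---------------------------------------------------------------------------
# annotation

_GFF3_CLASS = {
    "exon": "exon",
    "CDS": "exon",
    "five_prime_UTR": "UTR5",
    "three_prime_UTR": "UTR3",
    "ncRNA": "ncRNA",
    "ncRNA_gene": "ncRNA",
    "lnc_RNA": "ncRNA",
    "intron": "intron",
    "gene": "gene",
    "mRNA": "gene",
}


def read_annotation(
    path, format: str = "gff3", upstream_bp: int = 1000, downstream_bp: int = 1000
) -> AnnotationSet:
    """Read SNP annotation intervals from GFF3 or BED.

    Gene-body features (``gene``/``mRNA`` in GFF3, name ``gene`` in BED) are
    stored as ``intron`` intervals (a SNP inside a gene with no finer feature
    is intronic) and expanded into ``upstream``/``downstream`` flank intervals
    of the given widths, oriented by strand where available (BED input without
    a strand column is treated as + strand).  The 1 kb default flank width is
    the conventional gene-based-annotation default.
    """
    rows: list[tuple] = []
    if format == "gff3":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                comment="#",
                header=None,
                names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attr"],
                dtype={"chrom": str},
            )
        except pd.errors.EmptyDataError:
            return AnnotationSet()
        if df.empty:
            return AnnotationSet()
        for rec in df.itertuples(index=False):
            cls = _GFF3_CLASS.get(rec.type)
            if cls is None:
                warnings.warn(f"skipping unknown GFF3 feature type {rec.type!r}")
                continue
            _emit(rows, rec.chrom, int(rec.start), int(rec.end), cls,
                  rec.strand, upstream_bp, downstream_bp)
    elif format == "bed":
        try:
            df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype={0: str})
        except pd.errors.EmptyDataError:
            return AnnotationSet()
        if df.shape[1] < 3:
            raise FormatError("BED needs at least 3 columns")
        for rec in df.itertuples(index=False):
            chrom, start0, end0 = rec[0], int(rec[1]), int(rec[2])
            name = str(rec[3]) if df.shape[1] > 3 else "gene"
            strand = str(rec[5]) if df.shape[1] > 5 else "+"
            cls = name if name in FEATURE_CLASSES else _GFF3_CLASS.get(name)
            if cls is None:
                warnings.warn(f"skipping unknown BED feature name {name!r}")
                continue
            # BED is 0-based half-open
            _emit(rows, chrom, start0 + 1, end0, cls, strand, upstream_bp, downstream_bp)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not rows:
        return AnnotationSet()
    return AnnotationSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "feature"]))


def _emit(rows, chrom, start, end, cls, strand, up, down):
    if start > end:
        raise FormatError(f"interval start {start} > end {end} on {chrom}")
    body_cls = "intron" if cls == "gene" else cls
    rows.append((chrom, start, end, body_cls))
    if cls == "gene":
        left = (start - up, start - 1, "upstream" if strand != "-" else "downstream")
        right = (end + 1, end + down, "downstream" if strand != "-" else "upstream")
        for s, e, c in (left, right):
            s = max(1, s)
            if s <= e and (c == "upstream" and up > 0 or c == "downstream" and down > 0):
                rows.append((chrom, s, e, c))


# ---------------------------------------------------------------------------
# tables

def write_grm(ids, matrix: np.ndarray, path) -> None:
    """Write a relationship matrix: header of IDs, then the lower triangle."""
    matrix = np.asarray(matrix, float)
    with open(path, "w") as fh:
        fh.write("\t".join(str(i) for i in ids) + "\n")
        for i in range(matrix.shape[0]):
            fh.write("\t".join(f"{matrix[i, j]:.17g}" for j in range(i + 1)) + "\n")


def read_grm(path, tol: float = 1e-12):
    """Read a GRM text file; returns (ids, matrix).  The stored lower triangle
    is mirrored, so the result is symmetric by construction."""
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        n = len(ids)
        mat = np.zeros((n, n))
        for i in range(n):
            vals = fh.readline().split()
            if len(vals) != i + 1:
                raise FormatError(f"GRM row {i} has {len(vals)} values, expected {i + 1}")
            mat[i, : i + 1] = [float(v) for v in vals]
    mat = mat + np.tril(mat, -1).T
    return np.asarray(ids, dtype=object), mat


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table: columns id, value (EBV or DRP), reliability
    [, trait].  Reliabilities must lie in (0, 1]."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "value", "reliability"}
    if not required <= set(df.columns):
        raise FormatError(f"phenotype table needs columns {sorted(required)}")
    rel = df["reliability"].to_numpy(float)
    if (rel <= 0).any() or (rel > 1).any():
        bad = df.loc[(rel <= 0) | (rel > 1), "id"].iloc[0]
        raise FormatError(f"reliability outside (0,1] for individual {bad}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    if not {"id", "sire", "dam", "generation"} <= set(df.columns):
        raise FormatError("pedigree table needs columns id, sire, dam, generation")
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    out = ped.table.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].fillna("0")
    out.to_csv(path, sep="\t", index=False)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write hard-called genotypes as a minimal VCF 4.2 file (GT only).
    Dosages are rounded to the nearest integer call; NaN becomes ./. ."""
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in panel.individual_ids)
            + "\n"
        )
        snp_map = panel.snp_map
        for k in range(panel.n_snps):
            row = snp_map.iloc[k]
            calls = []
            for d in panel.dosage[:, k]:
                calls.append("./." if np.isnan(d) else code[int(round(d))])
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{panel.snp_ids[k]}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )
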