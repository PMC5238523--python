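"""Synthetic pedigreed layer-chicken populations for testing the pipeline.

The generator emulates the statistical structure the analysis assumes: a
multi-generation pedigree with full-sib families, linkage disequilibrium
decaying along chromosomes, polygenic traits controlled by many small-effect
loci, a dense "WGS" panel containing an evenly thinned "HD" subset,
genic/intergenic annotation, de-regressed-proof phenotypes with per-individual
reliabilities, and MAF-dependent imputation error with an Rsq-like quality
score.

Founder haplotypes are drawn from a Gaussian-copula Markov process: a latent
AR(1) series with per-adjacent-pair correlation exp(-d / d0) is thresholded
to give each locus its target allele frequency, producing LD that decays with
physical distance.  Offspring gametes are produced by gene dropping with a
Poisson number of crossovers per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import AnnotationSet, GenotypePanel, PedigreeTable
from .qc import classify_genic

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_population",
    "simulate_trait_and_drp",
    "emulate_array_and_imputation",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic population.

    Defaults emulate the real design this pipeline targets: roughly 900
    individuals from six generations of a closed layer line with full-sib
    families, segregating SNPs spread over a handful of macro-chromosomes,
    and about half of the SNPs in or around genes.
    """

    n_founders: int = 150
    n_generations: int = 6  # generations 0 .. n_generations-1, founders = 0
    n_matings: int = 25
    offspring_per_mating: int = 6
    n_chromosomes: int = 5
    n_snps: int = 5000
    chrom_length_bp: int = 50_000_000
    chrom_length_morgan: float = 1.0
    ld_decay_bp: float = 100_000.0  # d0 of the founder-haplotype copula
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    genic_fraction: float = 0.5
    genes_per_chromosome: int = 40
    n_qtl: int = 200
    qtl_genic_enrichment: float = 1.0  # sampling-odds ratio; inf = genic only
    h2: float = 0.4
    drp_reliability: float = 0.6
    thin_fraction: float = 0.1
    error_rate_low_maf: float = 0.3
    error_rate_high_maf: float = 0.01
    error_maf_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        if self.n_qtl > self.n_snps:
            raise ValueError("more QTL than SNPs")
        for name in ("n_founders", "n_generations", "n_matings",
                     "offspring_per_mating", "n_chromosomes", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulationTruth:
    """The oracle: QTL, true breeding values, realized heritability."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    tbv: np.ndarray  # per individual, centered-genotype dot effects
    realized_h2: float
    individual_ids: np.ndarray
    phenotype: np.ndarray | None = None


# ---------------------------------------------------------------------------


def _founder_haplotypes_block(rng, positions, p, d0, n_haplotypes):
    """Vectorized block of founder haplotypes (n_haplotypes x m)."""
    m = len(positions)
    rho = np.exp(-np.diff(positions) / d0)
    z = np.empty((n_haplotypes, m))
    z[:, 0] = rng.standard_normal(n_haplotypes)
    eps = rng.standard_normal((n_haplotypes, m - 1))
    scale = np.sqrt(1.0 - rho**2)
    for i in range(1, m):
        z[:, i] = rho[i - 1] * z[:, i - 1] + scale[i - 1] * eps[:, i - 1]
    return (z < norm.ppf(p)).astype(np.int8)


def _gamete(rng, hap_a, hap_b, positions, length_bp, length_morgan):
    """Recombine one parent's two haplotypes into a gamete."""
    n_xo = rng.poisson(length_morgan)
    current = rng.integers(2)
    if n_xo == 0:
        return (hap_a if current == 0 else hap_b).copy()
    xo = np.sort(rng.uniform(0, length_bp, size=n_xo))
    segment = current + np.searchsorted(xo, positions, side="right")
    take_b = (segment % 2).astype(bool)
    return np.where(take_b, hap_b, hap_a)


def _make_annotation(cfg: SimulationConfig, chrom_names) -> AnnotationSet:
    """Tile each chromosome with genes so gene bodies (plus flanks) cover
    about ``genic_fraction`` of the sequence; every 10th gene is an ncRNA."""
    rows = []
    flank = 1000
    L = cfg.chrom_length_bp
    n_genes = cfg.genes_per_chromosome
    body_len = int(cfg.genic_fraction * L / n_genes) - 2 * flank
    body_len = max(body_len, 600)
    pitch = L // n_genes
    for chrom in chrom_names:
        for gidx in range(n_genes):
            start = gidx * pitch + (pitch - body_len) // 2
            end = start + body_len - 1
            if gidx % 10 == 9:
                rows.append((chrom, start, end, "ncRNA"))
            else:
                utr = max(body_len // 20, 50)
                rows.append((chrom, start, start + utr - 1, "UTR5"))
                rows.append((chrom, end - utr + 1, end, "UTR3"))
                inner_start, inner_end = start + utr, end - utr
                n_ex = 5
                span = (inner_end - inner_start + 1) // (2 * n_ex - 1)
                pos = inner_start
                for k in range(2 * n_ex - 1):
                    seg_end = inner_end if k == 2 * n_ex - 2 else pos + span - 1
                    cls = "exon" if k % 2 == 0 else "intron"
                    rows.append((chrom, pos, seg_end, cls))
                    if cls == "intron":  # 2 bp splice sites at both ends
                        rows.append((chrom, pos, pos + 1, "splicing"))
                        rows.append((chrom, seg_end - 1, seg_end, "splicing"))
                    pos = seg_end + 1
            rows.append((chrom, max(1, start - flank), start - 1, "upstream"))
            rows.append((chrom, end + 1, end + flank, "downstream"))
    return AnnotationSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "feature"]))


def simulate_population(cfg: SimulationConfig):
    """Generate (GenotypePanel "WGS", PedigreeTable, AnnotationSet).

    The panel is returned with per-SNP annotation categories already
    assigned.  Same seed, same outputs, bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    snps_per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    snps_per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1

    positions, chroms = [], []
    for c, m_c in enumerate(snps_per_chrom):
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length_bp), size=m_c,
                                 replace=False))
        positions.append(pos)
        chroms.extend([chrom_names[c]] * m_c)
    target_maf = rng.uniform(cfg.founder_maf_low, cfg.founder_maf_high, cfg.n_snps)
    # the second allele is the minor one half the time
    flip = rng.random(cfg.n_snps) < 0.5
    target_p = np.where(flip, 1.0 - target_maf, target_maf)

    # pedigree
    records = []  # (id, sire, dam, generation, sex)
    for i in range(cfg.n_founders):
        records.append((f"G0_{i}", None, None, 0, i % 2))
    for g in range(1, cfg.n_generations):
        prev = [r for r in records if r[3] == g - 1]
        males = [r[0] for r in prev if r[4] == 0]
        females = [r[0] for r in prev if r[4] == 1]
        sires = rng.choice(males, size=cfg.n_matings, replace=len(males) < cfg.n_matings)
        dams = rng.choice(females, size=cfg.n_matings, replace=len(females) < cfg.n_matings)
        k = 0
        for s, d in zip(sires, dams):
            for _ in range(cfg.offspring_per_mating):
                records.append((f"G{g}_{k}", s, d, g, k % 2))
                k += 1
    ids = [r[0] for r in records]
    index = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)

    # haplotypes: n x 2 x m int8, per chromosome
    hap = np.empty((n, 2, cfg.n_snps), dtype=np.int8)
    offset = 0
    for c, m_c in enumerate(snps_per_chrom):
        sl = slice(offset, offset + m_c)
        founders_h = _founder_haplotypes_block(
            rng, positions[c].astype(float), target_p[sl], cfg.ld_decay_bp,
            2 * cfg.n_founders,
        )
        hap[: cfg.n_founders, 0, sl] = founders_h[0::2]
        hap[: cfg.n_founders, 1, sl] = founders_h[1::2]
        for rec in records[cfg.n_founders:]:
            i = index[rec[0]]
            si, di = index[rec[1]], index[rec[2]]
            hap[i, 0, sl] = _gamete(rng, hap[si, 0, sl], hap[si, 1, sl],
                                    positions[c], cfg.chrom_length_bp,
                                    cfg.chrom_length_morgan)
            hap[i, 1, sl] = _gamete(rng, hap[di, 0, sl], hap[di, 1, sl],
                                    positions[c], cfg.chrom_length_bp,
                                    cfg.chrom_length_morgan)
        offset += m_c

    dosage = hap.sum(axis=1).astype(float)
    snp_map = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.concatenate(positions),
            "ref": "A",
            "alt": "B",
        }
    )
    panel = GenotypePanel(
        individual_ids=np.asarray(ids, dtype=object),
        snp_ids=np.asarray([f"snp{k}" for k in range(cfg.n_snps)], dtype=object),
        dosage=dosage,
        snp_map=snp_map,
    )
    annotation = _make_annotation(cfg, chrom_names)
    panel = classify_genic(panel, annotation)
    pedigree = PedigreeTable(
        pd.DataFrame(
            {
                "id": ids,
                "sire": [r[1] for r in records],
                "dam": [r[2] for r in records],
                "generation": [r[3] for r in records],
            }
        )
    )
    return panel, pedigree, annotation


# ---------------------------------------------------------------------------


def _sample_qtl(rng, panel: GenotypePanel, n_qtl: int, enrichment: float):
    """QTL indices with genic sampling-odds enrichment (inf = genic only)."""
    m = panel.n_snps
    if panel.category is not None:
        genic = panel.genic
    else:
        genic = np.zeros(m, dtype=bool)
    if np.isinf(enrichment):
        pool = np.where(genic)[0]
        if len(pool) < n_qtl:
            raise ValueError("not enough genic SNPs for genic-only QTL sampling")
        return np.sort(rng.choice(pool, size=n_qtl, replace=False))
    w = np.where(genic, enrichment, 1.0).astype(float)
    w /= w.sum()
    return np.sort(rng.choice(m, size=n_qtl, replace=False, p=w))


def simulate_trait_and_drp(
    panel: GenotypePanel,
    n_qtl: int | None = None,
    h2: float | None = None,
    reliability: float | None = None,
    qtl_genic_enrichment: float = 1.0,
    mode: str = "direct_drp",
    trait: str = "trait",
    seed: int = 0,
    cfg: SimulationConfig | None = None,
):
    """Simulate a polygenic trait; returns (SimulationTruth, DRPTable).

    QTL effects are normal with small per-locus variance (the trait is
    controlled by numerous loci of very small effect); the true breeding value
    is the centered-genotype dot product with the effects.  ``direct_drp``
    draws DRP = TBV + noise calibrated so that corr(DRP, TBV)^2 equals the
    target reliability.  ``pedigree_ebv`` simulates phenotypes, runs a
    pedigree-BLUP animal model and feeds the EBVs through the Garrick
    de-regression (needs ``pedigree``).
    """
    if cfg is not None:
        n_qtl = cfg.n_qtl if n_qtl is None else n_qtl
        h2 = cfg.h2 if h2 is None else h2
        reliability = cfg.drp_reliability if reliability is None else reliability
    rng = np.random.default_rng(seed)
    n, m = panel.n_individuals, panel.n_snps
    if n_qtl == 0:
        if h2:
            raise ValueError("zero QTL with h2 > 0 is inconsistent")
        truth = SimulationTruth(
            qtl_indices=np.empty(0, int), qtl_effects=np.empty(0),
            tbv=np.zeros(n), realized_h2=0.0,
            individual_ids=panel.individual_ids,
        )
        drp = pd.DataFrame(
            {"id": panel.individual_ids.astype(str), "drp": np.zeros(n),
             "reliability": np.full(n, reliability or 0.5), "trait": trait,
             "method": "direct"}
        )
        return truth, drp

    qtl = _sample_qtl(rng, panel, n_qtl, qtl_genic_enrichment)
    effects = rng.standard_normal(n_qtl) / np.sqrt(n_qtl)
    p = panel.allele_freq[qtl]
    M = panel.dosage[:, qtl] - 2.0 * p
    tbv = M @ effects
    var_tbv = tbv.var()
    if var_tbv <= 0:
        raise ValueError("true breeding values have zero variance")
    var_env = var_tbv * (1.0 - h2) / h2
    phenotype = tbv + rng.standard_normal(n) * np.sqrt(var_env)
    realized_h2 = var_tbv / phenotype.var()

    if mode == "direct_drp":
        r2 = float(reliability)
        noise = rng.standard_normal(n) * np.sqrt(var_tbv * (1.0 - r2) / r2)
        drp_vals = tbv + noise
        drp = pd.DataFrame(
            {"id": panel.individual_ids.astype(str), "drp": drp_vals,
             "reliability": np.full(n, r2), "trait": trait, "method": "direct"}
        )
    elif mode == "pedigree_ebv":
        raise ValueError("pedigree_ebv mode needs simulate_trait_and_drp_pedigree")
    else:
        raise ValueError(f"unknown DRP mode {mode!r}")

    truth = SimulationTruth(
        qtl_indices=qtl, qtl_effects=effects, tbv=tbv,
        realized_h2=float(realized_h2), individual_ids=panel.individual_ids,
        phenotype=phenotype,
    )
    return truth, drp


def _a_inverse(pedigree: PedigreeTable) -> np.ndarray:
    """Dense inverse of the numerator relationship matrix by Henderson's
    rules (inbreeding ignored; adequate for the synthetic designs here)."""
    tab = pedigree.table
    ids = tab["id"].tolist()
    idx = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    Ainv = np.zeros((n, n))
    for rec in tab.itertuples(index=False):
        i = idx[rec.id]
        s = idx.get(rec.sire) if pd.notna(rec.sire) else None
        d = idx.get(rec.dam) if pd.notna(rec.dam) else None
        parents = [p for p in (s, d) if p is not None]
        alpha = {0: 1.0, 1: 4.0 / 3.0, 2: 2.0}[len(parents)]
        Ainv[i, i] += alpha
        for p in parents:
            Ainv[i, p] -= alpha / 2.0
            Ainv[p, i] -= alpha / 2.0
            Ainv[p, p] += alpha / 4.0
        if len(parents) == 2:
            Ainv[s, d] += alpha / 4.0
            Ainv[d, s] += alpha / 4.0
    return Ainv


def pedigree_blup_ebv(phenotype, pedigree: PedigreeTable, h2: float):
    """Single-trait animal-model BLUP on the full pedigree.

    Returns a DataFrame (id, value, reliability) of EBVs with reliabilities
    from the prediction error variances of the mixed-model equations.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    lam = (1.0 - h2) / h2
    Ainv = _a_inverse(pedigree)
    # MME: [n, 1'Z; Z'1, I + lam*Ainv] for mu and animal effects (Z = I)
    lhs = np.zeros((n + 1, n + 1))
    lhs[0, 0] = n
    lhs[0, 1:] = 1.0
    lhs[1:, 0] = 1.0
    lhs[1:, 1:] = np.eye(n) + lam * Ainv
    rhs = np.concatenate([[y.sum()], y])
    C = np.linalg.inv(lhs)
    sol = C @ rhs
    ebv = sol[1:]
    var_p = y.var()
    sigma2_a = h2 * var_p
    sigma2_e = (1.0 - h2) * var_p
    pev = np.diag(C)[1:] * sigma2_e
    rel = np.clip(1.0 - pev / sigma2_a, 1e-4, 0.999)
    return pd.DataFrame(
        {"id": pedigree.table["id"].astype(str), "value": ebv, "reliability": rel}
    )


def simulate_drp_via_pedigree(truth: SimulationTruth, pedigree: PedigreeTable,
                              h2: float, trait: str = "trait"):
    """End-to-end DRP: phenotype -> pedigree BLUP -> Garrick de-regression."""
    from .deregression import deregress, parent_average

    ebv_tab = pedigree_blup_ebv(truth.phenotype, pedigree, h2)
    pa = parent_average(ebv_tab, pedigree)
    merged = ebv_tab.merge(pa, on="id")
    # guard: the individual must carry information beyond its parent average
    r2 = np.maximum(merged["reliability"].to_numpy(),
                    merged["r2_pa"].to_numpy() + 1e-4)
    return deregress(
        ebv=merged["value"].to_numpy(),
        r2_ebv=r2,
        pa=merged["pa"].to_numpy(),
        r2_pa=merged["r2_pa"].to_numpy(),
        h2=h2,
        method="garrick",
        ids=merged["id"].to_numpy(),
        trait=trait,
    )


# ---------------------------------------------------------------------------


def emulate_array_and_imputation(
    panel: GenotypePanel,
    thin_fraction: float = 0.1,
    error_rate_low_maf: float = 0.3,
    error_rate_high_maf: float = 0.01,
    maf_threshold: float = 0.05,
    seed: int = 0,
):
    """Thin a "WGS" panel to an "HD" array and corrupt it like imputation.

    HD is the evenly spaced subset of round(thin_fraction * m) SNPs.  The
    imputed panel replaces each genotype, with a MAF-dependent probability,
    by a Hardy-Weinberg draw at that SNP's frequency; the per-SNP Rsq score
    is the squared correlation between the true and corrupted dosages (1.0
    where the corrupted SNP has no variance left or no error occurred).
    Returns (hd_panel, imputed_panel).
    """
    if not 0 < thin_fraction < 1:
        raise ValueError("thin_fraction must lie in (0, 1)")
    for r in (error_rate_low_maf, error_rate_high_maf):
        if not 0 <= r <= 0.5:
            raise ValueError("error rates must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    m = panel.n_snps
    k = int(round(thin_fraction * m))
    hd_idx = np.linspace(0, m - 1, k).round().astype(int)
    hd = panel.subset(snp_mask=hd_idx)

    p = panel.allele_freq
    maf = np.minimum(p, 1.0 - p)
    rate = np.where(maf < maf_threshold, error_rate_low_maf, error_rate_high_maf)
    err = rng.random(panel.dosage.shape) < rate
    hwe_draw = rng.binomial(2, np.broadcast_to(p, panel.dosage.shape)).astype(float)
    corrupted = np.where(err, hwe_draw, panel.dosage)

    rsq = np.ones(m)
    for j in range(m):
        a, b = panel.dosage[:, j], corrupted[:, j]
        if a.std() > 0 and b.std() > 0 and not np.array_equal(a, b):
            rsq[j] = np.corrcoef(a, b)[0, 1] ** 2
    imputed = panel.subset()
    imputed.dosage = corrupted
    imputed.rsq = rsq
    return hd, imputed
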