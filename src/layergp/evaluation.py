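"""The experimental design: cross-validation, predictive ability and bias,
the architecture-blend grid search, and full-sib ranking comparisons.

A scenario is a GRM recipe (G_I, G_P100, G_P005, G_S, G_z or G_G) applied to
a panel and a trait.  Per cross-validation fold, every trait-specific
quantity (GWAS p-values, RRBLUP effects, blend parameters, variance
components) is derived exclusively from the training individuals; centering
frequencies, by contrast, always come from the full current panel.
Predictive ability is the Pearson correlation between DGV and DRP in the
validation set; bias is the slope of the regression of DRP on DGV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deregression import reliability_weights
from .gblup import GBLUP
from .grm import (
    GRM,
    blend_blupga,
    build_architecture_matrix,
    build_grm,
    center_genotypes,
    compute_weights,
)
from .gwas import genotype_pca, single_snp_gwas, tracy_widom_select
from .io_formats import GenotypePanel

__all__ = [
    "CVPlan",
    "ScenarioResult",
    "make_cv_folds",
    "predictive_ability_and_bias",
    "family_rank_correlations",
    "blupga_grid_search",
    "run_scenario",
    "RECIPES",
]

RECIPES = ("G_I", "G_P100", "G_P005", "G_S", "G_z", "G_G")

#: Default grids of the architecture blend (the stated search ranges are
#: top% in [0.05, 10] and omega in [0.1, 0.99]).
DEFAULT_TOP_PCT_GRID = (0.05, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0)
DEFAULT_OMEGA_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)

_P_FLOOR = 1e-300


@dataclass
class CVPlan:
    """Fold assignments: folds[replicate][fold] is an array of validation IDs."""

    folds: list
    k: int
    replicates: int
    seed: int
    mode: str

    def validation_ids(self, rep: int, fold: int) -> np.ndarray:
        return self.folds[rep][fold]


@dataclass
class ScenarioResult:
    """Per-fold metrics of one scenario plus their aggregation."""

    scenario: str
    fold_records: pd.DataFrame  # replicate, fold, n_val, pa, bias, mu, s2g, s2e, ...
    mean_pa: float
    sd_pa: float
    mean_bias: float
    sd_bias: float
    chosen_params: list = field(default_factory=list)
    dgv_first_replicate: pd.Series | None = None

    def summary(self) -> str:
        return (
            f"{self.scenario}: predictive ability {self.mean_pa:.3f} "
            f"+/- {self.sd_pa:.3f}, bias slope {self.mean_bias:.3f} "
            f"+/- {self.sd_bias:.3f} over {len(self.fold_records)} folds"
        )


def make_cv_folds(
    ids,
    k: int = 5,
    replicates: int = 5,
    seed: int = 0,
    mode: str = "random",
    generations=None,
    n_forward_generations: int = 2,
) -> CVPlan:
    """Deal individuals into validation folds.

    random: each replicate shuffles the IDs with its own stream seeded from
    ``seed`` and deals k near-equal folds (sizes differ by at most one, the
    first n mod k folds being larger).  forward: a single "fold" holding all
    individuals of the last ``n_forward_generations`` generations.
    """
    ids = np.asarray(ids).astype(str)
    if len(np.unique(ids)) != len(ids):
        raise ValueError("IDs must be unique")
    if mode == "random":
        if not 2 <= k <= len(ids):
            raise ValueError("need 2 <= k <= n")
        streams = np.random.SeedSequence(seed).spawn(replicates)
        folds = []
        for rep in range(replicates):
            rng = np.random.default_rng(streams[rep])
            perm = rng.permutation(ids)
            folds.append([np.sort(a) for a in np.array_split(perm, k)])
        return CVPlan(folds=folds, k=k, replicates=replicates, seed=seed, mode=mode)
    if mode == "forward":
        if generations is None:
            raise ValueError("forward mode needs generation labels")
        gen = pd.Series(np.asarray(generations), index=ids)
        last = np.sort(gen.unique())[-n_forward_generations:]
        val = np.sort(gen.index[gen.isin(last)].to_numpy())
        return CVPlan(folds=[[val]], k=1, replicates=1, seed=seed, mode=mode)
    raise ValueError(f"unknown CV mode {mode!r}")


def predictive_ability_and_bias(dgv_val, drp_val):
    """(Pearson r between DGV and DRP, slope of DRP regressed on DGV).

    Returns (nan, nan) when the DGV has no variance (flagged missing).
    """
    dgv = np.asarray(dgv_val, dtype=float)
    drp = np.asarray(drp_val, dtype=float)
    if len(dgv) < 3 or len(dgv) != len(drp):
        raise ValueError("need at least 3 aligned pairs")
    if dgv.std() == 0 or drp.std() == 0:
        return (np.nan, np.nan)
    r = float(np.corrcoef(dgv, drp)[0, 1])
    slope = float(np.cov(drp, dgv, ddof=1)[0, 1] / np.var(dgv, ddof=1))
    return (r, slope)


def family_rank_correlations(dgv_by_scenario: dict, drp: pd.Series, family_ids):
    """Pairwise Spearman rank correlations among scenario DGVs and DRP,
    restricted to one (full-sib) family; ties handled by midranks."""
    fam = np.asarray(family_ids).astype(str)
    if len(fam) < 3:
        raise ValueError("family needs at least 3 members")
    vectors = {name: pd.Series(v).loc[fam].to_numpy(float)
               for name, v in dgv_by_scenario.items()}
    vectors["DRP"] = pd.Series(drp).loc[fam].to_numpy(float)
    names = list(vectors)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rho = stats.spearmanr(vectors[a], vectors[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


# ---------------------------------------------------------------------------
# scenario machinery


def _fit_fold(grm: GRM, drp_table: pd.DataFrame, train_ids, ridge: float = 1e-8):
    model = GBLUP.from_tables(drp_table, grm, train_ids=train_ids, ridge=ridge)
    return model.fit()


def _rrblup_effects_for(panel, drp_table, train_ids, cg_full, grm_identity,
                        ridge=1e-8):
    """Identity-weight RRBLUP effects derived from the given training set."""
    res = _fit_fold(grm_identity, drp_table, train_ids, ridge=ridge)
    eff = res.snp_effects(cg_full)
    return eff.beta, res


def blupga_grid_search(
    panel: GenotypePanel,
    drp_table: pd.DataFrame,
    train_ids,
    grm_identity: GRM,
    cg_full,
    top_pct_grid=DEFAULT_TOP_PCT_GRID,
    omega_grid=DEFAULT_OMEGA_GRID,
    inner_k: int = 5,
    seed: int = 0,
    ridge: float = 1e-8,
):
    """Pick (top%, omega) by inner cross-validation inside the training fold.

    For each inner split, RRBLUP effects come from the inner-training
    individuals only; every grid point then gets its blended matrix, a fresh
    REML fit and an inner-validation predictive ability.  The pair with the
    best mean predictive ability wins; exact ties break toward smaller omega,
    then smaller top%.
    """
    if len(top_pct_grid) == 0 or len(omega_grid) == 0:
        raise ValueError("grids must be non-empty")
    if inner_k < 2:
        raise ValueError("inner_k must be >= 2")
    if len(top_pct_grid) == 1 and len(omega_grid) == 1:
        return (top_pct_grid[0], omega_grid[0])
    train_ids = np.asarray(train_ids).astype(str)
    inner_plan = make_cv_folds(train_ids, k=inner_k, replicates=1, seed=seed)
    drp_train = drp_table[drp_table["id"].astype(str).isin(set(train_ids))]

    scores = {(t, w): [] for t in top_pct_grid for w in omega_grid}
    for fold in range(inner_k):
        val = inner_plan.validation_ids(0, fold)
        inner_train = np.setdiff1d(train_ids, val)
        beta, _ = _rrblup_effects_for(panel, drp_train, inner_train,
                                      cg_full, grm_identity, ridge)
        val_tab = drp_train.set_index(drp_train["id"].astype(str)).loc[val]
        for t in top_pct_grid:
            S = build_architecture_matrix(panel, beta, t)
            for w in omega_grid:
                Gz = blend_blupga(grm_identity, S, w)
                res = _fit_fold(Gz, drp_train, inner_train, ridge=ridge)
                pa, _ = predictive_ability_and_bias(
                    res.predict(val).to_numpy(), val_tab["drp"].to_numpy()
                )
                scores[(t, w)].append(pa)

    means = {k: float(np.nanmean(v)) for k, v in scores.items()}
    return _select_best(means, top_pct_grid, omega_grid)


def _select_best(means: dict, top_pct_grid, omega_grid):
    """Best (top_pct, omega) by mean inner predictive ability; exact ties
    break toward smaller omega, then smaller top%."""
    if all(np.isnan(v) for v in means.values()):
        raise ValueError("all grid points undefined")
    best, best_val = None, -np.inf
    for w in sorted(omega_grid):
        for t in sorted(top_pct_grid):
            v = means[(t, w)]
            if np.isfinite(v) and v > best_val:
                best, best_val = (t, w), v
    return best


def _weights_for_recipe(recipe, panel, drp_table, train_ids, cg, grm_identity,
                        seed, ridge):
    """Per-fold weight vector (or None for identity recipes)."""
    train_ids = np.asarray(train_ids).astype(str)
    tab = drp_table.set_index(drp_table["id"].astype(str))
    y_tr = tab.loc[train_ids, "drp"].to_numpy(float)
    ids_index = pd.Index(panel.individual_ids.astype(str))
    tr_pos = ids_index.get_indexer(train_ids)

    if recipe in ("G_P100", "G_P005"):
        alpha = 1e-100 if recipe == "G_P100" else 0.05
        cg_tr = center_genotypes(
            panel.subset(ind_mask=tr_pos), snp_subset=cg.snp_indices
        )
        pca = genotype_pca(cg_tr)
        pcs = tracy_widom_select(pca, alpha)
        cov = pca.scores[:, pcs] if pcs else None
        gw = single_snp_gwas(y_tr, panel.dosage[np.ix_(tr_pos, cg.snp_indices)], cov)
        return compute_weights("neglog10p", gw["p"].to_numpy(), p_floor=_P_FLOOR), {
            "n_pcs": len(pcs)
        }
    if recipe == "G_S":
        beta, _ = _rrblup_effects_for(panel, drp_table, train_ids, cg,
                                      grm_identity, ridge)
        return compute_weights("squared_effect", beta), {}
    raise ValueError(f"recipe {recipe!r} has no weight scheme")


def run_scenario(
    panel: GenotypePanel,
    drp_table: pd.DataFrame,
    recipe: str,
    cv_plan: CVPlan,
    snp_subset=None,
    top_pct_grid=DEFAULT_TOP_PCT_GRID,
    omega_grid=DEFAULT_OMEGA_GRID,
    inner_k: int = 5,
    ridge: float = 1e-8,
    fixed_blend=None,
) -> ScenarioResult:
    """Run one GRM recipe through a cross-validation plan.

    ``snp_subset`` restricts the matrix construction (G_G passes the genic
    mask; defaults to all SNPs).  ``fixed_blend`` = (top_pct, omega) skips the
    grid search of the G_z recipe.  Returns per-fold and aggregated metrics,
    and the validation-set DGVs of the first replicate (for the full-sib
    ranking comparison).
    """
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; one of {RECIPES}")
    if recipe == "G_G" and snp_subset is None:
        snp_subset = panel.genic
    cg = center_genotypes(panel, snp_subset=snp_subset)
    grm_identity = build_grm(cg)
    grm_identity.recipe["snp_subset_size"] = cg.n_snps

    tab = drp_table.set_index(drp_table["id"].astype(str))
    all_ids = panel.individual_ids.astype(str)
    records = []
    chosen = []
    dgv_first = {}
    for rep in range(cv_plan.replicates):
        for fold in range(len(cv_plan.folds[rep])):
            val = cv_plan.validation_ids(rep, fold)
            train = np.setdiff1d(all_ids, val)
            fold_seed = (cv_plan.seed * 1_000_003 + rep * 101 + fold) % (2**31)

            params = {}
            if recipe in ("G_I", "G_G"):
                G = grm_identity
            elif recipe in ("G_P100", "G_P005", "G_S"):
                w, params = _weights_for_recipe(
                    recipe, panel, drp_table, train, cg, grm_identity,
                    fold_seed, ridge,
                )
                G = build_grm(cg, w)
            elif recipe == "G_z":
                if fixed_blend is not None:
                    top_pct, omega = fixed_blend
                else:
                    top_pct, omega = blupga_grid_search(
                        panel, drp_table, train, grm_identity, cg,
                        top_pct_grid, omega_grid, inner_k, seed=fold_seed,
                        ridge=ridge,
                    )
                params = {"top_pct": top_pct, "omega": omega}
                chosen.append((rep, fold, top_pct, omega))
                beta, _ = _rrblup_effects_for(panel, drp_table, train, cg,
                                              grm_identity, ridge)
                S = build_architecture_matrix(
                    panel, beta, top_pct, snp_subset=cg.snp_indices
                )
                G = blend_blupga(grm_identity, S, omega)

            res = _fit_fold(G, drp_table, train, ridge=ridge)
            dgv_val = res.predict(val).to_numpy()
            drp_val = tab.loc[val, "drp"].to_numpy(float)
            pa, bias = predictive_ability_and_bias(dgv_val, drp_val)
            rec = {
                "replicate": rep,
                "fold": fold,
                "n_val": len(val),
                "n_train": len(train),
                "pa": pa,
                "bias": bias,
                "mu": res.mu,
                "sigma2_g": res.varcomps.sigma2_g,
                "sigma2_e": res.varcomps.sigma2_e,
            }
            rec.update(params)
            records.append(rec)
            if rep == 0:
                for iid, v in zip(val, dgv_val):
                    dgv_first[iid] = v

    fold_df = pd.DataFrame(records)
    return ScenarioResult(
        scenario=recipe,
        fold_records=fold_df,
        mean_pa=float(np.nanmean(fold_df["pa"])),
        sd_pa=float(np.nanstd(fold_df["pa"], ddof=1)),
        mean_bias=float(np.nanmean(fold_df["bias"])),
        sd_bias=float(np.nanstd(fold_df["bias"], ddof=1)),
        chosen_params=chosen,
        dgv_first_replicate=pd.Series(dgv_first, name=recipe),
    )
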