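"""GBLUP mixed model: REML variance components, genomic breeding values,
and the RRBLUP backsolve for per-SNP effects.

Model
-----
    y = X mu + Z g + e,   g ~ N(0, G sigma2_g),   e ~ N(0, R sigma2_e)

where y holds the de-regressed proofs of the training individuals, X is a
column of ones (the overall mean is the only fixed effect), Z maps each
training record onto the full set of genotyped individuals, G is a genomic
relationship matrix over all genotyped individuals, and R is diagonal with
R_ii = (1 - r2_DRP,i)/r2_DRP,i.

REML is computed by whitening with R^(-1/2), eigendecomposing the whitened
Z G Z' once, and maximizing the 1-D profile restricted likelihood over the
variance ratio lambda = sigma2_e / sigma2_g by Brent search on log(lambda).
Breeding values for individuals without records (the validation set) are
obtained through their G-covariances with the training individuals, which
requires no inversion of G itself:

    g_hat = G Z' (Z G Z' + lambda R)^(-1) (y - X mu_hat).

The dual RRBLUP parameterization g = M beta with Var(beta_k) = w_k sigma2_g / c
gives the backsolved SNP effects

    beta_hat_k = (w_k / c) m_k' (Z G Z' + lambda R)^(-1) (y - X mu_hat)

which reproduce the GBLUP breeding values exactly via DGV = M beta_hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .grm import GRM, CenteredGenotypes, WeightVector, compute_weights

__all__ = ["GBLUP", "GBLUPResults", "VarianceComponents", "SNPEffects"]

_LOG_LAMBDA_BOUNDS = (np.log(1e-6), np.log(1e6))
_LOG_LAMBDA_TOL = 1e-8


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    loglik: float
    converged: bool = True
    boundary: bool = False

    @property
    def lambda_(self) -> float:
        return self.sigma2_e / self.sigma2_g

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


@dataclass
class SNPEffects:
    """Backsolved RRBLUP SNP effects and the scaling they were computed under."""

    beta: np.ndarray
    weights: np.ndarray
    c: float
    snp_indices: np.ndarray


class GBLUP:
    """Genomic BLUP model for de-regressed proofs.

    Parameters
    ----------
    y : array of training records (DRP).
    grm : GRM over all genotyped individuals.
    train_ids : IDs of the individuals the records belong to, in y's order.
        Repeated IDs are allowed (multiple records per individual).
    r_weights : per-record diagonal of R; defaults to 1 (unweighted).
    ridge : epsilon added to the diagonal of G for near-singular matrices.
    """

    def __init__(self, y, grm: GRM, train_ids, r_weights=None, ridge: float = 0.0):
        self.grm = grm
        self.y = np.asarray(y, dtype=float)
        ids = pd.Index(np.asarray(grm.individual_ids).astype(str))
        pos = ids.get_indexer(np.asarray(train_ids).astype(str))
        if (pos < 0).any():
            missing = np.asarray(train_ids)[pos < 0][0]
            raise ValueError(f"training individual {missing!r} not in the GRM")
        self.train_pos = pos
        if len(self.y) != len(pos):
            raise ValueError("y and train_ids lengths differ")
        if len(self.y) < 3:
            raise ValueError("need at least 3 training records")
        self.r_weights = (
            np.ones(len(self.y)) if r_weights is None else np.asarray(r_weights, float)
        )
        if (self.r_weights <= 0).any():
            raise ValueError("residual weights must be positive")
        G = grm.values
        if ridge:
            G = G + ridge * np.eye(G.shape[0])
        self._G = G
        self._prepare()

    @classmethod
    def from_tables(cls, drp_table: pd.DataFrame, grm: GRM, train_ids=None, **kw):
        """Build from a DRP table (columns id, drp, reliability).

        ``train_ids`` restricts the records used for training; individuals in
        the GRM but not in the training records are predicted through G.
        """
        from .deregression import reliability_weights

        tab = drp_table
        if train_ids is not None:
            keep = tab["id"].astype(str).isin(set(map(str, train_ids)))
            tab = tab.loc[keep]
        return cls(
            y=tab["drp"].to_numpy(float),
            grm=grm,
            train_ids=tab["id"].to_numpy(),
            r_weights=reliability_weights(tab),
            **kw,
        )

    # -- internals ----------------------------------------------------------

    def _prepare(self):
        tr = self.train_pos
        K = self._G[np.ix_(tr, tr)]
        rhalf_inv = 1.0 / np.sqrt(self.r_weights)
        Kw = K * rhalf_inv[:, None] * rhalf_inv[None, :]
        evals, evecs = np.linalg.eigh((Kw + Kw.T) / 2.0)
        self._evals = np.maximum(evals, 0.0) if evals.min() > -1e-8 * max(
            1.0, evals.max()
        ) else self._reject_non_psd(evals)
        self._evecs = evecs
        self._rhalf_inv = rhalf_inv
        self._ystar = evecs.T @ (rhalf_inv * self.y)
        self._xstar = evecs.T @ rhalf_inv  # X is a column of ones

    @staticmethod
    def _reject_non_psd(evals):
        raise ValueError(
            f"G (whitened) is not PSD: min eigenvalue {evals.min():.3g}; "
            "add a diagonal ridge"
        )

    def _profile(self, log_lambda: float):
        """Profile REML pieces at a given log(lambda).

        V = sigma2_g (K + lambda I) in the whitened space; returns
        (-2 restricted loglik up to a constant, mu_hat, sigma2_g_hat).
        """
        lam = np.exp(log_lambda)
        d = self._evals + lam
        x, ys = self._xstar, self._ystar
        xtx = np.sum(x * x / d)
        xty = np.sum(x * ys / d)
        mu = xty / xtx
        resid = ys - mu * x
        rss = np.sum(resid * resid / d)
        n, p = len(ys), 1
        sigma2_g = rss / (n - p)
        # restricted loglik (constant terms dropped)
        ll = -0.5 * ((n - p) * np.log(sigma2_g) + np.log(d).sum() + np.log(xtx) + (n - p))
        return ll, mu, sigma2_g

    # -- API ----------------------------------------------------------------

    def fit(self, lambda_bounds=None, tol: float = _LOG_LAMBDA_TOL) -> "GBLUPResults":
        """Estimate (sigma2_g, sigma2_e) by profile REML and solve for mu and
        the breeding values of every genotyped individual."""
        lo, hi = (
            _LOG_LAMBDA_BOUNDS
            if lambda_bounds is None
            else (np.log(lambda_bounds[0]), np.log(lambda_bounds[1]))
        )
        res = minimize_scalar(
            lambda t: -self._profile(t)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        log_lam = float(res.x)
        boundary = log_lam > hi - 1e-3 or log_lam < lo + 1e-3
        if boundary:
            log_lam = hi if log_lam > (lo + hi) / 2 else lo
            warnings.warn(
                "REML optimum at the boundary of the variance-ratio search "
                "interval; variance component effectively at its bound"
            )
        ll, mu, sigma2_g = self._profile(log_lam)
        lam = np.exp(log_lam)
        vc = VarianceComponents(
            sigma2_g=sigma2_g,
            sigma2_e=sigma2_g * lam,
            loglik=ll,
            converged=bool(res.success),
            boundary=boundary,
        )
        return self.solve(vc)

    def solve(self, varcomps: VarianceComponents) -> "GBLUPResults":
        """Solve the mixed-model equations at fixed variance components."""
        if varcomps.sigma2_g <= 0:
            raise ValueError("sigma2_g must be positive to solve the MME")
        lam = varcomps.lambda_
        d = self._evals + lam
        x, ys = self._xstar, self._ystar
        xtx = np.sum(x * x / d)
        mu = np.sum(x * ys / d) / xtx
        resid = ys - mu * x
        # (ZGZ' + lam R)^(-1) (y - mu) in original record space:
        vinv_r = self._rhalf_inv * (self._evecs @ (resid / d))
        g_all = self._G[:, self.train_pos] @ vinv_r
        return GBLUPResults(model=self, mu=float(mu), varcomps=varcomps,
                            dgv=g_all, _vinv_resid=vinv_r)


class GBLUPResults:
    """Fitted GBLUP: variance components, overall mean and per-individual
    direct genomic values (DGV), including validation individuals."""

    def __init__(self, model: GBLUP, mu: float, varcomps: VarianceComponents,
                 dgv: np.ndarray, _vinv_resid: np.ndarray):
        self.model = model
        self.mu = mu
        self.varcomps = varcomps
        self._dgv = dgv
        self._vinv_resid = _vinv_resid

    @property
    def dgv(self) -> pd.Series:
        return pd.Series(
            self._dgv, index=np.asarray(self.model.grm.individual_ids).astype(str),
            name="dgv",
        )

    def predict(self, ids) -> pd.Series:
        return self.dgv.loc[np.asarray(ids).astype(str)]

    def snp_effects(self, cg: CenteredGenotypes, w: WeightVector | None = None) -> SNPEffects:
        """Backsolve RRBLUP SNP effects for the G = M diag(w) M'/c this model
        was (or would be) built from.  Zero-weight or monomorphic SNPs get 0."""
        if w is None:
            w = compute_weights("identity", m=cg.n_snps)
        M_tr = cg.M[self.model.train_pos]
        beta = (w.values / cg.c) * (M_tr.T @ self._vinv_resid)
        return SNPEffects(beta=beta, weights=w.values, c=cg.c,
                          snp_indices=cg.snp_indices)

    def summary(self) -> str:
        vc = self.varcomps
        n_train = len(self.model.y)
        lines = [
            "GBLUP mixed model (REML)",
            "=" * 40,
            f"training records        {n_train:>12d}",
            f"genotyped individuals   {self.model.grm.n:>12d}",
            f"mu                      {self.mu:>12.5f}",
            f"sigma2_g                {vc.sigma2_g:>12.5f}",
            f"sigma2_e                {vc.sigma2_e:>12.5f}",
            f"lambda (sigma2_e/g)     {vc.lambda_:>12.5f}",
            f"h2 (pseudo)             {vc.h2:>12.5f}",
            f"REML loglik (profile)   {vc.loglik:>12.5f}",
            f"boundary solution       {str(vc.boundary):>12s}",
        ]
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        return f"<GBLUPResults h2={self.varcomps.h2:.3f} n={self.model.grm.n}>"
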