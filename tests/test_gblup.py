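"""REML, GBLUP solving and the RRBLUP dual parameterization."""

import numpy as np
import pytest

from layergp import GBLUP
from layergp.gblup import VarianceComponents
from layergp.grm import GRM, build_grm, center_genotypes, compute_weights

from conftest import make_panel


def _hw_panel(rng, n, m, p_low=0.1, p_high=0.9):
    return make_panel(rng.binomial(2, rng.uniform(p_low, p_high, m), size=(n, m)))


def _simulate_y(rng, G, h2, sigma2=1.0):
    n = G.shape[0]
    L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
    g = L @ rng.standard_normal(n) * np.sqrt(h2 * sigma2)
    e = rng.standard_normal(n) * np.sqrt((1 - h2) * sigma2)
    return g + e


def _grm(values, ids=None):
    n = values.shape[0]
    ids = np.array([f"i{k}" for k in range(n)], dtype=object) if ids is None else ids
    return GRM(values=values, individual_ids=ids)


def _dense_mme(G, y, train_pos, r_diag, lam, ridge=1e-8):
    """Oracle: explicit inversion of the full mixed-model-equation matrix."""
    N = G.shape[0]
    n = len(y)
    Z = np.zeros((n, N))
    Z[np.arange(n), train_pos] = 1.0
    X = np.ones((n, 1))
    Rinv = np.diag(1.0 / r_diag)
    Ginv = np.linalg.inv(G + ridge * np.eye(N))
    lhs = np.block(
        [
            [X.T @ Rinv @ X, X.T @ Rinv @ Z],
            [Z.T @ Rinv @ X, Z.T @ Rinv @ Z + lam * Ginv],
        ]
    )
    rhs = np.concatenate([X.T @ Rinv @ y, Z.T @ Rinv @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[0], sol[1:]


class TestSolveGBLUP:
    def test_matches_dense_mme_inversion(self, rng):
        # 30 genotyped individuals, 10 of them validation-only
        N, n_train = 30, 20
        panel = _hw_panel(rng, N, 100)
        G = build_grm(center_genotypes(panel)).values
        train_pos = np.arange(n_train)
        y = _simulate_y(rng, G, 0.5)[:n_train]
        r_diag = rng.uniform(0.5, 2.0, n_train)
        lam = 1.3
        ridge = 1e-8
        mu_o, g_o = _dense_mme(G, y, train_pos, r_diag, lam, ridge)

        grm = _grm(G)
        model = GBLUP(y, grm, grm.individual_ids[train_pos], r_weights=r_diag,
                      ridge=ridge)
        vc = VarianceComponents(sigma2_g=1.0, sigma2_e=lam, loglik=0.0)
        res = model.solve(vc)
        assert abs(res.mu - mu_o) < 1e-8
        assert np.abs(res.dgv.to_numpy() - g_o).max() < 1e-8

    def test_identity_grm_closed_form_shrinkage(self, rng):
        n = 12
        y = rng.standard_normal(n)
        grm = _grm(np.eye(n))
        model = GBLUP(y, grm, grm.individual_ids)
        lam = 2.5
        res = model.solve(VarianceComponents(1.0, lam, 0.0))
        expected = (y - res.mu) / (1 + lam)
        np.testing.assert_allclose(res.dgv.to_numpy(), expected, atol=1e-10)

    def test_unlinked_validation_individual_gets_zero(self, rng):
        n = 10
        G = np.eye(n + 1)
        G[n, n] = 1.0  # no covariance with anyone
        y = rng.standard_normal(n)
        grm = _grm(G)
        model = GBLUP(y, grm, grm.individual_ids[:n])
        res = model.solve(VarianceComponents(1.0, 1.0, 0.0))
        assert res.dgv.iloc[-1] == 0.0

    def test_permutation_equivariance(self, rng):
        n = 25
        panel = _hw_panel(rng, n, 80)
        G = build_grm(center_genotypes(panel)).values
        y = _simulate_y(rng, G, 0.4)
        perm = rng.permutation(n)
        grm1 = _grm(G)
        res1 = GBLUP(y, grm1, grm1.individual_ids, ridge=1e-8).fit()
        grm2 = _grm(G[np.ix_(perm, perm)], ids=grm1.individual_ids[perm])
        res2 = GBLUP(y[perm], grm2, grm1.individual_ids[perm], ridge=1e-8).fit()
        np.testing.assert_allclose(
            res1.dgv.sort_index().to_numpy(), res2.dgv.sort_index().to_numpy(),
            atol=1e-8,
        )

    def test_shrinkage_monotone_in_lambda(self, rng):
        n = 20
        panel = _hw_panel(rng, n, 60)
        G = build_grm(center_genotypes(panel)).values
        y = _simulate_y(rng, G, 0.5)
        grm = _grm(G)
        model = GBLUP(y, grm, grm.individual_ids, ridge=1e-8)
        norms = [
            np.linalg.norm(model.solve(VarianceComponents(1.0, lam, 0.0)).dgv)
            for lam in [0.1, 0.5, 1.0, 5.0, 20.0, 100.0]
        ]
        assert all(b <= a + 1e-10 for a, b in zip(norms, norms[1:]))

    def test_split_record_equals_combined_weight(self, rng):
        # two half-information records on one individual == one full record
        n = 15
        panel = _hw_panel(rng, n, 50)
        G = build_grm(center_genotypes(panel)).values
        y = _simulate_y(rng, G, 0.5)
        grm = _grm(G)
        ids = grm.individual_ids
        r = np.ones(n)
        vc = VarianceComponents(1.0, 1.7, 0.0)
        res_single = GBLUP(y, grm, ids, r_weights=r, ridge=1e-8).solve(vc)
        y2 = np.concatenate([y, [y[0]]])
        ids2 = np.concatenate([ids, [ids[0]]])
        r2 = np.concatenate([r, [2.0]])
        r2[0] = 2.0
        res_split = GBLUP(y2, grm, ids2, r_weights=r2, ridge=1e-8).solve(vc)
        np.testing.assert_allclose(res_single.dgv, res_split.dgv, atol=1e-9)
        assert abs(res_single.mu - res_split.mu) < 1e-9


class TestREML:
    def _brute_force_reml(self, y, K, lam_grid):
        """Independent restricted-likelihood scan over the variance ratio."""
        n = len(y)
        X = np.ones((n, 1))
        best = (None, -np.inf)
        for lam in lam_grid:
            V = K + lam * np.eye(n)
            Vinv = np.linalg.inv(V)
            xvx = (X.T @ Vinv @ X).item()
            mu = (X.T @ Vinv @ y).item() / xvx
            r = y - mu
            rss = float(r @ Vinv @ r)
            s2g = rss / (n - 1)
            ll = -0.5 * (
                (n - 1) * np.log(s2g)
                + np.linalg.slogdet(V)[1]
                + np.log(xvx)
                + (n - 1)
            )
            if ll > best[1]:
                best = (lam, ll)
        return best[0]

    def test_matches_brute_force_scan(self, rng):
        n = 8
        panel = _hw_panel(rng, n, 30)
        G = build_grm(center_genotypes(panel)).values + 1e-6 * np.eye(n)
        y = _simulate_y(rng, G, 0.5)
        grid = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 50_001))
        lam_oracle = self._brute_force_reml(y, G, grid)
        grm = _grm(G)
        res = GBLUP(y, grm, grm.individual_ids).fit(lambda_bounds=(1e-4, 1e4))
        lam_hat = res.varcomps.lambda_
        assert abs(lam_hat - lam_oracle) / lam_oracle < 5e-3  # 3 significant digits

    def test_h2_recovery(self):
        # pedigreed population: relatedness makes h2 identifiable at n = 500
        from layergp import SimulationConfig, simulate_population

        h2_hats = []
        for s in range(20):
            cfg = SimulationConfig(
                n_founders=50, n_generations=4, n_matings=25,
                offspring_per_mating=6, n_snps=1000, n_chromosomes=2,
                seed=100 + s,
            )
            panel, _, _ = simulate_population(cfg)
            G = build_grm(center_genotypes(panel)).values
            rng = np.random.default_rng(200 + s)
            y = _simulate_y(rng, G, 0.4)
            grm = _grm(G, ids=panel.individual_ids)
            res = GBLUP(y, grm, grm.individual_ids, ridge=1e-8).fit()
            h2_hats.append(res.varcomps.h2)
        h2_hats = np.asarray(h2_hats)
        # per-run REML sampling sd at this design is about 0.05
        assert np.all(np.abs(h2_hats - 0.4) < 0.15)
        assert abs(h2_hats.mean() - 0.4) < 0.03

    def test_pure_noise_hits_boundary(self, rng):
        import warnings

        at_zero = 0
        for _ in range(20):
            panel = _hw_panel(rng, 800, 50)  # low-rank, strongly structured G
            G = build_grm(center_genotypes(panel)).values
            y = rng.standard_normal(800)  # no genetic signal
            grm = _grm(G)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = GBLUP(y, grm, grm.individual_ids, ridge=1e-8).fit()
            if res.varcomps.boundary or res.varcomps.h2 < 0.02:
                at_zero += 1
        assert at_zero >= 18

    def test_non_psd_grm_fatal(self, rng):
        n = 6
        G = -np.eye(n)
        y = rng.standard_normal(n)
        with pytest.raises(ValueError, match="PSD"):
            GBLUP(y, _grm(G), [f"i{k}" for k in range(n)])


class TestRRBLUP:
    @pytest.mark.parametrize("mode", ["identity", "neglog10p", "squared_effect"])
    def test_dgv_reconstruction_matches_gblup(self, rng, mode):
        n, m = 60, 150
        panel = _hw_panel(rng, n, m)
        cg = center_genotypes(panel)
        if mode == "identity":
            w = compute_weights("identity", m=m)
        elif mode == "neglog10p":
            w = compute_weights("neglog10p", rng.uniform(1e-6, 1.0, m))
        else:
            w = compute_weights("squared_effect", rng.standard_normal(m))
        grm = build_grm(cg, w)
        y = _simulate_y(rng, grm.values, 0.5)[:40]
        model = GBLUP(y, grm, grm.individual_ids[:40])
        res = model.fit()
        eff = res.snp_effects(cg, w)
        dgv_rebuilt = cg.M @ eff.beta
        assert np.abs(dgv_rebuilt - res.dgv.to_numpy()).max() < 1e-6

    def test_single_snp_closed_form_ridge(self, rng):
        n = 40
        dos = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        panel = make_panel(dos)
        cg = center_genotypes(panel)
        w = compute_weights("identity", m=1)
        grm = build_grm(cg, w)
        y = 0.8 * cg.M[:, 0] + rng.standard_normal(n)
        model = GBLUP(y, grm, grm.individual_ids, ridge=1e-10)
        lam = 2.0
        res = model.solve(VarianceComponents(1.0, lam, 0.0))
        eff = res.snp_effects(cg, w)
        mcol = cg.M[:, 0]
        resid = y - res.mu
        ols = (mcol @ resid) / (mcol @ mcol)
        shrink = (mcol @ mcol) / (mcol @ mcol + cg.c * lam / w.values[0])
        np.testing.assert_allclose(eff.beta[0], ols * shrink, rtol=1e-6)

    def test_monomorphic_snp_zero_effect(self, rng):
        dos = np.column_stack([rng.binomial(2, 0.5, 30), np.full(30, 2.0)])
        panel = make_panel(dos)
        cg = center_genotypes(panel)  # second column centered to zeros
        w = compute_weights("identity", m=2)
        grm = build_grm(cg, w)
        y = rng.standard_normal(30)
        res = GBLUP(y, grm, grm.individual_ids, ridge=1e-8).solve(
            VarianceComponents(1.0, 1.0, 0.0)
        )
        eff = res.snp_effects(cg, w)
        assert eff.beta[1] == 0.0
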