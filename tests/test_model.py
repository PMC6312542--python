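"""Covariance structures, REML likelihood, AI-REML fits, MME and LRT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metgblup import GxEModel, RelationshipMatrix, lrt
from metgblup.structures import (
    StructureError,
    env_cov_matrix,
    get_structure,
    implied_env_correlations,
)

from conftest import MODEL_KW, anova_reml_oneway, reml_loglik_error_contrast


def make_model(y, ids, envs, grm_values=None, labels=None, units=None):
    labels = labels or sorted(set(ids))
    pheno = pd.DataFrame({
        "Location": [e[0] for e in envs],
        "Year": [e[1] for e in envs],
        "REF_ID": ids,
        "y": y,
        "Experimental unit": units if units is not None
        else [f"u{k}" for k in range(len(y))],
    })
    grm = RelationshipMatrix(
        labels, grm_values if grm_values is not None else np.eye(len(labels))
    )
    return GxEModel(pheno, grm)


class TestEnvCovStructures:
    def test_cs_matrix(self):
        np.testing.assert_allclose(
            env_cov_matrix("cs", [3.0, 1.0], 2), [[4, 3], [3, 4]]
        )

    def test_fa1_rank_one(self):
        np.testing.assert_allclose(
            env_cov_matrix("fa1", [1, 1, 0, 0], 2), np.ones((2, 2))
        )

    def test_fa1_hand_example_and_correlation(self):
        cov = env_cov_matrix("fa1", [2, 1, 0, 3], 2)
        np.testing.assert_allclose(cov, [[4, 2], [2, 4]])
        corr = implied_env_correlations(cov)
        assert corr[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_uniform_matrix(self):
        np.testing.assert_allclose(
            env_cov_matrix("uniform", [2.5], 3), 2.5 * np.ones((3, 3))
        )

    def test_fa1_with_equal_params_is_cs(self):
        lam, psi = 1.7, 0.9
        fa = env_cov_matrix("fa1", [lam] * 4 + [psi] * 4, 4)
        cs = env_cov_matrix("cs", [lam**2, psi], 4)
        np.testing.assert_allclose(fa, cs)

    def test_cs_implied_correlation(self):
        corr = implied_env_correlations(env_cov_matrix("cs", [9.6, 0.4], 8))
        off = corr[np.triu_indices(8, 1)]
        np.testing.assert_allclose(off, 0.96)

    def test_fa1_zero_specifics_correlation_one(self):
        corr = implied_env_correlations(env_cov_matrix("fa1", [2, -1, 0, 0], 2))
        assert abs(corr[0, 1]) == pytest.approx(1.0)

    def test_negative_variance_rejected(self):
        with pytest.raises(StructureError):
            env_cov_matrix("cs", [1.0, -0.5], 2)

    def test_fa1_sign_convention(self):
        s = get_structure("fa1", 3)
        out = s.finalize(np.array([-1.0, -2.0, 1.0, 0.1, 0.1, 0.1]))
        assert out[0] >= 0
        np.testing.assert_allclose(s.cov(out), s.cov([-1, -2, 1, 0.1, 0.1, 0.1]))


class TestRemlLoglik:
    def test_closed_form_two_records(self):
        m = make_model([1.0, 2.0], ["a", "b"], [("L", "1")] * 2)
        ll = m.reml_loglik(np.array([[0.0]]), np.array([1.0]))
        assert ll == pytest.approx(-0.5 * (np.log(2 * np.pi) + np.log(2) + 0.5))

    def test_translation_invariance(self, small_model):
        Sigma = 5.0 * np.eye(small_model.n_env) + 3.0
        resid = np.full(small_model.n_env, 7.0)
        ll1 = small_model.reml_loglik(Sigma, resid)
        shifted = small_model.df.copy()
        shifted["y"] = shifted["y"] + 123.0
        m2 = GxEModel(shifted, small_model.grm, **MODEL_KW)
        assert m2.reml_loglik(Sigma, resid) == pytest.approx(ll1, abs=1e-8)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_error_contrast_oracle_on_tiny_instances(self, seed):
        """On random <=6-record instances the profiled REML formula equals
        the error-contrast restricted likelihood."""
        rng = np.random.default_rng(seed)
        n_ind = int(rng.integers(2, 5))
        n_env = int(rng.integers(1, 3))
        labels = [f"g{i}" for i in range(n_ind)]
        records = [
            (labels[i], ("L", str(e)))
            for i in range(n_ind)
            for e in range(n_env)
            if rng.random() < 0.8
        ][:6]
        if len(records) < 3 or len({r[1] for r in records}) < n_env:
            return
        G = rng.standard_normal((n_ind, n_ind))
        GA = G @ G.T / n_ind + np.eye(n_ind)
        y = rng.standard_normal(len(records)) * 3 + 10
        m = make_model(
            y, [r[0] for r in records], [r[1] for r in records],
            grm_values=GA, labels=labels,
        )
        lam = rng.uniform(0.2, 2, n_env)
        psi = rng.uniform(0.1, 1, n_env)
        Sigma = np.outer(lam, lam) + np.diag(psi)
        resid = rng.uniform(0.5, 2, m.n_env)
        V = m._build_V(Sigma, resid)
        expected = reml_loglik_error_contrast(m.y, m.exog, V)
        assert m.reml_loglik(Sigma, resid) == pytest.approx(expected, abs=1e-8)


class TestDesign:
    def test_planting_year_column_only_at_designated_location(self, small_model):
        py_cols = [n for n in small_model.exog_names if n.startswith("planting_year")]
        assert py_cols  # the factor exists at the designated location
        at_loc = small_model.location_of_record == "Balandran.FR"
        for name in py_cols:
            col = small_model.exog[:, small_model.exog_names.index(name)]
            assert not col[~at_loc].any()

    def test_full_column_rank(self, small_model):
        X = small_model.exog
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_every_record_maps_to_one_env(self, small_model):
        assert small_model.env_idx.min() >= 0
        assert small_model.env_idx.max() < small_model.n_env


class TestFit:
    def test_single_env_matches_anova_reml_oracle(self):
        """Balanced one-way design (2 replicate records per individual,
        identity GRM): AI-REML must match the closed-form ANOVA/REML
        estimates of the two variances."""
        rng = np.random.default_rng(42)
        n, r = 40, 2
        u = rng.normal(0, np.sqrt(4.0), n)
        y = 100 + u[:, None] + rng.normal(0, np.sqrt(2.0), (n, r))
        ids = [f"g{i}" for i in range(n) for _ in range(r)]
        envs = [("L", "1")] * (n * r)
        m = make_model(y.ravel(), ids, envs, labels=[f"g{i}" for i in range(n)])
        res = m.fit(structure="uniform", tol_logl=1e-10, tol_par=1e-8)
        vA, vR = anova_reml_oneway(y)
        assert res.converged
        assert res.params[0] == pytest.approx(vA, abs=1e-4 * max(vA, 1))
        assert res.params[1] == pytest.approx(vR, abs=1e-4 * max(vR, 1))

    def test_zero_genetic_signal_pins_variance_at_boundary(self):
        # replicated records, pure noise: between-individual mean square is
        # below the within mean square for this seed, so the REML estimate
        # of the genetic variance must sit on the zero boundary
        rng = np.random.default_rng(3)
        n, r = 50, 2
        y = 50 + rng.normal(0, 1.0, (n, r))
        vA_oracle, _ = anova_reml_oneway(y)
        assert vA_oracle == 0.0  # seed chosen to put the truth at the boundary
        ids = [f"g{i}" for i in range(n) for _ in range(r)]
        m = make_model(y.ravel(), ids, [("L", "1")] * (n * r),
                       labels=[f"g{i}" for i in range(n)])
        res = m.fit(structure="uniform")
        assert res.params[0] <= 0.01 * res.params[1]

    def test_nesting_loglik_ordering(self, fits):
        assert fits["uniform"].llf <= fits["cs"].llf + 1e-3
        assert fits["cs"].llf <= fits["fa1"].llf + 1e-3

    def test_fa1_on_cs_truth_not_worse(self, small_grm):
        from metgblup import SimConfig, simulate_study

        cfg = SimConfig(
            n_founders=80, n_families=14, offspring_per_family=5, m_loci=300,
            structure_kind="cs", structure_params=(45.0, 5.0),
        )
        study = simulate_study(cfg, seed=9)
        m = GxEModel(study.phenotypes, small_grm, **MODEL_KW)
        cs = m.fit(structure="cs")
        fa = m.fit(structure="fa1")
        assert fa.llf >= cs.llf - 1e-3


class TestMME:
    def test_mme_residual_identity(self, small_model, fits):
        """Plugging (b-hat, u-hat) back into Henderson's equations must
        reproduce the right-hand side."""
        res = fits["fa1"]
        m = small_model
        Sigma = res.env_cov
        R = m._build_R(res.resid_params)
        Rinv = np.diag(1.0 / np.diag(R))
        nG, nE = m.n_ind, m.n_env
        Z = np.zeros((m.nobs, nE * nG))
        Z[np.arange(m.nobs), m.env_idx * nG + m.ind_idx] = 1.0
        X = m.exog
        b = res.blues.to_numpy()
        u = res.blups.to_numpy().T.ravel()  # environment-major
        # G^-1 u = Z' V^-1 (y - X b) for the MME solution, so the equations
        # can be verified without inverting the (possibly singular) G
        V = m._build_V(Sigma, res.resid_params)
        Ginv_u = Z.T @ np.linalg.solve(V, m.y - X @ b)
        lhs_top = X.T @ Rinv @ (X @ b + Z @ u)
        lhs_bot = Z.T @ Rinv @ (X @ b + Z @ u) + Ginv_u
        rhs_top = X.T @ Rinv @ m.y
        rhs_bot = Z.T @ Rinv @ m.y
        scale = max(np.abs(rhs_top).max(), np.abs(rhs_bot).max())
        np.testing.assert_allclose(lhs_top, rhs_top, atol=1e-6 * scale)
        np.testing.assert_allclose(lhs_bot, rhs_bot, atol=1e-6 * scale)

    def test_zero_genetic_variance_shrinks_blups_to_zero(self):
        y = [10.0, 12.0, 11.0, 13.0]
        m = make_model(y, ["a", "b", "c", "d"], [("L", "1")] * 4)
        _, _, blups, _ = m.solve_mme(np.array([[0.0]]), np.array([1.0]))
        np.testing.assert_allclose(blups.to_numpy(), 0.0, atol=1e-6)

    def test_single_env_identity_blup_closed_form(self):
        """With G_A = I, one record each and known variances, the BLUP is
        the shrunken deviation h2 * (y_i - GLS mean)."""
        rng = np.random.default_rng(3)
        n, s2a, s2r = 30, 3.0, 1.0
        y = 20 + rng.normal(0, 2, n)
        ids = [f"g{i}" for i in range(n)]
        m = make_model(y, ids, [("L", "1")] * n)
        blues, _, blups, _ = m.solve_mme(np.array([[s2a]]), np.array([s2r]))
        expected = s2a / (s2a + s2r) * (y - blues[0])
        got = blups.loc[ids].to_numpy().ravel()
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_unobserved_individual_predicted_through_correlations(self):
        # 'b' has no record anywhere but is related to 'a'; 'c' and 'd' are
        # unrelated fillers that keep the environment means estimable
        GA = np.eye(4)
        GA[0, 1] = GA[1, 0] = 0.8
        y = [5.0, 1.0, 6.0, 2.0, 4.0, 3.0]
        ids = ["a", "c", "a", "c", "a", "d"]
        envs = [("L", "1"), ("L", "1"), ("L", "2"), ("L", "2"),
                ("M", "1"), ("M", "1")]
        m = make_model(y, ids, envs, grm_values=GA, labels=["a", "b", "c", "d"])
        Sigma = 2.0 * np.ones((3, 3)) + 0.5 * np.eye(3)
        _, _, blups, _ = m.solve_mme(Sigma, np.ones(3))
        assert np.all(np.abs(blups.loc["b"].to_numpy()) > 1e-8)

    def test_pev_available_on_request(self, small_model, fits):
        res = fits["uniform"]
        *_, pev = small_model.solve_mme(res.env_cov, res.resid_params, pev=True)
        assert pev is not None and np.all(pev > 0)


class TestLRT:
    def test_equal_loglik_gives_p_one(self):
        r = lrt(-100.0, -100.0, df=1)
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_reported_cs_vs_uniform_values(self):
        # restricted logL -2560.7 (no AxE) vs -2554.2 (A + AxE), df = 1
        r = lrt(-2560.7, -2554.2, df=1)
        assert r.statistic == pytest.approx(13.0, abs=1e-9)
        assert r.pvalue == pytest.approx(stats.chi2.sf(13.0, 1), rel=1e-12)
        assert r.pvalue < 0.001

    def test_reported_fa1_vs_cs_values(self):
        # df = 2 nE - 2 = 14 loadings/specifics replacing the 2 cs params
        r = lrt(-2554.2, -2519.2, df=14)
        assert r.statistic == pytest.approx(70.0, abs=1e-9)
        assert r.pvalue < 0.001

    def test_negative_statistic_clipped_with_warning(self):
        r = lrt(-10.0, -11.0, df=1)
        assert r.statistic == 0.0 and r.pvalue == 1.0 and r.warning


class TestLsmeans:
    def _fit_two_env(self, delta, noise_seed=0):
        rng = np.random.default_rng(noise_seed)
        n = 30
        ids = [f"g{i}" for i in range(n)]
        y1 = 100 + rng.normal(0, 1, n)
        y2 = 100 + delta + rng.normal(0, 1, n)
        m = make_model(
            np.concatenate([y1, y2]), ids * 2,
            [("L", "1")] * n + [("L", "2")] * n,
            labels=ids,
        )
        return m.fit(structure="cs")

    def test_identical_means_share_letter(self):
        ls = self._fit_two_env(0.0).lsmeans()
        assert ls["letters"].iloc[0] == ls["letters"].iloc[1]

    def test_large_difference_gets_distinct_letters(self):
        ls = self._fit_two_env(10.0).lsmeans()
        assert set(ls["letters"].iloc[0]) & set(ls["letters"].iloc[1]) == set()

    def test_letters_invariant_to_environment_ordering(self, fits):
        ls = fits["fa1"].lsmeans()
        # recompute from a row-shuffled phenotype table
        m = fits["fa1"].model
        shuffled = m.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m2 = GxEModel(shuffled, m.grm, **MODEL_KW)
        ls2 = m2.fit(structure="fa1").lsmeans()
        merged = ls.merge(ls2, on=["location", "season"], suffixes=("_a", "_b"))
        assert (merged["letters_a"] == merged["letters_b"]).all()

    def test_summary_renders(self, fits):
        text = fits["fa1"].summary()
        assert "Restricted logL" in text and "fa1" in text
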