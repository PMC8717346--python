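import numpy as np
import pandas as pd
import pytest

from songspace.mixedmodel import (CHAIN_PRESETS, ChainSpec, GibbsMixedModel,
                                  PriorSpec, RandomEffect, autocorr,
                                  design_matrix, diagnostics, dredge_by_dic,
                                  ess_ips, pmcmc, scale_covariates)


class TestPmcmc:
    def test_symmetric_samples_near_one(self, rng):
        assert pmcmc(rng.normal(size=10_000)) > 0.9

    def test_all_positive_floor(self):
        assert pmcmc(np.abs(np.random.default_rng(0).normal(size=1000)) + 0.1
                     ) == pytest.approx(1 / 1000)

    def test_exact_tail_arithmetic(self):
        s = np.concatenate([np.full(25, -1.0), np.full(975, 1.0)])
        assert pmcmc(s) == pytest.approx(0.05)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            assert pmcmc(np.zeros(200)) == 1.0


class TestDiagnostics:
    def test_iid_chain_low_autocorr_full_ess(self, rng):
        x = rng.normal(size=5000)
        assert abs(autocorr(x, 1)) < 0.05
        assert 0.85 * 5000 < ess_ips(x) <= 5000

    def test_ar1_chain_flagged(self, rng):
        n, phi = 20_000, 0.9
        x = np.empty(n)
        x[0] = 0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        assert autocorr(x, 1) == pytest.approx(phi, abs=0.05)
        assert ess_ips(x) < n / 5

    def test_ess_bounded_by_n(self, rng):
        for _ in range(5):
            x = rng.normal(size=500)
            assert ess_ips(x) <= 500


class TestGibbsSampler:
    def test_fixed_effects_match_ols(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        beta = np.array([1.0, 2.0, -0.5])
        y = X @ beta + rng.normal(size=n)
        m = GibbsMixedModel(PriorSpec(), ChainSpec(4000, 500, 2, seed=1)
                            ).fit(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        post = m.summary_["posterior_mean"].to_numpy()
        mcse = (m.chain_.samples.std() / np.sqrt(
            m.chain_.ess[m.chain_.fixed_names])).to_numpy()
        se_ols = np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(post - ols) < 2 * (mcse + 0.2 * se_ols))

    def test_same_seed_bit_identical(self, rng):
        n = 100
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1, 0.5] + rng.normal(size=n)
        groups = np.repeat(np.arange(10), 10)
        re = lambda: [RandomEffect("g", groups)]
        m1 = GibbsMixedModel(PriorSpec(), ChainSpec(2000, 200, 2, seed=5)
                             ).fit(X, y, re())
        m2 = GibbsMixedModel(PriorSpec(), ChainSpec(2000, 200, 2, seed=5)
                             ).fit(X, y, re())
        assert m1.chain_.samples.equals(m2.chain_.samples)
        assert m1.dic_ == m2.dic_

    def test_aliased_columns_dropped_with_warning(self, rng):
        n = 80
        x = rng.normal(size=n)
        X = pd.DataFrame({"(Intercept)": 1.0, "x": x, "x2": 2 * x})
        with pytest.warns(UserWarning, match="aliased"):
            m = GibbsMixedModel(PriorSpec(), ChainSpec(500, 100, 2, seed=0)
                                ).fit(X, x + rng.normal(size=n))
        assert m.chain_.dropped_columns == ["x2"]

    def test_nonfinite_response_rejected(self):
        with pytest.raises(ValueError):
            GibbsMixedModel().fit(np.ones((5, 1)),
                                  np.array([1, 2, np.nan, 4, 5.0]))

    def test_residual_variance_tracks_sample_variance(self, rng):
        n = 2000
        X = np.ones((n, 1))
        y = 3.0 + rng.normal(scale=1.5, size=n)
        m = GibbsMixedModel(PriorSpec(residual_nu=1e-4),
                            ChainSpec(3000, 500, 2, seed=2)).fit(X, y)
        post_var = m.chain_.posterior_mean["var_residual"]
        assert post_var == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_phylo_random_effect_recovers_structure(self, rng):
        # species effects simulated with covariance s2*C; posterior variance
        # should concentrate near the truth
        from songspace.phylo import phylo_vcv
        from songspace.simulate import simulate_tree
        tree = simulate_tree(30, seed=8)
        vcv = phylo_vcv(tree)
        L = np.linalg.cholesky(vcv.C + 1e-10 * np.eye(30))
        s2_true = 2.0
        covered = 0
        for rep in range(10):
            u = np.sqrt(s2_true) * (L @ rng.normal(size=30))
            groups = np.repeat(vcv.species, 20)
            y = u.repeat(20) + rng.normal(size=600)
            X = np.ones((600, 1))
            re = [RandomEffect("sp", groups, cov=vcv.C,
                               cov_levels=vcv.species)]
            m = GibbsMixedModel(PriorSpec(), ChainSpec(1500, 300, 2, seed=rep)
                                ).fit(X, y, re)
            lo = m.chain_.ci_lower["var_sp"]
            hi = m.chain_.ci_upper["var_sp"]
            covered += int(lo <= s2_true <= hi)
        assert covered >= 8


class TestDic:
    def test_identical_model_identical_dic(self, rng):
        n = 100
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [0.5, 1.0] + rng.normal(size=n)
        d1 = GibbsMixedModel(PriorSpec(), ChainSpec(1000, 200, 2, seed=3)
                             ).fit(X, y).dic_
        d2 = GibbsMixedModel(PriorSpec(), ChainSpec(1000, 200, 2, seed=3)
                             ).fit(X, y).dic_
        assert d1 == d2

    def test_strong_covariate_lowers_dic(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = 3.0 * x + rng.normal(size=n)
        X0 = np.ones((n, 1))
        X1 = np.column_stack([np.ones(n), x])
        hits = 0
        for s in range(5):
            d0 = GibbsMixedModel(PriorSpec(), ChainSpec(1200, 200, 2, seed=s)
                                 ).fit(X0, y).dic_
            d1 = GibbsMixedModel(PriorSpec(), ChainSpec(1200, 200, 2, seed=s)
                                 ).fit(X1, y).dic_
            hits += int(d0 - d1 > 10)
        assert hits == 5

    def test_parsimony_under_null(self, rng):
        # data generated without the extra covariate: the smaller model
        # should not lose by much
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            r = np.random.default_rng(1000 + s)
            n = 200
            y = 1.0 + r.normal(size=n)
            x = r.normal(size=n)
            d0 = GibbsMixedModel(PriorSpec(), ChainSpec(800, 150, 2, seed=s)
                                 ).fit(np.ones((n, 1)), y).dic_
            d1 = GibbsMixedModel(PriorSpec(), ChainSpec(800, 150, 2, seed=s)
                                 ).fit(np.column_stack([np.ones(n), x]), y).dic_
            wins += int(d0 <= d1 + 2)
        assert wins >= 0.8 * n_rep


class TestDesignAndDredge:
    def test_design_matrix_treatment_coding(self):
        df = pd.DataFrame({"sex": ["male", "female", "male"],
                           "x": [1.0, 2.0, 3.0]})
        X = design_matrix(df, ["sex", "x", "x:sex"])
        assert list(X.columns) == ["(Intercept)", "sex[male]", "x",
                                   "x:sex[male]"]
        assert X["sex[male]"].tolist() == [1.0, 0.0, 1.0]
        assert X["x:sex[male]"].tolist() == [1.0, 0.0, 3.0]

    def test_scale_covariates_fills_missing_with_mean(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0]})
        out = scale_covariates(df, ["a"])
        assert out["a"].iloc[2] == 0.0
        assert out["a"].abs().max() < 3

    def test_single_candidate_two_models(self, rng):
        n = 60
        df = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)})
        table = dredge_by_dic(df, "y", ["x"],
                              chain=ChainSpec(600, 100, 2, seed=1))
        assert len(table) == 2
        assert table["best"].sum() == 1

    def test_planted_covariate_selected(self, rng):
        hits = 0
        for s in range(8):
            r = np.random.default_rng(200 + s)
            n = 150
            df = pd.DataFrame({f"x{i}": r.normal(size=n) for i in range(3)})
            df["y"] = 1.5 * df["x0"] + r.normal(size=n)
            table = dredge_by_dic(df, "y", ["x0", "x1", "x2"],
                                  chain=ChainSpec(600, 100, 2, seed=s))
            best = table[table["best"]].iloc[0]["terms"]
            hits += int("x0" in best)
        assert hits >= 7

    def test_combinatorial_guard(self, rng):
        df = pd.DataFrame({f"x{i}": rng.normal(size=10) for i in range(14)})
        df["y"] = rng.normal(size=10)
        with pytest.raises(ValueError, match="refusing"):
            dredge_by_dic(df, "y", [f"x{i}" for i in range(14)])
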