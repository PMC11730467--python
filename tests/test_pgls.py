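"""PGLS likelihood machinery, VIF screening, candidate sets, averaging."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import coashift
from coashift import PGLS, brownian_correlation, simulate_tree
from coashift.pgls import (
    PGLSResults,
    RankError,
    build_design,
    candidate_designs,
    model_average,
    vif,
    vif_filter,
)
from coashift.simulate import _brownian_on_tree


def _design(df, numeric):
    X, blocks = build_design(df, numeric, {})
    return X, blocks


class TestPGLSFit:
    def test_star_tree_zero_se_equals_ols(self, rng):
        n = 40
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = 1.0 + 2.0 * df.x1 - 0.5 * df.x2 + rng.normal(0, 1, n)
        X, _ = _design(df, ["x1", "x2"])
        res = PGLS(y, X, np.eye(n)).fit()
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ols.params.to_numpy(),
                                   atol=1e-8)

    def test_identity_corr_constant_se_equals_weighted_ols(self, rng):
        # V proportional to I: coefficients equal the OLS closed form
        n = 30
        df = pd.DataFrame({"x": rng.normal(size=n)})
        y = 0.5 + 1.5 * df.x + rng.normal(0, 1, n)
        X, _ = _design(df, ["x"])
        res = PGLS(y, X, np.eye(n), se_y=np.full(n, 2.0)).fit()
        A = X.to_numpy()
        beta = np.linalg.solve(A.T @ A, A.T @ y.to_numpy())
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)

    def test_aicc_closed_form_and_aic_limit(self, rng):
        n = 50
        df = pd.DataFrame({"x": rng.normal(size=n)})
        y = df.x + rng.normal(0, 1, n)
        X, _ = _design(df, ["x"])
        res = PGLS(y, X, np.eye(n)).fit()
        k = res.k
        assert res.aicc == pytest.approx(
            -2 * res.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1), rel=1e-12)
        # AICc -> AIC as n -> infinity
        big = PGLSResults(params=res.params, bse=res.bse, sigma2=1.0, llf=res.llf,
                          nobs=10**6 * k, k=k, cov_params=res.cov_params)
        assert abs(big.aicc - big.aic) < 1e-3

    def test_huge_se_removes_leverage(self, rng):
        tree = simulate_tree(25, seed=3)
        C = brownian_correlation(tree).to_numpy()
        n = 25
        df = pd.DataFrame({"x": rng.normal(size=n)})
        y = 2.0 * df.x + rng.multivariate_normal(np.zeros(n), C)
        se = np.full(n, 0.5)
        se[7] = 1e5
        X, _ = _design(df, ["x"])
        full = PGLS(y, X, C, se_y=se).fit()
        keep = np.arange(n) != 7
        sub = PGLS(y[keep], X.iloc[keep], C[np.ix_(keep, keep)], se_y=se[keep]).fit()
        np.testing.assert_allclose(full.params.to_numpy(), sub.params.to_numpy(),
                                   atol=1e-3)

    def test_rank_deficient_design_rejected(self, rng):
        n = 20
        x = rng.normal(size=n)
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x, "x2": 2 * x})
        with pytest.raises(RankError):
            PGLS(rng.normal(size=n), X, np.eye(n))

    def test_brownian_recovery_small_calibration(self, rng):
        """Planted slope recovered without bias, CI coverage near nominal."""
        beta = 2.0
        hits, ests = 0, []
        for rep in range(120):
            tree = simulate_tree(40, seed=rep)
            C = brownian_correlation(tree).to_numpy()
            x = rng.normal(size=40)
            se = np.full(40, 0.5)
            resid = rng.multivariate_normal(np.zeros(40), C + np.diag(se**2))
            y = 1.0 + beta * x + resid
            X = pd.DataFrame({"Intercept": np.ones(40), "x": x})
            res = PGLS(y, X, C, se_y=se).fit()
            ests.append(res.params["x"])
            ci = res.conf_int().loc["x"]
            hits += ci["lower"] <= beta <= ci["upper"]
        assert np.mean(ests) == pytest.approx(beta, rel=0.05)
        assert 0.88 <= hits / 120 <= 0.99


class TestBrownianCorrelation:
    def test_star_tree_identity(self):
        import dendropy
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
        C = brownian_correlation(tree)
        np.testing.assert_allclose(C.to_numpy(), np.eye(4), atol=1e-12)

    def test_sister_pair_shared_depth(self):
        import dendropy
        tree = dendropy.Tree.get(data="((A:0.5,B:0.5):0.5,C:1);", schema="newick")
        C = brownian_correlation(tree)
        assert C.loc["A", "B"] == pytest.approx(0.5)
        assert C.loc["A", "C"] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_matches_brute_force_mrca_traversal(self):
        tree = simulate_tree(20, seed=11)
        C = brownian_correlation(tree)
        t = tree.clone(depth=1)
        t.calc_node_root_distances()
        # brute force: for each pair, walk ancestors to find the MRCA depth
        anc = {}
        for lf in t.leaf_node_iter():
            chain = []
            node = lf
            while node is not None:
                chain.append(node)
                node = node.parent_node
            anc[lf.taxon.label] = chain
        labels = list(C.index)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                mrca = next(n for n in anc[a] if n in anc[b])
                assert C.loc[a, b] == pytest.approx(mrca.root_distance or 0.0,
                                                    abs=1e-9)


class TestVIF:
    def test_orthogonal_columns_unit_vif(self):
        n = 64
        h = np.tile([1.0, -1.0], n // 2)
        X = pd.DataFrame({"Intercept": np.ones(n), "a": h,
                          "b": np.repeat([1.0, -1.0], n // 2)})
        v = vif(X)
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-10)
        Xr, _, log = vif_filter(X, {"a": ["a"], "b": ["b"]})
        assert log == [] and list(Xr.columns) == list(X.columns)

    def test_duplicated_column_removed_reverse_order(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"Intercept": np.ones(30), "a": x, "b": rng.normal(size=30),
                          "a_copy": x})
        Xr, blocks, log = vif_filter(X, {"a": ["a"], "b": ["b"], "a_copy": ["a_copy"]})
        assert [e["removed"] for e in log] == ["a_copy"]
        assert "a" in Xr.columns

    def test_matches_brute_force_r_squared(self, rng):
        n = 200
        z = rng.normal(size=n)
        X = pd.DataFrame({
            "Intercept": np.ones(n),
            "a": z + 0.3 * rng.normal(size=n),
            "b": z + 0.3 * rng.normal(size=n),
            "c": z + 0.3 * rng.normal(size=n),
        })
        v = vif(X)
        for col in ("a", "b", "c"):
            others = [c for c in ("a", "b", "c") if c != col]
            r2 = sm.OLS(X[col], sm.add_constant(X[others])).fit().rsquared
            assert v[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)


class TestCandidates:
    def test_three_predictors_eight_subsets(self, rng):
        n = 200
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        X, blocks = _design(df, ["a", "b", "c"])
        cands = candidate_designs(X, blocks, n)
        assert len(cands) == 8
        assert any(sub == () for sub, _ in cands)  # intercept-only

    def test_samples_per_variable_exclusion(self, rng):
        n = 25
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        X, blocks = _design(df, ["a", "b", "c"])
        cands = candidate_designs(X, blocks, n, min_samples_per_variable=10)
        sizes = {len(sub) for sub, _ in cands}
        assert 3 not in sizes  # 25/3 < 10
        assert {0, 1, 2} <= sizes

    def test_factor_block_never_split(self, rng):
        n = 300
        df = pd.DataFrame({
            "x": rng.normal(size=n),
            "f": rng.choice(["solo", "small", "large"], size=n),
        })
        X, blocks = build_design(df, ["x"], {"f": "solo"})
        assert len(blocks["f"]) == 2
        for sub, Xc in candidate_designs(X, blocks, n):
            dummies = [c for c in Xc.columns if c.startswith("f[")]
            assert len(dummies) in (0, 2)


class TestModelAverage:
    @staticmethod
    def _fake_fit(terms, params, ses, aicc):
        # back out an llf that produces the requested AICc with k = len(params)+1
        k = len(params) + 1
        n = 1000
        llf = -(aicc - 2 * k - 2 * k * (k + 1) / (n - k - 1)) / 2
        s = pd.Series(params, index=terms)
        return PGLSResults(params=s, bse=pd.Series(ses, index=terms), sigma2=1.0,
                           llf=llf, nobs=n, k=k,
                           cov_params=pd.DataFrame(np.diag(np.array(ses) ** 2),
                                                   index=terms, columns=terms))

    def test_single_model_degenerate_average(self):
        fit = self._fake_fit(["Intercept", "x"], [1.0, 2.0], [0.1, 0.2], 100.0)
        avg = model_average([(("x",), fit)])
        got = avg.coefficients.set_index("term")
        assert got.loc["x", "estimate"] == pytest.approx(2.0)
        assert got.loc["x", "se"] == pytest.approx(0.2)

    def test_equal_aicc_half_weights(self):
        f1 = self._fake_fit(["Intercept", "x"], [0.0, 1.0], [0.1, 0.1], 50.0)
        f2 = self._fake_fit(["Intercept", "y"], [0.0, 3.0], [0.1, 0.1], 50.0)
        avg = model_average([(("x",), f1), (("y",), f2)])
        w = avg.candidates["weight"].to_numpy()
        np.testing.assert_allclose(w, [0.5, 0.5])
        got = avg.coefficients.set_index("term")
        # full averaging zero-substitutes the absent term
        assert got.loc["x", "estimate"] == pytest.approx(0.5)
        assert got.loc["y", "estimate"] == pytest.approx(1.5)

    def test_delta_013_hand_weights(self):
        fits = [
            (("a",), self._fake_fit(["Intercept", "a"], [0, 1.0], [0.1, 0.1], 10.0)),
            (("b",), self._fake_fit(["Intercept", "b"], [0, 1.0], [0.1, 0.1], 11.0)),
            (("c",), self._fake_fit(["Intercept", "c"], [0, 1.0], [0.1, 0.1], 13.0)),
        ]
        avg = model_average(fits, window=2.0)
        assert avg.retained == 2
        w0 = 1.0 / (1.0 + math.exp(-0.5))
        np.testing.assert_allclose(
            avg.candidates["weight"].to_numpy()[:2], [w0, 1.0 - w0], rtol=1e-12)
        assert avg.candidates["weight"].iloc[2] == 0.0

    def test_revised_unconditional_se_hand_computed(self):
        f1 = self._fake_fit(["Intercept", "x"], [0.0, 2.0], [0.1, 0.3], 50.0)
        f2 = self._fake_fit(["Intercept", "x"], [0.0, 1.0], [0.1, 0.4], 50.0)
        avg = model_average([(("x",), f1), (("x", "z"), f2)])
        est = 0.5 * 2.0 + 0.5 * 1.0
        se = 0.5 * math.sqrt(0.3**2 + (2.0 - est) ** 2) + 0.5 * math.sqrt(
            0.4**2 + (1.0 - est) ** 2)
        got = avg.coefficients.set_index("term").loc["x"]
        assert got["estimate"] == pytest.approx(est)
        assert got["se"] == pytest.approx(se)


class TestTraitModelDriver:
    def test_planted_effect_recovered_with_averaging(self):
        rng = np.random.default_rng(99)
        sc = coashift.SimScenario(n_species=81, seed=99)
        tree = simulate_tree(81, 99)
        traits, truth = coashift.simulate_traits(tree, sc, seed=99)
        from coashift.traits import NUMERIC_PREDICTORS, zscore_columns
        traits, _ = zscore_columns(traits, NUMERIC_PREDICTORS)
        C = brownian_correlation(tree, order=traits["species"].tolist())
        avg = coashift.fit_trait_models(traits, C, "B")
        got = avg.coefficients.set_index("term")
        est = got.loc["flocking_behaviour[mixed_age_flocks]", "estimate"]
        se = got.loc["flocking_behaviour[mixed_age_flocks]", "se"]
        assert abs(est - truth["flocking_effects"]["mixed_age_flocks"]) < 2.5 * se
        assert got.loc["flocking_behaviour[mixed_age_flocks]", "significant"]
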