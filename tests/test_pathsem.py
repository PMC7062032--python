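"""Path analysis: ML/OLS equivalence, fit indices, elimination, modification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from palmvision.pathsem import (
    FitGates,
    PathModel,
    backward_eliminate,
    rmsea_confidence_interval,
)


def _random_recursive_instance(rng, n_vars, n_obs):
    """Random recursive DAG + data; returns (edges, DataFrame)."""
    names = [f"v{i}" for i in range(n_vars)]
    edges = []
    for j in range(1, n_vars):
        parents = [i for i in range(j) if rng.random() < 0.6]
        for i in parents:
            edges.append((names[i], names[j]))
    X = np.zeros((n_obs, n_vars))
    X[:, 0] = rng.standard_normal(n_obs)
    for j in range(1, n_vars):
        pa = [i for i in range(j) if (names[i], names[j]) in edges]
        X[:, j] = rng.standard_normal(n_obs)
        for i in pa:
            X[:, j] += rng.normal(0.5, 0.3) * X[:, i]
    return edges, pd.DataFrame(X, columns=names)


def _ols(y, X):
    X1 = np.column_stack([np.ones(len(y)), X])
    return np.linalg.lstsq(X1, y, rcond=None)[0][1:]


class TestMLEqualsOLS:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_recursive_models(self, seed):
        rng = np.random.default_rng(seed)
        n_vars = int(rng.integers(3, 7))
        edges, data = _random_recursive_instance(rng, n_vars, 200)
        if not edges:
            edges = [(data.columns[0], data.columns[1])]
        res = PathModel(edges, data=data,
                        extra_variables=list(data.columns)).fit()
        paths = res.paths
        for effect in paths.effect.unique():
            causes = list(paths[paths.effect == effect].cause)
            b_ols = _ols(data[effect].to_numpy(), data[causes].to_numpy())
            b_ml = [float(paths[(paths.effect == effect)
                                & (paths.cause == c)].estimate.iloc[0])
                    for c in causes]
            np.testing.assert_allclose(b_ml, b_ols, atol=1e-6)

    def test_saturated_chi_square_zero(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        res = PathModel([("a", "c"), ("b", "c"), ("a", "b")], data=data).fit()
        assert res.df == 0
        assert res.chisq == pytest.approx(0.0, abs=1e-8)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        data = pd.DataFrame({"x1": x, "x2": 2 * x,
                             "y": x + rng.standard_normal(50)})
        with pytest.raises(ValueError, match="singular"):
            PathModel([("x1", "y"), ("x2", "y")], data=data)


class TestInvariance:
    def test_chi_square_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.standard_normal((150, 4)),
                            columns=list("wxyz"))
        data["y"] += 0.5 * data["x"]
        edges = [("x", "y"), ("w", "y")]
        r1 = PathModel(edges, data=data, extra_variables=["z"]).fit()
        scaled = data.copy()
        scaled["x"] = scaled["x"] * 7.0 + 3.0
        scaled["y"] = scaled["y"] * 0.1 - 2.0
        r2 = PathModel(edges, data=scaled, extra_variables=["z"]).fit()
        assert r1.chisq == pytest.approx(r2.chisq, abs=1e-7)

    def test_standardized_coefficients_scale_invariant(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.standard_normal((200, 3)),
                            columns=list("abc"))
        data["c"] += 0.6 * data["a"]
        edges = [("a", "c"), ("b", "c")]
        s1 = PathModel(edges, data=data).fit(refine=False).standardized_paths()
        data2 = data.copy()
        data2["a"] *= 13.0
        s2 = PathModel(edges, data=data2).fit(refine=False).standardized_paths()
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], abs=1e-8)

    def test_standardize_arithmetic(self):
        # b = 2, sd(cause) = 1, sd(effect) ~ 2 -> standardized ~ 1.0
        # (a tiny residual variance keeps the covariance nonsingular)
        cov = pd.DataFrame([[1.0, 2.0], [2.0, 4.0 + 1e-6]],
                           index=["x", "y"], columns=["x", "y"])
        res = PathModel([("x", "y")], cov=cov, nobs=100).fit(refine=False)
        assert res.standardized_paths()[("x", "y")] == pytest.approx(1.0,
                                                                     abs=1e-6)

    def test_chisq_never_decreases_when_path_removed(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.standard_normal((120, 4)),
                            columns=list("abcd"))
        data["d"] += 0.4 * data["a"] + 0.3 * data["b"]
        full = [("a", "d"), ("b", "d"), ("c", "d")]
        chi_full = PathModel(full, data=data).fit().chisq
        for drop in full:
            sub = [e for e in full if e != drop]
            chi_sub = PathModel(sub, data=data,
                                extra_variables=list("abcd")).fit().chisq
            assert chi_sub >= chi_full - 1e-9


class TestFitIndices:
    def test_null_chi_square_pvalues_uniform(self):
        """Independence model on truly independent data: p ~ Uniform(0,1)."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            data = pd.DataFrame(rng.standard_normal((500, 4)),
                                columns=list("abcd"))
            res = PathModel([], data=data,
                            extra_variables=list("abcd")).fit_independence()
            pvals.append(res.chisq_pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_saturated_model_indices(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        res = PathModel([("a", "c"), ("b", "c"), ("a", "b")], data=data).fit()
        ind = res.fit_indices()
        assert ind["cfi"] == 1.0
        assert ind["rmsea"] == 0.0 and ind["rmsea_undefined"]

    def test_rmsea_zero_when_chisq_equals_df(self):
        # formula check: max(chi2 - df, 0) = 0
        lo, hi = rmsea_confidence_interval(5.0, 5, 200)
        assert lo == 0.0

    def test_rmsea_ci_matches_bisection_oracle(self):
        chisq, df, n = 48.3, 20, 300
        lo, hi = rmsea_confidence_interval(chisq, df, n)

        def bisect(target):
            a, b = 0.0, 500.0
            for _ in range(200):
                m = 0.5 * (a + b)
                if stats.ncx2.cdf(chisq, df, m) > target:
                    a = m
                else:
                    b = m
            return np.sqrt(0.5 * (a + b) / (df * (n - 1)))

        assert lo == pytest.approx(bisect(0.95), abs=1e-6)
        assert hi == pytest.approx(bisect(0.05), abs=1e-6)
        assert lo <= np.sqrt(max(chisq - df, 0) / (df * (n - 1))) <= hi


class TestBackwardElimination:
    def test_all_significant_model_unchanged(self):
        rng = np.random.default_rng(7)
        n = 500
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        y = 0.8 * a + 0.8 * b + 0.3 * rng.standard_normal(n)
        data = pd.DataFrame({"a": a, "b": b, "y": y})
        model = PathModel([("a", "y"), ("b", "y")], data=data)
        res, log = backward_eliminate(model)
        assert log[-1]["final_paths"] == [("a", "y"), ("b", "y")]

    def test_true_zero_path_removed_first(self):
        removed_first = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 1000
            a = rng.standard_normal(n)
            c = rng.standard_normal(n)
            y = 0.5 * a + rng.standard_normal(n)
            data = pd.DataFrame({"a": a, "c": c, "y": y})
            model = PathModel([("a", "y"), ("c", "y")], data=data)
            _, log = backward_eliminate(model)
            if log[0].get("removed") == ("c", "y"):
                removed_first += 1
        assert removed_first >= 18

    def test_alpha_one_removes_nothing(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("aby"))
        model = PathModel([("a", "y"), ("b", "y")], data=data)
        res, log = backward_eliminate(model, alpha=1.0000001)
        assert len(log) == 1 and log[0]["final_paths"] == [("a", "y"), ("b", "y")]

    def test_gates_reported(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("aby"))
        data["y"] += 0.5 * data["a"]
        model = PathModel([("a", "y")], data=data, extra_variables=["b"])
        res, log = backward_eliminate(model, gates=FitGates())
        assert set(log[-1]["gates"]) == {"chisq_p_ok", "cfi_ok", "rmsea_ok"}


class TestModificationIndices:
    def test_freeing_saturating_edge_recovers_full_chisq(self):
        rng = np.random.default_rng(10)
        data = pd.DataFrame(rng.standard_normal((150, 3)),
                            columns=list("abc"))
        data["c"] += 0.5 * data["a"] + 0.5 * data["b"]
        res = PathModel([("a", "c"), ("a", "b")], data=data).fit()
        mi = res.modification_indices([("b", "c")])
        assert mi.delta_chisq.iloc[0] == pytest.approx(res.chisq, abs=1e-6)

    def test_cycle_candidate_rejected(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(rng.standard_normal((100, 3)),
                            columns=list("abc"))
        res = PathModel([("a", "b"), ("b", "c")], data=data).fit()
        with pytest.raises(ValueError, match="cycle"):
            res.modification_indices([("c", "a")])

    def test_null_delta_chisq_mean_near_one(self):
        """Freeing a truly-zero edge: delta chi2 ~ chi2(1)."""
        rng = np.random.default_rng(12)
        deltas = []
        for _ in range(150):
            data = pd.DataFrame(rng.standard_normal((300, 3)),
                                columns=list("aby"))
            data["y"] += 0.5 * data["a"]
            res = PathModel([("a", "y")], data=data,
                            extra_variables=["b"]).fit()
            deltas.append(res.modification_indices([("b", "y")])
                          .delta_chisq.iloc[0])
        assert np.mean(deltas) == pytest.approx(1.0, abs=0.35)


class TestFormulas:
    def test_parsing_and_summary(self):
        rng = np.random.default_rng(13)
        data = pd.DataFrame(rng.standard_normal((100, 3)),
                            columns=["y", "x1", "x2"])
        model = PathModel.from_formulas("y ~ x1 + x2\nx1 ~ x2", data)
        assert set(model.edges) == {("x1", "y"), ("x2", "y"), ("x2", "x1")}
        out = model.fit().summary()
        assert "CFI" in out and "RMSEA" in out

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModel.from_formulas("a ~ b\nb ~ a",
                                    pd.DataFrame({"a": [1.0, 2], "b": [3.0, 4]}))
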