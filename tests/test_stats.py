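import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonokit.stats import (
    KMeans1D,
    StepwiseOLS,
    assign_ggi_groups,
    cluster_1d,
    compare_groups,
    correlate_by_larynx,
    diagnostics,
    normality_screen,
    simple_linreg,
    stepwise_regression,
)


def _exhaustive_kmeans_sse(values, k):
    xs = np.sort(values)
    n = xs.size
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        sse = sum(
            float(((xs[a:b] - xs[a:b].mean()) ** 2).sum())
            for a, b in zip(bounds[:-1], bounds[1:])
        )
        best = min(best, sse)
    return best


class TestGGIGroups:
    @pytest.mark.parametrize(
        "value, group",
        [(0.0, 1), (0.005, 1), (0.01, 1), (0.011, 2), (0.399, 2), (0.4, 3), (1.0, 3)],
    )
    def test_interval_boundaries(self, value, group):
        assert assign_ggi_groups([value]).labels[0] == group

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_ggi_groups([1.2])


class TestKMeans1D:
    def test_spec_partition(self):
        ca = cluster_1d([0.0, 0.01, 0.02, 0.5, 0.51, 0.9, 0.95])
        np.testing.assert_array_equal(ca.labels, [1, 1, 1, 2, 2, 3, 3])

    def test_repeated_values_zero_inertia(self):
        x = np.repeat([0.1, 0.5, 0.9], 10)
        km = KMeans1D(3).fit(x)
        assert km.inertia_ == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.sort(km.cluster_centers_), [0.1, 0.5, 0.9])

    def test_matches_exhaustive_optimum_small_n(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            x = rng.uniform(0, 1, rng.integers(4, 13))
            if np.unique(x).size < 3:
                continue
            km = KMeans1D(3).fit(x)
            assert km.inertia_ == pytest.approx(_exhaustive_kmeans_sse(x, 3), abs=1e-9)

    def test_beats_lloyd_restarts(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(m, 0.05, 40) for m in (0.1, 0.5, 0.6)])
        dp = KMeans1D(3).fit(x)
        lloyd = KMeans(3, n_init=100, random_state=0).fit(x[:, None])
        assert dp.inertia_ <= lloyd.inertia_ + 1e-9

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            KMeans1D(3).fit([1.0, 1.0, 2.0])

    @given(st.lists(st.floats(0, 1), min_size=6, max_size=12))
    @settings(max_examples=30, deadline=None)
    def test_dp_optimality_property(self, values):
        x = np.asarray(values)
        if np.unique(x).size < 3:
            return
        km = KMeans1D(3).fit(x)
        assert km.inertia_ <= _exhaustive_kmeans_sse(x, 3) + 1e-9


class TestNormalityScreen:
    def test_detects_normal_and_uniform(self):
        rng = np.random.default_rng(0)
        assert normality_screen(rng.normal(0, 1, 1000))[2] is True
        assert normality_screen(rng.uniform(0, 1, 1000))[2] is False

    def test_constant_sample_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            stat, p, ok = normality_screen(np.full(20, 3.0))
        assert not ok


class TestGroupComparison:
    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(42)
        rejects = sum(
            compare_groups(rng.normal(0, 1, 90), np.repeat([1, 2, 3], 30)).kw_significant
            for _ in range(1000)
        )
        assert 0.03 <= rejects / 1000 <= 0.07

    def test_shifted_groups_all_significant(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30), rng.normal(6, 1, 30)])
        res = compare_groups(v, np.repeat([1, 2, 3], 30))
        assert res.kw_significant
        assert len(res.pairwise) == 3
        assert all(sig for _, _, sig in res.pairwise.values())

    def test_identical_constant_groups(self):
        res = compare_groups(np.ones(30), np.repeat([1, 2, 3], 10))
        assert res.kw_h == pytest.approx(0.0)
        assert not res.kw_significant and not res.pairwise

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.ones(10), np.repeat([1, 2], 5))


class TestCorrelation:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 60)
        y = 2 * x + 1
        lids = np.repeat(["L1", "L2", "L3"], 20)
        s = correlate_by_larynx(x, y, lids)
        assert s.mean_r == pytest.approx(1.0)
        assert s.sd_r == pytest.approx(0.0, abs=1e-12)

    def test_opposite_correlations_hand_computed(self):
        x = np.tile(np.arange(5.0), 2)
        y = np.concatenate([np.arange(5.0), -np.arange(5.0)])
        lids = np.repeat(["L1", "L2"], 5)
        s = correlate_by_larynx(x, y, lids)
        assert s.mean_r == pytest.approx(0.0, abs=1e-12)
        # sample sd of {+1, -1} is sqrt(2)
        assert s.sd_r == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert (s.min_r, s.max_r) == (-1.0, 1.0)

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(5)
        rho = 0.7
        xs, ys, lids = [], [], []
        for i in range(9):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=50)
            xs.append(z[:, 0])
            ys.append(z[:, 1])
            lids += [f"L{i+1}"] * 50
        s = correlate_by_larynx(np.concatenate(xs), np.concatenate(ys), lids)
        assert s.mean_r == pytest.approx(rho, abs=0.1)

    def test_zero_variance_larynx_skipped(self):
        x = np.concatenate([np.ones(5), np.arange(5.0)])
        y = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero variance"):
            s = correlate_by_larynx(x, y, np.repeat(["L1", "L2"], 5))
        assert list(s.per_larynx_r) == ["L2"]


class TestSimpleRegression:
    def test_exact_coefficient_recovery(self):
        # generating line y = 0.98 x + 1.94 recovered exactly, R^2 = 1
        x = np.linspace(1, 20, 50)
        y = 0.98 * x + 1.94
        r = simple_linreg(x, y)
        assert r.slope == pytest.approx(0.98, abs=1e-12)
        assert r.intercept == pytest.approx(1.94, abs=1e-12)
        assert r.r2 == pytest.approx(1.0, abs=1e-12)
        assert r.df == (1, 48)

    def test_independent_noise_low_r2(self):
        rng = np.random.default_rng(8)
        r = simple_linreg(rng.normal(size=400), rng.normal(size=400))
        assert r.r2 < 0.02

    def test_two_points_need_not_apply(self):
        with pytest.raises(ValueError):
            simple_linreg([1.0, 2.0], [1.0, 2.0])

    def test_three_points_perfect_fit(self):
        r = simple_linreg([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert r.r2 == pytest.approx(1.0)


class TestStepwise:
    def _candidates(self, rng, n=400, k=6):
        return pd.DataFrame({f"x{i+1}": rng.normal(size=n) for i in range(k)})

    def test_selects_true_predictors_only(self):
        rng = np.random.default_rng(3)
        X = self._candidates(rng)
        y = 2 * X.x1 + 3 * X.x2 + rng.normal(0, 0.5, len(X))
        res = stepwise_regression(y, X)
        assert set(res.selected) == {"x1", "x2"}
        assert res.steps[0].variable == "x2"  # stronger signal enters first

    def test_pure_noise_mostly_empty(self):
        # with 2 candidates at alpha 0.05 the no-entry probability is ~0.95^2
        rng = np.random.default_rng(4)
        empty = 0
        reps = 200
        for _ in range(reps):
            X = self._candidates(rng, n=100, k=2)
            res = stepwise_regression(rng.normal(size=100), X, with_diagnostics=False)
            empty += not res.selected
        assert empty / reps >= 0.90

    def test_single_perfect_candidate(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=50)
        res = stepwise_regression(y, pd.DataFrame({"x1": y}))
        assert res.selected == ["x1"]
        assert res.adj_r2 == pytest.approx(1.0)

    def test_categorical_block_in_and_out_together(self):
        rng = np.random.default_rng(6)
        n = 180
        lid = np.repeat([f"L{i+1}" for i in range(9)], n // 9)
        effects = dict(zip([f"L{i+1}" for i in range(9)], rng.normal(0, 2, 9)))
        X = pd.DataFrame({"x1": rng.normal(size=n), "lid": lid})
        y = np.array([effects[l] for l in lid]) + rng.normal(0, 0.5, n)
        res = stepwise_regression(y, X)
        assert "lid" in res.selected
        # indicator columns never appear as separate selections
        assert all(v in ("x1", "lid") for v in res.selected)

    def test_delta_adj_r2_telescopes(self):
        rng = np.random.default_rng(7)
        X = self._candidates(rng)
        y = 2 * X.x1 + 1.5 * X.x3 + rng.normal(0, 1.0, len(X))
        res = stepwise_regression(y, X)
        total = sum(s.delta_adj_r2 for s in res.steps)
        assert total == pytest.approx(res.steps[-1].adj_r2, abs=1e-9)

    def test_collinear_candidate_skipped(self):
        rng = np.random.default_rng(8)
        X = self._candidates(rng, k=3)
        X["dup"] = X["x1"]
        y = 2 * X.x1 + rng.normal(0, 0.3, len(X))
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_regression(y, X, with_diagnostics=False)
        # exactly one of the identical twins is selected, never both
        assert len({"x1", "dup"} & set(res.selected)) == 1

    def test_simultaneous_entry_confirms_selection(self):
        # refitting the final model with all selected variables at once
        # reproduces the same significance pattern
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        X = self._candidates(rng)
        y = 2 * X.x1 + 3 * X.x2 + 0.8 * X.x4 + rng.normal(0, 0.5, len(X))
        est = StepwiseOLS().fit(X, y)
        refit = sm.OLS(y, sm.add_constant(X[est.selected_])).fit()
        stepwise_sig = {v: est.final_pvalues_[v] < 0.05 for v in est.selected_}
        refit_sig = {v: refit.pvalues[v] < 0.05 for v in est.selected_}
        assert stepwise_sig == refit_sig

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        rng = np.random.default_rng(10)
        X = self._candidates(rng, n=100, k=3)
        y = X.x1.to_numpy() * 2 + rng.normal(0, 0.1, 100)
        est = clone(StepwiseOLS(p_enter=0.01))
        assert est.get_params()["p_enter"] == 0.01
        est.fit(X, y)
        pred = est.predict(X)
        assert np.corrcoef(pred, y)[0, 1] > 0.99


class TestDiagnostics:
    def test_collinearity_flagged_above_advisory(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x1 = rng.normal(size=200)
        X = pd.DataFrame({"x1": x1, "x2": 0.95 * x1 + 0.1 * rng.normal(size=200)})
        y = x1 + rng.normal(0, 0.5, 200)
        model = sm.OLS(y, sm.add_constant(X)).fit()
        rep = diagnostics(model, X)
        assert rep.max_abs_corr > 0.65 and rep.collinearity_flag

    def test_well_behaved_model_unflagged(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        X = pd.DataFrame({"x1": rng.normal(size=300), "x2": rng.normal(size=300)})
        y = X.x1 + X.x2 + rng.normal(0, 1.0, 300)
        model = sm.OLS(y, sm.add_constant(X)).fit()
        rep = diagnostics(model, X)
        assert not rep.collinearity_flag
        assert rep.resid_normal and rep.homoscedastic
        assert 1.5 < rep.durbin_watson < 2.5

    def test_duplicate_predictor_flag(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        x = rng.normal(size=100)
        X = pd.DataFrame({"x1": x, "x2": x.copy()})
        y = x + rng.normal(0, 0.2, 100)
        model = sm.OLS(y, sm.add_constant(X.x1)).fit()
        rep = diagnostics(model, X)
        assert rep.max_abs_corr == pytest.approx(1.0)
        assert rep.collinearity_flag
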