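"""Driver-model estimator: fit, OOB metrics, importance, p-values, PDPs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from grazedrivers import (
    ResidencyDriverForest,
    partial_dependence,
    rank_importance,
    subset_grazing_hours,
)


def make_signal_data(rng, n=5000, noise_sd=None):
    """Deterministic smooth target of one predictor plus small noise."""
    X = pd.DataFrame(rng.uniform(0, 1, (n, 5)), columns=list("abcde"))
    signal = np.sin(2 * np.pi * X["a"]) + 2 * X["a"] ** 2
    if noise_sd is None:
        noise_sd = 0.05 * signal.std()
    y = signal + rng.normal(0, noise_sd, n)
    return X, y.to_numpy()


class TestFit:
    def test_strong_signal_gives_high_oob_r2(self, rng):
        X, y = make_signal_data(rng)
        est = ResidencyDriverForest(n_trees=200, mtry=2, seed=0).fit(X, y)
        assert est.oob_r2_ >= 0.9

    def test_pure_noise_gives_low_oob_r2(self):
        scores = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(1500, 5)), columns=list("abcde"))
            y = r.normal(size=1500)
            est = ResidencyDriverForest(n_trees=100, mtry=2, seed=seed).fit(X, y)
            scores.append(est.oob_r2_)
        assert np.mean(scores) <= 0.1
        assert max(scores) <= 0.15

    def test_same_seed_identical_results(self, rng):
        X, y = make_signal_data(rng, n=1200)
        a = ResidencyDriverForest(n_trees=100, seed=7).fit(X, y)
        b = ResidencyDriverForest(n_trees=100, seed=7).fit(X, y)
        assert a.oob_r2_ == b.oob_r2_ and a.oob_mse_ == b.oob_mse_
        pd.testing.assert_series_equal(a.importances_, b.importances_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_constant_target_rejected(self, rng):
        X, _ = make_signal_data(rng, n=600)
        with pytest.raises(ValueError, match="constant target"):
            ResidencyDriverForest(n_trees=100).fit(X, np.ones(len(X)))

    def test_too_few_trees_rejected(self, rng):
        X, y = make_signal_data(rng, n=600)
        with pytest.raises(ValueError, match="at least 100"):
            ResidencyDriverForest(n_trees=50).fit(X, y)

    def test_calibration_validation_counts_partition_rows(self, rng):
        X, y = make_signal_data(rng, n=1500)
        est = ResidencyDriverForest(n_trees=100, seed=1).fit(X, y)
        assert est.n_calibration_ + est.n_validation_ == len(X)
        assert 0 < est.n_validation_ < len(X)

    def test_blocked_split_holds_out_whole_hours(self, rng):
        X, y = make_signal_data(rng, n=2400)
        hours = np.repeat(np.arange(24), 100)
        est = ResidencyDriverForest(n_trees=100, seed=2).fit(X, y, hours=hours)
        val_hours = set(hours[est._val_mask])
        cal_hours = set(hours[~est._val_mask])
        assert val_hours.isdisjoint(cal_hours)

    def test_sklearn_params_roundtrip(self):
        est = ResidencyDriverForest(n_trees=150, seed=3)
        params = est.get_params()
        clone = ResidencyDriverForest(**params)
        assert clone.get_params() == params

    def test_oob_r2_orderings_agree_with_correlation_fallback(self, rng):
        """1 - mse/var and squared-correlation R2 rank model quality the same way."""
        qualities = []
        for noise in (0.1, 0.5, 2.0):
            X, y = make_signal_data(rng, n=1500, noise_sd=noise)
            est = ResidencyDriverForest(n_trees=100, seed=4).fit(X, y)
            cal = ~est._val_mask
            oob = est.forest_.oob_prediction_
            r2_corr = np.corrcoef(oob, y[cal])[0, 1] ** 2
            qualities.append((est.oob_r2_, r2_corr))
        order_a = np.argsort([q[0] for q in qualities])
        order_b = np.argsort([q[1] for q in qualities])
        np.testing.assert_array_equal(order_a, order_b)


class TestImportanceSignificance:
    def test_signal_detected_and_noise_not(self, rng):
        X, y = make_signal_data(rng, n=2500)
        est = ResidencyDriverForest(n_trees=100, seed=5).fit(X, y)
        pv = est.importance_pvalues(X, y, n_perm=100)
        assert pv.loc["a", "p_value"] <= 0.01
        assert (pv.loc[list("bcde"), "p_value"] > 0.01).all()

    def test_table_wrapper_matches_method(self, ip_like_bundle):
        from grazedrivers import fit_rf, importance_significance

        tab = ip_like_bundle["table"].sample(3000, random_state=0).reset_index(drop=True)
        est, _ = fit_rf(pd.concat([tab]), n_trees=100, seed=3)
        pv = importance_significance(est, tab, n_perm=20, max_rows=1000)
        assert set(pv.index) == set(tab.columns[:12])
        assert pv["p_value"].between(0, 1).all()

    def test_too_few_permutations_rejected(self, rng):
        X, y = make_signal_data(rng, n=600)
        est = ResidencyDriverForest(n_trees=100, seed=5).fit(X, y)
        with pytest.raises(ValueError, match="at least 20"):
            est.importance_pvalues(X, y, n_perm=10)

    def test_pvalue_formula_extremes(self):
        # observed below every null draw -> p = (1 + B)/(1 + B) = 1
        null = np.ones((100, 1))
        observed = np.zeros(1)
        p = (1.0 + (null >= observed).sum(axis=0)) / (1.0 + 100)
        assert p[0] == 1.0
        # observed above every null draw -> p = 1/(1 + B)
        p = (1.0 + (null >= np.full(1, 2.0)).sum(axis=0)) / (1.0 + 100)
        assert p[0] == pytest.approx(1 / 101)

    def test_null_pvalues_roughly_uniform(self):
        """Under a global null the permutation p-values are not anti-conservative."""
        from scipy.stats import kstest

        draws = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(800, 5)), columns=list("abcde"))
            y = r.normal(size=800)
            est = ResidencyDriverForest(n_trees=100, seed=seed).fit(X, y)
            pv = est.importance_pvalues(X, y, n_perm=40, max_rows=800)
            draws.extend(pv["p_value"].tolist())
        stat, _ = kstest(draws, "uniform", alternative="greater")
        # one-sided: the empirical CDF must not exceed uniform by much
        assert stat < 0.25


class TestRankImportance:
    def test_descending_scores_rank_1_2_3(self):
        s = pd.Series({"x": 3.0, "y": 2.0, "z": 1.0})
        out = rank_importance(s)
        assert out.set_index("predictor")["rank"].to_dict() == {"x": 1, "y": 2, "z": 3}

    def test_exact_tie_breaks_by_name(self):
        s = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})
        out = rank_importance(s)
        assert out["predictor"].tolist() == ["c", "a", "b"]

    def test_stars_attach_below_alpha(self):
        s = pd.Series({"a": 2.0, "b": 1.0})
        p = pd.Series({"a": 0.005, "b": 0.5})
        out = rank_importance(s, p).set_index("predictor")
        assert bool(out.loc["a", "significant"]) and not bool(out.loc["b", "significant"])


class TestPartialDependence:
    def test_constant_model_flat_curve(self, rng):
        X, y = make_signal_data(rng, n=700)
        est = ResidencyDriverForest(n_trees=100, seed=6).fit(X, np.full(len(X), 0.0) + y.mean()
                                                             + rng.normal(0, 1e-9, len(X)))
        curve = est.partial_dependence(X, "a", n_grid=10)
        assert curve["mean_prediction"].std() == pytest.approx(0.0, abs=1e-6)

    def test_stump_matches_brute_force_set_and_average(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (400, 3)), columns=list("abc"))
        y = (X["a"] > 0.5).astype(float).to_numpy()
        stump = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        curve = partial_dependence(stump, X, "a", n_grid=21)
        for g, m in zip(curve["a"], curve["mean_prediction"]):
            Xg = X.copy()
            Xg["a"] = g  # brute force: set column, average predictions
            assert m == pytest.approx(stump.predict(Xg).mean(), abs=1e-12)

    def test_matches_sklearn_brute_partial_dependence(self, rng):
        from sklearn.inspection import partial_dependence as skl_pd

        X, y = make_signal_data(rng, n=800)
        est = ResidencyDriverForest(n_trees=100, seed=8).fit(X, y)
        ours = partial_dependence(est, X, "a", n_grid=20)
        ref = skl_pd(est.forest_, X.to_numpy(), [0], kind="average", method="brute",
                     custom_values={0: ours["a"].to_numpy()})
        np.testing.assert_allclose(ours["mean_prediction"], ref["average"][0], atol=1e-9)

    def test_curve_within_prediction_range(self, rng):
        X, y = make_signal_data(rng, n=600)
        est = ResidencyDriverForest(n_trees=100, seed=9).fit(X, y)
        preds = est.predict(X)
        curve = est.partial_dependence(X, "a", n_grid=15)
        assert curve["mean_prediction"].between(preds.min(), preds.max()).all()

    def test_unknown_predictor_rejected(self, rng):
        X, y = make_signal_data(rng, n=600)
        est = ResidencyDriverForest(n_trees=100, seed=9).fit(X, y)
        with pytest.raises(ValueError, match="not among predictors"):
            est.partial_dependence(X, "zz")


class TestCoordinateInflation:
    def test_adding_coordinates_never_hurts_apparent_fit(self):
        """EA/NO proxy the autocorrelated residency surface, so the bagging
        OOB R² with coordinates is at least as high as without them."""
        from grazedrivers.validation import coordinate_inflation

        df = coordinate_inflation(seeds=range(1, 9), n_animals=6, max_fit_rows=4000)
        assert (df["oob_r2_with"] >= df["oob_r2_without"] - 0.01).all()
        assert df["oob_r2_with"].mean() >= df["oob_r2_without"].mean()


class TestSubsetGrazingHours:
    @pytest.fixture
    def rows(self, trial_start):
        ts = pd.date_range(trial_start, periods=100, freq="10min")
        return pd.DataFrame({"timestamp": ts, "v": np.arange(100)})

    def test_all_hours_mode_is_identity(self, rows):
        out = subset_grazing_hours(rows, None, mode="AH")
        pd.testing.assert_frame_equal(out, rows)

    def test_full_coverage_is_identity(self, rows, trial_start):
        out = subset_grazing_hours(rows, [(trial_start, trial_start + pd.Timedelta("1d"))])
        assert len(out) == len(rows)

    def test_single_hour_interval(self, rows, trial_start):
        iv = [(trial_start + pd.Timedelta("1h"), trial_start + pd.Timedelta("2h"))]
        out = subset_grazing_hours(rows, iv)
        assert len(out) == 6  # 10-min cadence -> 6 rows per hour

    def test_random_intervals_match_membership_oracle(self, rows, trial_start, rng):
        ivs = []
        for _ in range(5):
            s = trial_start + pd.Timedelta(minutes=int(rng.integers(0, 900)))
            ivs.append((s, s + pd.Timedelta(minutes=int(rng.integers(10, 120)))))
        out = subset_grazing_hours(rows, ivs)
        oracle = [
            any(s <= t < e for s, e in ivs) for t in rows["timestamp"]
        ]
        assert out["v"].tolist() == rows.loc[oracle, "v"].tolist()

    def test_empty_intervals_in_gh_mode_rejected(self, rows):
        with pytest.raises(ValueError, match="grazing interval"):
            subset_grazing_hours(rows, [], mode="GH")
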