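"""Prediction probability, rank tests, sample size, study battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import catacrotic as cc
from catacrotic.stats import PredictionProbability, analyze_study


def pk_bruteforce(x, y):
    """Exhaustive pair enumeration of (C + T/2)/(C + D + T)."""
    c = d = t = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        if x[i] == x[j]:
            continue
        dy = (y[j] - y[i]) * (1 if x[i] < x[j] else -1)
        if dy > 0:
            c += 1
        elif dy < 0:
            d += 1
        else:
            t += 1
    return (c + t / 2.0) / (c + d + t)


class TestPredictionProbability:
    def test_strictly_decreasing_response(self):
        res = cc.pk_statistic([0, 0, 1, 1, 3, 3], [6, 5, 4, 3, 2, 1])
        assert res.pk == 1.0
        assert res.direction == "anticoncordant"

    def test_all_tied_responses(self):
        res = cc.pk_statistic([0, 0, 1, 1, 3, 3], [2, 2, 2, 2, 2, 2])
        assert res.pk_raw == 0.5 and res.pk == 0.5

    def test_mixed_example_with_ties(self):
        # 12 cross-group pairs: 9 discordant, 3 response-tied
        res = cc.pk_statistic([0, 0, 1, 1, 3, 3], [5, 4, 4, 3, 3, 3])
        assert res.pk_raw == pytest.approx(1.5 / 12.0)
        assert res.pk == pytest.approx(10.5 / 12.0)
        assert res.direction == "anticoncordant"
        assert res.n_pairs == 12

    def test_matches_bruteforce_and_somers_d_on_random_data(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            levels = rng.choice([2, 3])
            x = rng.integers(0, levels, n)
            while np.unique(x).size < 2:
                x = rng.integers(0, levels, n)
            y = rng.integers(0, 5, n).astype(float)
            res = cc.pk_statistic(x, y)
            assert res.pk_raw == pk_bruteforce(x, y)
            d = sps.somersd(x, y).statistic
            assert res.pk_raw == pytest.approx((d + 1.0) / 2.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.integers(0, 3, 20)
        x[:2] = [0, 1]
        y = rng.standard_normal(20)
        a = cc.pk_statistic(x, y)
        b = cc.pk_statistic(x, np.exp(3 * y))
        assert a.pk_raw == b.pk_raw and a.se == pytest.approx(b.se)

    def test_reflection_symmetry_without_ties(self, rng):
        x = rng.integers(0, 3, 15)
        x[:2] = [0, 1]
        y = rng.standard_normal(15)  # continuous: no ties
        assert (cc.pk_statistic(x, y).pk_raw
                + cc.pk_statistic(x, -y).pk_raw) == pytest.approx(1.0)

    def test_jackknife_se_positive_and_finite(self, rng):
        x = np.repeat([0, 1, 3], 10)
        y = -x + rng.standard_normal(30)
        res = cc.pk_statistic(x, y)
        assert 0 < res.se < 0.5

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            cc.pk_statistic([1, 1, 1], [1, 2, 3])

    def test_estimator_surface(self):
        est = PredictionProbability().fit([0, 0, 1, 1], [4, 3, 2, 1])
        assert est.pk_ == 1.0 and est.direction_ == "anticoncordant"


class TestWilcoxon:
    def test_no_change_gives_p_one(self):
        with pytest.warns(UserWarning):
            res = cc.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_exact_p_for_uniform_shift(self):
        pre = np.arange(1.0, 11.0)
        res = cc.wilcoxon_signed_rank(pre, pre + 1.0)
        assert res.p_value == pytest.approx(2.0 / 1024.0)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            d = rng.standard_normal(12)
            res = cc.wilcoxon_signed_rank(np.zeros(12), d)
            ref = sps.wilcoxon(d, method="exact").pvalue
            assert res.p_value == pytest.approx(float(ref), abs=1e-12)

    def test_large_sample_approximation(self, rng):
        pre = rng.standard_normal(40)
        post = pre + 0.5 + rng.standard_normal(40)
        res = cc.wilcoxon_signed_rank(pre, post)
        assert res.note == "normal approximation"
        assert 0 <= res.p_value <= 1

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            cc.wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestMannWhitney:
    def test_identical_groups(self):
        res = cc.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_fully_separated_small_groups_exact(self):
        res = cc.mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.note == "exact"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cc.mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        res = cc.kruskal_wallis([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_rank_formula_value(self):
        # ranks 1..6; H = 12/(6*7) * sum n_i (Rbar_i - 3.5)^2 = (12/42)*16
        res = cc.kruskal_wallis([1, 2], [3, 4], [5, 6])
        assert res.statistic == pytest.approx(32.0 / 7.0)

    def test_monotone_transform_invariance(self):
        a = cc.kruskal_wallis([1, 2], [3, 4], [5, 6]).statistic
        b = cc.kruskal_wallis([10, 20], [30, 40], [50, 60]).statistic
        assert a == pytest.approx(b)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cc.kruskal_wallis([1, 2])
        with pytest.raises(ValueError):
            cc.kruskal_wallis([1], [2, 3])


class TestSpearmanMatrix:
    def test_self_and_reversed_correlation(self, rng):
        x = rng.standard_normal(20)
        df = pd.DataFrame({"a": x, "b": -x, "c": rng.standard_normal(20)})
        rho, p = cc.spearman_matrix(df)
        assert rho.loc["a", "a"] == 1.0
        assert rho.loc["a", "b"] == pytest.approx(-1.0)
        assert p.loc["a", "c"] == pytest.approx(
            float(sps.spearmanr(x, df["c"]).pvalue))

    def test_constant_column_flagged_nan(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(10), "b": np.ones(10)})
        rho, _ = cc.spearman_matrix(df)
        assert np.isnan(rho.loc["a", "b"])

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            cc.spearman_matrix(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))


class TestSampleSize:
    def test_published_design_value(self):
        assert cc.sample_size_two_groups(0.1, 0.08, 0.05, 0.8) == 12

    def test_unit_effect_size(self):
        assert cc.sample_size_two_groups(1.0, 1.0, 0.05, 0.8) == 17

    def test_vanishing_power_needs_minimum_n(self):
        assert cc.sample_size_two_groups(0.1, 0.08, 0.05, 1e-9) == 2

    def test_monotonicity(self):
        base = cc.sample_size_two_groups(0.1, 0.08, 0.05, 0.8)
        assert cc.sample_size_two_groups(0.2, 0.08, 0.05, 0.8) <= base
        assert cc.sample_size_two_groups(0.1, 0.16, 0.05, 0.8) >= base
        assert cc.sample_size_two_groups(0.1, 0.08, 0.01, 0.8) >= base
        assert cc.sample_size_two_groups(0.1, 0.08, 0.05, 0.95) >= base

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            cc.sample_size_two_groups(0.0, 1.0)
        with pytest.raises(ValueError):
            cc.sample_size_two_groups(1.0, 1.0, alpha=1.5)


class TestAnalyzeStudy:
    def _frame(self, post_fn, n=6):
        rows = []
        for i in range(3 * n):
            ce = [0.0, 1.0, 3.0][i // n]
            for par in ("PBI", "DI"):
                rows.append({"subject": f"S{i}", "ce": ce, "parameter": par,
                             "pre_value": 0.0, "post_value": post_fn(i, ce, par)})
        return pd.DataFrame(rows)

    def test_null_frame_shows_nothing(self):
        frame = self._frame(lambda i, ce, par: 0.0)
        with pytest.warns(UserWarning):
            report = analyze_study(frame)
        for par in ("PBI", "DI"):
            for g in (0.0, 1.0, 3.0):
                assert not report["within_group"][par][g]["significant"]
            assert report["prediction_probability"][par]["pk"] == 0.5
        assert report["sample_size"]["n_per_group"] == 12

    def test_graded_frame_is_detected(self):
        rng = np.random.default_rng(0)
        frame = self._frame(lambda i, ce, par: -1.0 / (1 + ce) + 0.05 * rng.standard_normal())
        report = analyze_study(frame)
        assert report["within_group"]["PBI"][0.0]["significant"]
        assert report["prediction_probability"]["PBI"]["pk"] > 0.9
        assert report["between_group"]["PBI"]["0.0-3.0"]["significant"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            analyze_study(pd.DataFrame({"subject": [], "ce": []}))
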