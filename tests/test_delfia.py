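"""Plate-assay analytics: positivity threshold, SE/SP arithmetic, group
tests against a brute-force hypergeometric oracle, ROC against the
pairwise-count oracle, and marker combination rules."""

import math

import numpy as np
import pandas as pd
import pytest

from seropanel.delfia import (
    combine_markers,
    delfia_positivity,
    group_tests,
    roc_auc,
    sens_spec,
    significance_stars,
)
from seropanel.stability import round_half_up


class TestPositivity:
    def test_threshold_is_hd_mean_plus_one_sem(self):
        hd = np.array([90.0, 100.0, 100.0, 110.0])  # mean 100, SD ~8.165, n 4
        values = pd.Series({"s1": 110.0, "s2": 100.0})
        calls, thr = delfia_positivity(values, hd)
        assert thr.value == pytest.approx(100 + 8.164966 / 2, rel=1e-6)
        assert calls["s1"] == 1 and calls["s2"] == 0

    def test_value_at_threshold_is_negative(self):
        hd = np.array([100.0, 100.0, 120.0, 80.0])
        _, thr = delfia_positivity(pd.Series({"s": 0.0}), hd)
        calls, _ = delfia_positivity(pd.Series({"s": thr.value}), hd)
        assert calls["s"] == 0

    def test_constant_hd_threshold_is_the_constant(self):
        calls, thr = delfia_positivity(
            pd.Series({"s": 100.0}), np.array([100.0] * 10)
        )
        assert thr.value == 100.0 and calls["s"] == 0

    def test_requires_two_hd_values(self):
        with pytest.raises(ValueError):
            delfia_positivity(pd.Series({"s": 1.0}), np.array([1.0]))


class TestSensSpec:
    def _calls(self, pos_aih, n_aih, pos_hd, n_hd):
        idx = [f"a{i}" for i in range(n_aih)] + [f"h{i}" for i in range(n_hd)]
        calls = pd.Series(
            [1] * pos_aih + [0] * (n_aih - pos_aih)
            + [1] * pos_hd + [0] * (n_hd - pos_hd),
            index=idx,
        )
        labels = pd.Series(["AIH"] * n_aih + ["HD"] * n_hd, index=idx)
        return calls, labels

    def test_reported_percentages(self):
        calls, labels = self._calls(18, 40, 4, 35)
        se, sp = sens_spec(calls, labels, "AIH", "HD")
        assert round_half_up(se) == 45   # 18/40
        assert round_half_up(sp) == 89   # 31/35 = 88.57 -> 89

    def test_perfect_specificity(self):
        calls, labels = self._calls(10, 40, 0, 35)
        _, sp = sens_spec(calls, labels, "AIH", "HD")
        assert sp == 100.0

    def test_empty_group_rejected(self):
        calls, labels = self._calls(1, 2, 1, 2)
        with pytest.raises(ValueError):
            sens_spec(calls, labels, "AIH", "HCV")


def _fisher_oracle(table):
    """Two-sided Fisher p by exact integer hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= obs:
            num += w
    return num / math.comb(n, c1)


class TestGroupTests:
    def _series(self, table, values_shift=0.0, seed=0):
        (a, b), (c, d) = table
        g = np.random.default_rng(seed)
        n1, n2 = a + b, c + d
        idx = [f"x{i}" for i in range(n1 + n2)]
        calls = pd.Series([1] * a + [0] * b + [1] * c + [0] * d, index=idx)
        labels = pd.Series(["G1"] * n1 + ["G2"] * n2, index=idx)
        values = pd.Series(
            np.r_[g.normal(values_shift, 1, n1), g.normal(0, 1, n2)], index=idx
        )
        return values, calls, labels

    def test_identical_proportions_not_significant(self):
        values, calls, labels = self._series([[20, 20], [20, 20]])
        res = group_tests(values, calls, labels, ("G1", "G2"))
        assert res["call_test"] == "chi2"
        assert res["p_calls"] == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        """20/20 vs 0/20 positive: Fisher p = 2 / C(40, 20)."""
        values, calls, labels = self._series([[20, 0], [0, 20]])
        res = group_tests(values, calls, labels, ("G1", "G2"), call_test="fisher")
        assert res["call_test"] == "fisher"
        assert res["p_calls"] == pytest.approx(2 / math.comb(40, 20), rel=1e-9)
        assert res["p_calls"] == pytest.approx(
            _fisher_oracle([[20, 0], [0, 20]]), rel=1e-9
        )

    def test_t_test_type_i_error_calibrated(self):
        """Equal-mean samples reject at ~5% over seeded repetitions."""
        rej = 0
        reps = 200
        for seed in range(reps):
            values, calls, labels = self._series([[5, 15], [5, 15]], seed=seed)
            res = group_tests(values, calls, labels, ("G1", "G2"))
            rej += res["p_intensity"] < 0.05
        se3 = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < se3

    def test_star_convention(self):
        assert significance_stars(0.2) == ""
        assert significance_stars(0.01) == "*"
        assert significance_stars(5e-4) == "**"
        assert significance_stars(5e-5) == "***"


def _auc_oracle(scores, labels, positive=1):
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.best_se == 100.0 and res.best_sp == 100.0

    def test_null_scores_near_half(self):
        g = np.random.default_rng(0)
        res = roc_auc(g.standard_normal(4000), g.integers(0, 2, 4000))
        assert abs(res.auc - 0.5) < 0.05

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(5, 50))
        scores = g.integers(0, 6, n).astype(float)  # heavy ties
        labels = np.r_[np.ones(2, dtype=int), g.integers(0, 2, n - 4), np.zeros(2, dtype=int)]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(_auc_oracle(scores, labels), abs=1e-12)

    def test_sklearn_agreement(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.integers(0, 10, 200).astype(float)
        labels = rng.integers(0, 2, 200)
        labels[:2], labels[-2:] = 1, 0
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(100)
        labels = rng.integers(0, 2, 100)
        labels[:2], labels[-2:] = 1, 0
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_curve_is_monotone_staircase(self, rng):
        scores = rng.integers(0, 5, 60).astype(float)
        labels = rng.integers(0, 2, 60)
        labels[:2], labels[-2:] = 1, 0
        curve = roc_auc(scores, labels).curve
        assert (np.diff(curve["tpr"]) >= 0).all()
        assert (np.diff(curve["fpr"]) >= 0).all()


class TestCombination:
    def _frame(self, rng, n=60):
        idx = [f"s{i}" for i in range(n)]
        data = pd.DataFrame(
            {"A": rng.normal(10, 2, n), "B": rng.normal(10, 2, n)}, index=idx
        )
        calls = pd.DataFrame(
            {"A": rng.integers(0, 2, n), "B": rng.integers(0, 2, n)}, index=idx
        )
        labels = pd.Series(["AIH"] * (n // 2) + ["HD"] * (n - n // 2), index=idx)
        return data, calls, labels

    def test_or_rule_union_and_bounds(self, rng):
        data, calls, labels = self._frame(rng)
        combo = combine_markers(data, ["A", "B"], "or-rule", calls=calls)
        assert (combo == calls.max(axis=1)).all()
        se_c, sp_c = sens_spec(combo, labels, "AIH", "HD")
        for m in ["A", "B"]:
            se, sp = sens_spec(calls[m], labels, "AIH", "HD")
            assert se_c >= se and sp_c <= sp

    def test_or_rule_single_marker_identity(self, rng):
        data, calls, labels = self._frame(rng)
        combo = combine_markers(data, ["A"], "or-rule", calls=calls)
        assert (combo == calls["A"]).all()

    def test_reported_combined_specificity(self):
        """Marker A 0/35 HD positive, marker B 4/35: or-rule SP = 89%."""
        idx = [f"h{i}" for i in range(35)]
        calls = pd.DataFrame(
            {"A": [0] * 35, "B": [1] * 4 + [0] * 31}, index=idx
        )
        data = pd.DataFrame(np.zeros((35, 2)), columns=["A", "B"], index=idx)
        combo = combine_markers(data, ["A", "B"], "or-rule", calls=calls)
        assert combo.sum() == 4          # union of HD positives
        sp = 100 * (1 - combo).mean()    # 31/35 true negatives
        assert round_half_up(sp) == 89

    def test_redundant_markers_score_sum_preserves_auc(self, rng):
        n = 80
        idx = [f"s{i}" for i in range(n)]
        base = rng.normal(10, 3, n)
        data = pd.DataFrame({"A": base, "B": base * 2 + 5}, index=idx)
        labels = pd.Series(
            np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)],
            index=idx,
        )
        hd_mask = labels == 0
        score = combine_markers(data, ["A", "B"], "score-sum", hd_mask=hd_mask)
        assert roc_auc(score, labels).auc == pytest.approx(
            roc_auc(data["A"], labels).auc, abs=1e-12
        )

    def test_invalid_modes_and_inputs(self, rng):
        data, calls, _ = self._frame(rng)
        with pytest.raises(ValueError, match="unknown markers"):
            combine_markers(data, ["A", "Z"], "or-rule", calls=calls)
        with pytest.raises(ValueError, match="unknown combination"):
            combine_markers(data, ["A", "B"], "and-rule", calls=calls)
        with pytest.raises(ValueError):
            combine_markers(data, ["A", "B"], "score-sum")
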