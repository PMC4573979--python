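"""Preprocessing: signal ratios, IgG-curve normalization, negative-control
thresholding, replicate QC, imputation and positivity calling."""

import numpy as np
import pandas as pd
import pytest

from seropanel.preprocess import (
    ThresholdSpec,
    call_positivity,
    compute_threshold,
    fit_igg_map,
    impute_invalid_signals,
    normalize_within_array,
    preprocess_scans,
    reference_igg_curve,
    replicate_cv_filter,
    spot_signal,
)


@pytest.mark.parametrize(
    "fg,bg,expected",
    [(8000, 2000, 4.0), (1500, 1500, 1.0), (0, 100, 0.0)],
)
def test_spot_signal_ratio(fg, bg, expected):
    assert spot_signal(fg, bg) == expected


def test_spot_signal_invalid_background_is_nan():
    out = spot_signal(np.array([100.0, 100.0]), np.array([0.0, -5.0]))
    assert np.isnan(out).all()


def _toy_scan(igg_signals, antigen_signals, array_id="a1"):
    levels = np.arange(1, len(igg_signals) + 1, dtype=float) * 1000
    rows = [
        {"array_id": array_id, "sample_id": array_id,
         "antigen_id": f"IgG-{lv:g}", "replicate": 0, "fg_mean": s,
         "bg_mean": 1.0, "control_type": "igg", "nominal_igg": lv}
        for lv, s in zip(levels, igg_signals)
    ]
    rows += [
        {"array_id": array_id, "sample_id": array_id,
         "antigen_id": f"AG{i:02d}", "replicate": 0, "fg_mean": s,
         "bg_mean": 1.0, "control_type": "none", "nominal_igg": np.nan}
        for i, s in enumerate(antigen_signals)
    ]
    return pd.DataFrame(rows), pd.Series(levels, index=levels)


class TestNormalization:
    def test_identity_when_array_matches_reference(self):
        scan, ref = _toy_scan([1000, 2000, 3000, 4000], [500, 1500])
        out = normalize_within_array(scan, ref)
        np.testing.assert_allclose(
            out.loc[out["control_type"] == "none", "normalized"], [500, 1500]
        )

    def test_scale_drift_inverted(self):
        scan, ref = _toy_scan(
            [2000, 4000, 6000, 8000], [1000, 3000]
        )  # array reads exactly 2x the reference
        out = normalize_within_array(scan, ref)
        np.testing.assert_allclose(
            out.loc[out["control_type"] == "none", "normalized"], [500, 1500]
        )

    def test_too_few_or_degenerate_curve_rejected(self):
        scan, ref = _toy_scan([1000, 2000], [500])
        with pytest.raises(ValueError, match="IgG curve"):
            normalize_within_array(scan, ref)
        scan, ref = _toy_scan([1000, 1000, 1000, 1000], [500])
        with pytest.raises(ValueError, match="degenerate"):
            normalize_within_array(scan, ref)

    def test_drift_cv_reduced_across_arrays(self, small_scans, small_cohort):
        """Between-array CV of IgG-curve points shrinks after normalization
        (log-normal drift, sigma = 0.3)."""
        ref = reference_igg_curve(small_scans)
        raw_cv, norm_cv = [], []
        igg_by_level_raw, igg_by_level_norm = {}, {}
        for _, scan in small_scans.groupby("array_id", observed=True):
            out = normalize_within_array(scan, ref)
            igg = out[out["control_type"] == "igg"]
            sig = spot_signal(igg["fg_mean"].to_numpy(), igg["bg_mean"].to_numpy())
            for lv, raw, norm in zip(igg["nominal_igg"], sig, igg["normalized"]):
                igg_by_level_raw.setdefault(lv, []).append(raw)
                igg_by_level_norm.setdefault(lv, []).append(norm)
        for lv in igg_by_level_raw:
            r = np.array(igg_by_level_raw[lv])
            n = np.array(igg_by_level_norm[lv])
            raw_cv.append(r.std() / r.mean())
            norm_cv.append(n.std() / abs(n.mean()))
        assert np.mean(norm_cv) < np.mean(raw_cv)

    def test_scale_equivariance_of_pipeline(self, small_scans, small_cohort):
        """Multiplying one array's raw intensities (IgG curve included) by a
        constant leaves its normalized MFI row essentially unchanged."""
        scans = small_scans.copy()
        target = scans["array_id"] == small_cohort["sample_id"].iloc[0]
        scans.loc[target, "fg_mean"] *= 7.0
        base = preprocess_scans(small_scans, small_cohort)
        pert = preprocess_scans(scans, small_cohort)
        row = small_cohort["sample_id"].iloc[0]
        np.testing.assert_allclose(
            pert.mfi.loc[row], base.mfi.loc[row], rtol=1e-8
        )


class TestThreshold:
    def test_mean_plus_two_sd(self):
        thr = compute_threshold(np.array([3000.0, 3200.0, 2800.0]))
        assert thr.value == pytest.approx(3400.0)

    def test_constant_controls(self):
        assert compute_threshold(np.array([5.0, 5.0, 5.0])).value == 5.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            compute_threshold(np.array([3000.0]))

    def test_calibrated_generator_hits_design_target(self, small_pre):
        """Estimated threshold (control mean + 2 SD) within 5% of the
        4000-normalized-MFI design target."""
        assert abs(small_pre.threshold.value - 4000) / 4000 < 0.05


class TestReplicateFilter:
    def _frame(self, values):
        return pd.DataFrame(
            {"array_id": "a1", "antigen_id": "AG1", "normalized": values}
        )

    def test_zero_cv_kept(self):
        out = replicate_cv_filter(self._frame([10.0, 10, 10, 10]))
        assert out.loc[0, "cv_pct"] == 0.0 and out.loc[0, "kept"]

    def test_high_cv_dropped(self):
        out = replicate_cv_filter(self._frame([1.0, 100, 1, 100]))
        assert out.loc[0, "cv_pct"] == pytest.approx(113.2, abs=0.5)
        assert not out.loc[0, "kept"]

    def test_infinite_ceiling_keeps_all(self):
        out = replicate_cv_filter(self._frame([1.0, 100, 1, 100]), cv_max=np.inf)
        assert out["kept"].all()

    def test_nonpositive_mean_dropped(self):
        out = replicate_cv_filter(self._frame([-2.0, 2.0]))
        assert not out.loc[0, "kept"]

    def test_replicate_order_invariance(self, small_scans, small_cohort):
        shuffled = small_scans.sample(frac=1.0, random_state=0)
        a = preprocess_scans(small_scans, small_cohort)
        b = preprocess_scans(shuffled, small_cohort)
        pd.testing.assert_frame_equal(
            a.positivity.sort_index(), b.positivity.sort_index()
        )


class TestImputation:
    def _samples(self):
        return pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3"], "group": ["AIH", "AIH", "AIH"]}
        )

    def test_group_mean_fills_invalid(self):
        m = pd.DataFrame({"AG1": [2.0, 4.0, np.nan]}, index=["s1", "s2", "s3"])
        out = impute_invalid_signals(m, self._samples())
        assert out.loc["s3", "AG1"] == 3.0

    def test_no_invalid_is_identity(self):
        m = pd.DataFrame({"AG1": [2.0, 4.0, 6.0]}, index=["s1", "s2", "s3"])
        pd.testing.assert_frame_equal(impute_invalid_signals(m, self._samples()), m)

    def test_all_invalid_in_group_drops_antigen(self):
        m = pd.DataFrame(
            {"AG1": [np.nan, np.nan, np.nan], "AG2": [1.0, 2.0, 3.0]},
            index=["s1", "s2", "s3"],
        )
        with pytest.warns(UserWarning, match="dropping 1 antigen"):
            out = impute_invalid_signals(m, self._samples())
        assert list(out.columns) == ["AG2"]


class TestPositivity:
    def test_strict_threshold(self):
        thr = ThresholdSpec(4000.0)
        m = pd.DataFrame({"AG1": [4001.0, 4000.0, 10.0]}, index=list("abc"))
        out = call_positivity(m, thr)
        assert out["AG1"].tolist() == [1, 0, 0]

    def test_all_below_gives_zero_matrix(self):
        m = pd.DataFrame(np.full((3, 4), 5.0))
        assert call_positivity(m, ThresholdSpec(4000.0)).to_numpy().sum() == 0

    def test_nonfinite_matrix_rejected(self):
        m = pd.DataFrame({"AG1": [1.0, np.nan]})
        with pytest.raises(ValueError):
            call_positivity(m, ThresholdSpec(1.0))


def test_lad_fit_robust_to_single_outlier():
    x = np.array([1.0, 2, 3, 4, 5, 6])
    y = 2 * x + 1
    y[2] += 50  # one corrupted curve point
    a, b = fit_igg_map(x, y)
    assert a == pytest.approx(2.0) and b == pytest.approx(1.0)
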