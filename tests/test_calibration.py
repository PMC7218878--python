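"""oPTP / mPTP / fPTP calibration and the penalty factor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pttbp.calibration import (
    CalibrationSet,
    adjust_ptt0,
    build_calibration_set,
    calibrate_fptp,
    calibrate_mptp,
    calibrate_optp,
    penalty_factor,
)
from pttbp.exceptions import DataError, ValidationError
from pttbp.models import dmkbh_estimate
from pttbp.signals import BeatPTTSeries, WindowMedianSeries

GAMMA = 0.017


def make_set(medians, cuff_sbp, cuff_dbp, beat_ptts=None, window_s=30.0):
    medians = np.asarray(medians, float)
    n = medians.size
    starts = window_s * np.arange(n)
    windows = WindowMedianSeries(starts, medians, np.full(n, 30), window_s)
    if beat_ptts is None:
        beat_ptts = medians
    beat_ptts = np.asarray(beat_ptts, float)
    beats = BeatPTTSeries(np.linspace(0.0, window_s * n, beat_ptts.size, endpoint=False),
                          beat_ptts)
    return CalibrationSet(
        window_medians=windows,
        cuff_times=starts + window_s / 2,
        cuff_sbp=np.asarray(cuff_sbp, float),
        cuff_dbp=np.asarray(cuff_dbp, float),
        beat_ptts=beats,
        duration=window_s * n,
    )


class TestPenaltyFactor:
    def test_worked_value(self):
        assert penalty_factor([2.0, -1.0, 3.0]) == pytest.approx(4.0 / 18.0)

    def test_symmetric_deviations_cancel(self):
        assert penalty_factor([-1.0, 1.0]) == 0.0

    def test_all_zero_guard(self):
        assert penalty_factor([0.0, 0.0, 0.0]) == 0.0

    def test_sign_follows_total_bias(self):
        assert penalty_factor([5.0, -1.0]) > 0
        assert penalty_factor([-5.0, 1.0]) < 0

    def test_literal_typeset_form_degenerates(self):
        # the literal expression collapses to 1/n whenever the sum is nonzero
        assert penalty_factor([2.0, -1.0, 3.0], literal_form=True) == pytest.approx(1 / 3)
        assert penalty_factor([-1.0, 1.0], literal_form=True) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            penalty_factor([])

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.floats(-100.0, 100.0), min_size=2, max_size=50))
    def test_bounded_by_reciprocal_n(self, devs):
        alpha = penalty_factor(devs)
        assert abs(alpha) <= 1.0 / len(devs) + 1e-12


class TestAdjustPtt0:
    def test_worked_value(self):
        cal = make_set([250.0, 260.0, 240.0], [120] * 3, [80] * 3,
                       beat_ptts=np.full(30, 252.0))
        # d = {-2, 8, -12}; alpha = -6/66; ptt0 = 252 * (1 + 6/66)
        assert adjust_ptt0(cal) == pytest.approx(252.0 * (1 + 6.0 / 66.0))

    def test_medians_equal_mean_no_adjustment(self):
        cal = make_set([250.0, 250.0], [120] * 2, [80] * 2, beat_ptts=np.full(20, 250.0))
        assert adjust_ptt0(cal) == pytest.approx(250.0)

    def test_symmetric_medians_no_adjustment(self):
        cal = make_set([245.0, 255.0], [120] * 2, [80] * 2, beat_ptts=np.full(20, 250.0))
        assert adjust_ptt0(cal) == pytest.approx(250.0)

    def test_single_window_rejected(self):
        cal = make_set([250.0], [120.0], [80.0])
        with pytest.raises(ValidationError):
            adjust_ptt0(cal)


class TestOptp:
    def test_direct_assignment(self):
        cal = make_set([250.0, 260.0], [120.0, 118.0], [80.0, 78.0])
        p = calibrate_optp(0, cal, GAMMA)
        assert (p.sbp0, p.dbp0, p.pp0, p.ptt0) == (120.0, 80.0, 40.0, 250.0)
        assert p.mbp0 == pytest.approx(80.0 + 40.0 / 3.0)
        sbp, dbp = dmkbh_estimate(p.ptt0, p)
        assert sbp == pytest.approx(120.0) and dbp == pytest.approx(80.0)

    def test_initial_value_sensitivity(self):
        cal = make_set([250.0, 260.0], [120.0, 118.0], [80.0, 78.0])
        assert calibrate_optp(0, cal, GAMMA) != calibrate_optp(1, cal, GAMMA)

    def test_inverted_cuff_pair_rejected(self):
        with pytest.raises(DataError):
            make_set([250.0], [80.0], [120.0])

    def test_out_of_range_index_rejected(self):
        cal = make_set([250.0, 260.0], [120.0, 118.0], [80.0, 78.0])
        with pytest.raises(ValidationError):
            calibrate_optp(5, cal, GAMMA)


class TestMptp:
    def test_means(self):
        cal = make_set([250.0, 254.0], [118.0, 122.0], [78.0, 82.0],
                       beat_ptts=np.full(40, 252.0))
        p = calibrate_mptp(cal, GAMMA)
        assert (p.sbp0, p.dbp0, p.pp0) == (120.0, 80.0, 40.0)
        assert p.mbp0 == pytest.approx(80.0 + 40.0 / 3.0)
        assert p.ptt0 == pytest.approx(252.0)

    def test_degenerate_mean_equals_optp(self):
        cal = make_set([250.0, 250.0], [120.0, 120.0], [80.0, 80.0],
                       beat_ptts=np.full(20, 250.0))
        assert calibrate_mptp(cal, GAMMA) == calibrate_optp(0, cal, GAMMA)

    def test_single_window_rejected(self):
        cal = make_set([250.0], [120.0], [80.0])
        with pytest.raises(ValidationError):
            calibrate_mptp(cal, GAMMA)


class TestFptp:
    def test_noiseless_consistency_collapses_to_mptp(self):
        """All medians equal the beat mean and the model reproduces the
        cuff exactly: every alpha is 0 and all three methods agree."""
        cal = make_set([250.0, 250.0, 250.0], [120.0] * 3, [80.0] * 3,
                       beat_ptts=np.full(30, 250.0))
        fp, factors = calibrate_fptp(cal, "dmkbh", GAMMA, return_factors=True)
        assert factors.alpha_ptt == factors.alpha_sbp == factors.alpha_dbp == 0.0
        assert fp == calibrate_mptp(cal, GAMMA) == calibrate_optp(0, cal, GAMMA)

    def test_systematic_overestimate_lowers_base(self):
        """Window medians drift below the beat-level mean, so the
        mPTP-anchored model over-estimates every cuff reading; the
        penalty factors come out positive and shrink the base values."""
        medians = np.array([238.0, 240.0, 242.0, 239.0, 241.0])
        from pttbp.models import ModelParams, dmkbh_estimate as est

        truth = ModelParams.from_cuff_pair(120.0, 80.0, 250.0, GAMMA)
        sbp, dbp = est(medians, truth)  # cuff follows the true model
        cal = make_set(medians, sbp, dbp, beat_ptts=np.full(50, 250.0))
        fp, factors = calibrate_fptp(cal, "dmkbh", GAMMA, return_factors=True)
        assert factors.alpha_sbp > 0 and factors.alpha_dbp > 0
        assert fp.sbp0 < float(np.mean(cal.cuff_sbp))
        assert fp.dbp0 < float(np.mean(cal.cuff_dbp))

    def test_adjustment_magnitude_eq4(self):
        """The adjusted bases equal the cuff means shrunk by (1 - alpha)."""
        medians = np.array([238.0, 240.0, 242.0, 239.0, 241.0])
        from pttbp.models import ModelParams, dmkbh_estimate as est

        truth = ModelParams.from_cuff_pair(120.0, 80.0, 250.0, GAMMA)
        sbp, dbp = est(medians, truth)
        cal = make_set(medians, sbp, dbp, beat_ptts=np.full(50, 250.0))
        fp, factors = calibrate_fptp(cal, "dmkbh", GAMMA, return_factors=True)
        assert factors.alpha_sbp != 0.0
        assert fp.sbp0 == pytest.approx(np.mean(cal.cuff_sbp) * (1 - factors.alpha_sbp))
        assert fp.dbp0 == pytest.approx(np.mean(cal.cuff_dbp) * (1 - factors.alpha_dbp))

    def test_collapse_to_inverted_base_rejected(self):
        """An adjustment that drives SBP0 <= DBP0 is refused, naming alpha.

        With n = 2 the SBP penalty can reach its 1/n = 0.5 bound when the
        model over-estimates both cuff SBP readings by the same amount,
        halving SBP0 while DBP0 shrinks far less — an inverted base pair.
        """
        cal = make_set(
            [240.0, 260.0],
            [96.061, 85.292],
            [82.0, 74.0],
            beat_ptts=np.full(20, 250.0),
        )
        with pytest.raises(DataError, match="alpha"):
            calibrate_fptp(cal, "dmkbh", GAMMA)

    def test_single_window_rejected(self):
        cal = make_set([250.0], [120.0], [80.0])
        with pytest.raises(ValidationError):
            calibrate_fptp(cal, "dmkbh", GAMMA)


class TestBuildCalibrationSet:
    def test_aligns_by_containing_window(self):
        windows = WindowMedianSeries([0.0, 30.0, 60.0], [250.0, 251.0, 252.0],
                                     [30, 30, 30], 30.0)
        beats = BeatPTTSeries(np.linspace(0, 90, 90, endpoint=False), np.full(90, 250.0))
        cal = build_calibration_set(windows, [15.0, 45.0], [120.0, 121.0],
                                    [80.0, 81.0], beats)
        assert cal.n == 2
        assert np.allclose(cal.window_medians.ptt_median, [250.0, 251.0])

    def test_duplicate_cuff_in_one_window_rejected(self):
        windows = WindowMedianSeries([0.0], [250.0], [30], 30.0)
        beats = BeatPTTSeries([1.0, 2.0], [250.0, 250.0])
        with pytest.raises(DataError):
            build_calibration_set(windows, [10.0, 20.0], [120.0, 121.0],
                                  [80.0, 81.0], beats)

    def test_mismatched_lengths_rejected(self):
        windows = WindowMedianSeries([0.0], [250.0], [30], 30.0)
        beats = BeatPTTSeries([1.0], [250.0])
        with pytest.raises(DataError):
            CalibrationSet(windows, np.array([15.0, 45.0]), np.array([120.0]),
                           np.array([80.0]), beats, 30.0)


def test_model_params_immutable():
    from pttbp.models import ModelParams

    p = ModelParams.from_cuff_pair(120.0, 80.0, 250.0, GAMMA)
    with pytest.raises(Exception):
        p.sbp0 = 130.0
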