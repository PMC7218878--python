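"""Point-to-point calibration: oPTP, mPTP, and fPTP.

A PTT-based blood-pressure model needs per-subject base values
(SBP0, DBP0, PTT0, and the derived PP0/MBP0) before it can monitor.  All
three methods derive them from a calm-segment calibration set: ~5 minutes
of beat-level PTT, its 30-s window medians PTT_i, and one cuff reading
(SBP_i, DBP_i) per window.

* **oPTP** uses a single (PTT_i, cuff_i) pair.  It is maximally simple but
  sensitive to which pair is chosen, because PTT and BP fluctuate even at
  rest.
* **mPTP** averages the calm state: SBP0/DBP0 are the cuff means and PTT0
  is the mean of all beat-level PTT samples.
* **fPTP** starts from mPTP and applies a bounded, signed penalty factor
  to each base value:

      alpha = sum(d_i) / (n * sum(|d_i|)),        x0 = x_mean * (1 - alpha)

  For PTT0 the deviations are the window medians about the beat-level
  mean; for SBP0/DBP0 they are the errors of the mPTP-calibrated model at
  the calibration windows against the cuff readings.  alpha lies in
  [-1/n, 1/n], is zero for symmetric or vanishing deviations, and acts as
  negative feedback: a consistent over-estimate lowers the base value.

Calibration is performed once per subject; the resulting ``ModelParams``
are immutable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import DataError, ValidationError
from .models import ModelName, ModelParams, estimate_bp
from .signals import BeatPTTSeries, WindowMedianSeries


@dataclass(frozen=True)
class CalibrationSet:
    """Calm-segment data backing one subject's calibration.

    ``cuff_times/cuff_sbp/cuff_dbp`` are aligned index-for-index with the
    retained windows in ``window_medians``; ``beat_ptts`` holds every
    beat-level PTT of the calm segment (the basis of the beat-level mean).
    """

    window_medians: WindowMedianSeries
    cuff_times: np.ndarray
    cuff_sbp: np.ndarray
    cuff_dbp: np.ndarray
    beat_ptts: BeatPTTSeries
    duration: float

    def __post_init__(self) -> None:
        for name in ("cuff_times", "cuff_sbp", "cuff_dbp"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.window_medians)
        if not (self.cuff_times.size == self.cuff_sbp.size == self.cuff_dbp.size == n):
            raise DataError(
                f"need one cuff reading per retained window: "
                f"{self.cuff_times.size} cuff readings vs {n} windows"
            )
        if np.any(self.cuff_sbp <= self.cuff_dbp):
            raise DataError("cuff readings must satisfy SBP > DBP")

    @property
    def n(self) -> int:
        """Number of paired (window median, cuff) calibration points."""
        return len(self.window_medians)

    @property
    def ptt_bar(self) -> float:
        """Beat-level mean PTT of the calm segment, ms."""
        if len(self.beat_ptts) == 0:
            raise DataError("calibration set has no beat-level PTT samples")
        return float(np.mean(self.beat_ptts.ptt))


@dataclass(frozen=True)
class PenaltyFactors:
    """Signed relative-bias penalty factors applied by fPTP."""

    alpha_ptt: float
    alpha_sbp: float
    alpha_dbp: float


def penalty_factor(deviations: Sequence[float], literal_form: bool = False) -> float:
    """Bounded signed relative-bias statistic of a deviation vector.

    Canonical form ``alpha = sum(d) / (n * sum(|d|))``: bounded by
    ``|alpha| <= 1/n``, zero when the deviations cancel or all vanish, with
    the sign of the total bias.  ``literal_form=True`` evaluates the
    originally typeset (degenerate) expression with signed deviations in
    both numerator and denominator — it collapses to ``1/n`` or 0 and is
    kept for auditability only.
    """
    d = np.asarray(deviations, dtype=float)
    if d.size < 1:
        raise ValidationError("penalty_factor requires at least one deviation")
    denom_core = np.sum(d) if literal_form else np.sum(np.abs(d))
    denom = d.size * denom_core
    if denom == 0:
        return 0.0
    return float(np.sum(d) / denom)


def adjust_ptt0(cal: CalibrationSet, literal_form: bool = False) -> float:
    """Penalty-adjusted base PTT: ``PTT0 = PTT_bar * (1 - alpha_PTT)``.

    Deviations are the window medians about the beat-level mean PTT.
    Equals the beat-level mean exactly when the medians are symmetric
    about it or all coincide with it.
    """
    if cal.n < 2:
        raise ValidationError("PTT adjustment requires n >= 2 calibration windows")
    ptt_bar = cal.ptt_bar
    alpha = penalty_factor(cal.window_medians.ptt_median - ptt_bar, literal_form)
    return ptt_bar * (1.0 - alpha)


def calibrate_optp(
    pair_index: int,
    cal: CalibrationSet,
    gamma: float,
    mbp_footnote_form: bool = False,
) -> ModelParams:
    """One point-to-point calibration from a single (PTT_i, cuff_i) pair.

    Different ``pair_index`` choices on fluctuating rest data yield
    different parameters — the initial-value sensitivity that mPTP/fPTP
    address.
    """
    if cal.n == 0:
        raise DataError("empty calibration set")
    if not (0 <= pair_index < cal.n):
        raise ValidationError(f"pair_index {pair_index} out of range [0, {cal.n})")
    return ModelParams.from_cuff_pair(
        sbp0=float(cal.cuff_sbp[pair_index]),
        dbp0=float(cal.cuff_dbp[pair_index]),
        ptt0=float(cal.window_medians.ptt_median[pair_index]),
        gamma=gamma,
        mbp_footnote_form=mbp_footnote_form,
    )


def calibrate_mptp(
    cal: CalibrationSet,
    gamma: float,
    mbp_footnote_form: bool = False,
) -> ModelParams:
    """Mean point-to-point calibration over the whole calm segment.

    SBP0/DBP0 are the arithmetic means of the cuff readings; PTT0 is the
    mean of all beat-level PTT samples.
    """
    if cal.n < 2:
        raise ValidationError(
            "mPTP requires at least 2 calibration windows; use oPTP for a single pair"
        )
    return ModelParams.from_cuff_pair(
        sbp0=float(np.mean(cal.cuff_sbp)),
        dbp0=float(np.mean(cal.cuff_dbp)),
        ptt0=cal.ptt_bar,
        gamma=gamma,
        mbp_footnote_form=mbp_footnote_form,
    )


def calibrate_fptp(
    cal: CalibrationSet,
    model: ModelName,
    gamma: float,
    literal_form: bool = False,
    mbp_footnote_form: bool = False,
    return_factors: bool = False,
):
    """Penalty-factor point-to-point calibration.

    Step 1 adjusts PTT0 from the beat-level mean by the PTT penalty
    factor.  Step 2 runs the mPTP-calibrated model (with mPTP's own PTT0)
    over the calibration-window medians, forms signed errors against the
    cuff readings separately for SBP and DBP, and shrinks the cuff means
    by the resulting penalty factors.  PP0/MBP0 are re-derived from the
    adjusted base pressures.

    With ``return_factors=True`` returns ``(ModelParams, PenaltyFactors)``.
    """
    if cal.n < 2:
        raise ValidationError("fPTP requires at least 2 calibration windows")
    mptp = calibrate_mptp(cal, gamma, mbp_footnote_form)

    ptt_bar = cal.ptt_bar
    alpha_ptt = penalty_factor(cal.window_medians.ptt_median - ptt_bar, literal_form)
    ptt0 = ptt_bar * (1.0 - alpha_ptt)

    est_sbp, est_dbp = estimate_bp(cal.window_medians.ptt_median, mptp, model)
    alpha_sbp = penalty_factor(est_sbp - cal.cuff_sbp, literal_form)
    alpha_dbp = penalty_factor(est_dbp - cal.cuff_dbp, literal_form)
    sbp0 = float(np.mean(cal.cuff_sbp)) * (1.0 - alpha_sbp)
    dbp0 = float(np.mean(cal.cuff_dbp)) * (1.0 - alpha_dbp)
    if sbp0 <= dbp0:
        raise DataError(
            f"fPTP adjustment produced SBP0={sbp0:.2f} <= DBP0={dbp0:.2f} "
            f"(alpha_SBP={alpha_sbp:.4f}, alpha_DBP={alpha_dbp:.4f})"
        )
    params = ModelParams.from_cuff_pair(sbp0, dbp0, ptt0, gamma, mbp_footnote_form)
    if return_factors:
        return params, PenaltyFactors(alpha_ptt, alpha_sbp, alpha_dbp)
    return params


def build_calibration_set(
    windows: WindowMedianSeries,
    cuff_times: np.ndarray,
    cuff_sbp: np.ndarray,
    cuff_dbp: np.ndarray,
    beats: BeatPTTSeries,
    duration: Optional[float] = None,
) -> CalibrationSet:
    """Align cuff readings with retained windows and assemble a set.

    Each cuff reading is assigned to the window whose half-open span
    contains its timestamp; readings falling in dropped windows are
    discarded, and windows without a reading are dropped (with their
    median) so the pairing is one-to-one.
    """
    cuff_times = np.asarray(cuff_times, dtype=float)
    cuff_sbp = np.asarray(cuff_sbp, dtype=float)
    cuff_dbp = np.asarray(cuff_dbp, dtype=float)
    w = windows.window_s
    keep_w, keep_c = [], []
    for ci, t in enumerate(cuff_times):
        hits = np.flatnonzero(
            (windows.window_start <= t) & (t < windows.window_start + w)
        )
        if hits.size:
            keep_w.append(int(hits[0]))
            keep_c.append(ci)
    if len(set(keep_w)) != len(keep_w):
        raise DataError("more than one cuff reading falls in the same window")
    if not keep_w:
        raise DataError("no cuff reading falls inside any retained window")
    sub = WindowMedianSeries(
        windows.window_start[keep_w],
        windows.ptt_median[keep_w],
        windows.n_beats[keep_w],
        w,
    )
    if duration is None:
        duration = (
            float(sub.window_start[-1] + w - sub.window_start[0]) if len(sub) else 0.0
        )
    return CalibrationSet(
        window_medians=sub,
        cuff_times=cuff_times[keep_c],
        cuff_sbp=cuff_sbp[keep_c],
        cuff_dbp=cuff_dbp[keep_c],
        beat_ptts=beats,
        duration=duration,
    )
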