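"""Model/Results front door for cuff-less BP estimation.

``CuffLessBP`` bundles a subject's calm-segment calibration data with a
model choice (MK-BH or dMK-BH) and a vascular parameter gamma; ``fit()``
runs one of the point-to-point calibration methods and returns a
``CuffLessBPResults`` carrying the base values, the penalty factors (for
fPTP), calibration-segment residual diagnostics, and prediction /
evaluation / summary methods.

Example
-------
>>> from pttbp.synth import ProtocolConfig, simulate_subject
>>> from pttbp.estimator import CuffLessBP
>>> subj = simulate_subject(ProtocolConfig(seed=7))
>>> res = CuffLessBP(subj.rest_calibration_set(), model="dmkbh").fit("fptp")
>>> sbp, dbp = res.predict(230.0)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationSet,
    PenaltyFactors,
    build_calibration_set,
    calibrate_fptp,
    calibrate_mptp,
    calibrate_optp,
)
from .evaluation import AgreementReport, agreement_report, error_stats
from .exceptions import ValidationError
from .models import DEFAULT_GAMMA, ModelName, ModelParams, estimate_bp
from .signals import SampledSignal, WindowMedianSeries, extract_ptt, window_median_ptt


class CuffLessBP:
    """PTT-based cuff-less blood-pressure model for one subject.

    Parameters
    ----------
    calibration : CalibrationSet
        Calm-segment window medians, aligned cuff readings, and the
        underlying beat-level PTTs.
    model : {'mkbh', 'dmkbh'}
        Estimation equation family.
    gamma : float
        Vascular information parameter, 1/mmHg.
    literal_eq_form, mbp_footnote_form : bool
        Audit switches for the literal typeset penalty-factor expression
        and the non-standard mean-BP footnote form.
    """

    def __init__(
        self,
        calibration: CalibrationSet,
        model: ModelName = "dmkbh",
        gamma: float = DEFAULT_GAMMA,
        literal_eq_form: bool = False,
        mbp_footnote_form: bool = False,
    ) -> None:
        if model not in ("mkbh", "dmkbh"):
            raise ValidationError(f"unknown model {model!r}")
        self.calibration = calibration
        self.model = model
        self.gamma = gamma
        self.literal_eq_form = literal_eq_form
        self.mbp_footnote_form = mbp_footnote_form

    @classmethod
    def from_signals(
        cls,
        ecg: SampledSignal,
        ppg: SampledSignal,
        cuff_times,
        cuff_sbp,
        cuff_dbp,
        window_s: float = 30.0,
        min_beats: int = 10,
        **kwargs,
    ) -> "CuffLessBP":
        """Build the model straight from raw calm-segment waveforms."""
        beats = extract_ptt(ecg, ppg)
        windows = window_median_ptt(beats, window_s=window_s, min_beats=min_beats)
        cal = build_calibration_set(windows, cuff_times, cuff_sbp, cuff_dbp, beats)
        return cls(cal, **kwargs)

    def fit(self, method: str = "fptp", pair_index: int = 0) -> "CuffLessBPResults":
        """Calibrate by 'optp', 'mptp', or 'fptp' and return results."""
        factors: Optional[PenaltyFactors] = None
        if method == "optp":
            params = calibrate_optp(
                pair_index, self.calibration, self.gamma, self.mbp_footnote_form
            )
        elif method == "mptp":
            params = calibrate_mptp(self.calibration, self.gamma, self.mbp_footnote_form)
        elif method == "fptp":
            params, factors = calibrate_fptp(
                self.calibration,
                self.model,
                self.gamma,
                literal_form=self.literal_eq_form,
                mbp_footnote_form=self.mbp_footnote_form,
                return_factors=True,
            )
        else:
            raise ValidationError(f"unknown calibration method {method!r}")
        return CuffLessBPResults(self, method, params, factors)


@dataclass
class CuffLessBPResults:
    """Fitted base values plus diagnostics for one subject."""

    model_obj: CuffLessBP
    method: str
    params: ModelParams
    penalty: Optional[PenaltyFactors] = None

    def predict(self, ptt):
        """(SBP, DBP) at one or more PTT values in ms."""
        return estimate_bp(ptt, self.params, self.model_obj.model)

    def estimate_windows(self, windows: WindowMedianSeries) -> pd.DataFrame:
        """One BP estimate per window median, as a tidy frame."""
        sbp, dbp = self.predict(windows.ptt_median)
        return pd.DataFrame(
            {
                "time_s": windows.window_start,
                "sbp_mmHg": sbp,
                "dbp_mmHg": dbp,
                "model": self.model_obj.model,
                "method": self.method,
            }
        )

    def calibration_residuals(self) -> pd.DataFrame:
        """Errors of the fitted model at the calibration windows."""
        cal = self.model_obj.calibration
        sbp, dbp = self.predict(cal.window_medians.ptt_median)
        return pd.DataFrame(
            {
                "window_start_s": cal.window_medians.window_start,
                "sbp_err_mmHg": sbp - cal.cuff_sbp,
                "dbp_err_mmHg": dbp - cal.cuff_dbp,
            }
        )

    def evaluate(self, windows: WindowMedianSeries, cuff_sbp, cuff_dbp) -> Dict[str, AgreementReport]:
        """Full agreement battery of window estimates against cuff readings."""
        est = self.estimate_windows(windows)
        return {
            "sbp": agreement_report(est["sbp_mmHg"].to_numpy(), np.asarray(cuff_sbp, float)),
            "dbp": agreement_report(est["dbp_mmHg"].to_numpy(), np.asarray(cuff_dbp, float)),
        }

    def summary(self) -> str:
        """Plain-text summary: base values, penalty factors, residuals."""
        cal = self.model_obj.calibration
        p = self.params
        res = self.calibration_residuals()
        lines = [
            "Cuff-less BP calibration results",
            "================================",
            f"model:               {self.model_obj.model}",
            f"calibration method:  {self.method}",
            f"calibration windows: {cal.n}  (duration {cal.duration:.0f} s, "
            f"{len(cal.beat_ptts)} beats)",
            f"gamma:               {p.gamma:g} 1/mmHg",
            "",
            f"SBP0 = {p.sbp0:8.3f} mmHg    DBP0 = {p.dbp0:8.3f} mmHg",
            f"PP0  = {p.pp0:8.3f} mmHg    MBP0 = {p.mbp0:8.3f} mmHg",
            f"PTT0 = {p.ptt0:8.3f} ms",
        ]
        if self.penalty is not None:
            a = self.penalty
            lines += [
                "",
                f"alpha_PTT = {a.alpha_ptt:+.5f}   alpha_SBP = {a.alpha_sbp:+.5f}   "
                f"alpha_DBP = {a.alpha_dbp:+.5f}   (|alpha| <= 1/n = {1.0/cal.n:.5f})",
            ]
        for key, col in (("SBP", "sbp_err_mmHg"), ("DBP", "dbp_err_mmHg")):
            err = res[col].to_numpy()
            if err.size >= 2:
                mean, sd, mad = error_stats(err, np.zeros_like(err))
                lines.append(
                    f"calibration residual {key}: {mean:+.3f} +- {sd:.3f} mmHg (MAD {mad:.3f})"
                )
        return "\n".join(lines)
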