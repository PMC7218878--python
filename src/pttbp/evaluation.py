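"""Agreement and error statistics between estimated and cuff BP.

Covers the standard accuracy battery for cuff-less estimators: mean error
+- sample SD and mean absolute difference (MAD), Bland-Altman bias and 95%
limits of agreement, Pearson correlation, and the AAMI accuracy criterion
(|mean error| <= 5 mmHg and SD <= 8 mmHg, bounds inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

from .exceptions import DataError, ValidationError

#: Two-sided 95% normal quantile used for limits of agreement.
LOA_Z = 1.96

AAMI_MEAN_MMHG = 5.0
AAMI_SD_MMHG = 8.0


@dataclass(frozen=True)
class AgreementReport:
    """Agreement summary for one (method, model, pressure) comparison."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    within_pct: float
    r: float
    mad: float
    aami_pass: bool
    n: int

    def __post_init__(self) -> None:
        if not np.isclose(self.loa_low, self.bias - LOA_Z * self.sd):
            raise ValidationError("loa_low must equal bias - 1.96*sd")
        if not np.isclose(self.loa_high, self.bias + LOA_Z * self.sd):
            raise ValidationError("loa_high must equal bias + 1.96*sd")
        if not (0.0 <= self.within_pct <= 100.0):
            raise ValidationError("within_pct must lie in [0, 100]")
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValidationError("r must lie in [-1, 1]")


def _paired(est, ref, min_n: int) -> Tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise DataError(f"paired 1-D arrays required, got shapes {est.shape} vs {ref.shape}")
    if est.size < min_n:
        raise DataError(f"need at least {min_n} pairs, got {est.size}")
    return est, ref


def error_stats(est, ref) -> Tuple[float, float, float]:
    """Mean error, sample SD (n-1) of errors, and MAD of ``est - ref``."""
    est, ref = _paired(est, ref, 2)
    d = est - ref
    return float(np.mean(d)), float(np.std(d, ddof=1)), float(np.mean(np.abs(d)))


def bland_altman(est, ref) -> Tuple[float, float, float, float, float]:
    """Bland-Altman bias, SD, 95% limits of agreement, and % within.

    Differences are ``est - ref``; the limits are ``bias +- 1.96*sd`` with
    sample SD, and ``within_pct`` counts boundary points as inside.
    """
    est, ref = _paired(est, ref, 2)
    d = est - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low = bias - LOA_Z * sd
    loa_high = bias + LOA_Z * sd
    within = np.abs(d - bias) <= LOA_Z * sd
    return bias, sd, loa_low, loa_high, float(100.0 * np.mean(within))


def pearson_r(est, ref) -> float:
    """Product-moment correlation between estimates and reference."""
    est, ref = _paired(est, ref, 3)
    if np.std(est) == 0.0 or np.std(ref) == 0.0:
        raise DataError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(est, ref).statistic)


def aami_check(mean: float, sd: float) -> bool:
    """AAMI accuracy verdict: |mean| <= 5 mmHg and SD <= 8 mmHg (inclusive)."""
    return abs(mean) <= AAMI_MEAN_MMHG and sd <= AAMI_SD_MMHG


def agreement_report(est, ref) -> AgreementReport:
    """Full agreement battery on one paired series."""
    bias, sd, loa_low, loa_high, within = bland_altman(est, ref)
    _, _, mad = error_stats(est, ref)
    r = pearson_r(est, ref)
    return AgreementReport(
        bias=bias,
        sd=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        within_pct=within,
        r=r,
        mad=mad,
        aami_pass=aami_check(bias, sd),
        n=int(np.asarray(est).size),
    )
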