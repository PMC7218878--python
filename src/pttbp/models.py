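"""Closed-form PTT -> blood-pressure estimation models.

Two models relate pulse transit time (PTT) to arterial pressure, both
descended from the Moens-Korteweg relation between pulse-wave velocity and
arterial elasticity:

* **MK-BH** — systolic pressure is affine in PTT and diastolic pressure
  follows from the Bramwell-Hill pulse-pressure term::

      SBP = SBP0 - (2 / gamma) * (PTT - PTT0) / PTT0
      DBP = SBP - PP0 * (PTT0 / PTT)**2

* **dMK-BH** — diastolic pressure is anchored to mean pressure with a
  logarithmic elasticity term; systolic pressure adds the same
  pulse-pressure term::

      DBP = MBP0 + (2 / gamma) * ln(PTT0 / PTT) - (PP0 / 3) * (PTT0 / PTT)**2
      SBP = DBP + PP0 * (PTT0 / PTT)**2

Base values (``SBP0``, ``DBP0``, ``PP0``, ``MBP0``, ``PTT0``) are fixed once
per subject by calibration against a cuff device and never change during
monitoring.  ``gamma`` is the vascular information parameter (1/mmHg); it
scales the pressure-elasticity relation and is subject- and age-dependent.

Both models satisfy the calibration-point identity: at ``PTT == PTT0`` they
return exactly ``(SBP0, DBP0)``.  The MK-BH linear term is written with the
``(PTT - PTT0) / PTT0`` ratio so the PTT unit cancels; either model gives
identical output whether PTT0 and PTT are both in ms or both in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Tuple

import numpy as np

from .exceptions import ValidationError

ModelName = Literal["mkbh", "dmkbh"]

#: Default vascular information parameter, 1/mmHg.  A typical literature
#: magnitude for young healthy adults; it must be supplied explicitly in any
#: quantitative use and is echoed in every output header.
DEFAULT_GAMMA = 0.017


def mean_bp(sbp: float, dbp: float, footnote_form: bool = False) -> float:
    """Mean blood pressure from systolic and diastolic pressure.

    The standard hemodynamic estimate is ``DBP + PP/3``.  The alternative
    ``(PP + DBP) / 3`` (``footnote_form=True``) is retained for auditability
    only: it breaks the dMK-BH calibration-point identity and is not used by
    default.
    """
    pp = sbp - dbp
    if footnote_form:
        return (pp + dbp) / 3.0
    return dbp + pp / 3.0


@dataclass(frozen=True)
class ModelParams:
    """Per-subject base values fixing one estimation model.

    Attributes
    ----------
    sbp0, dbp0 : float
        Base systolic / diastolic pressure, mmHg.
    pp0 : float
        Base pulse pressure ``sbp0 - dbp0``, mmHg.
    mbp0 : float
        Base mean pressure, mmHg (``dbp0 + pp0/3`` unless the audit
        footnote form was requested).
    ptt0 : float
        Base pulse transit time, ms.
    gamma : float
        Vascular information parameter, 1/mmHg.
    """

    sbp0: float
    dbp0: float
    pp0: float
    mbp0: float
    ptt0: float
    gamma: float
    mbp_footnote_form: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.sbp0 > self.dbp0 > 0):
            raise ValidationError(
                f"require SBP0 > DBP0 > 0, got SBP0={self.sbp0}, DBP0={self.dbp0}"
            )
        if self.ptt0 <= 0:
            raise ValidationError(f"PTT0 must be positive, got {self.ptt0}")
        if self.gamma <= 0:
            raise ValidationError(f"gamma must be positive, got {self.gamma}")
        if not math.isclose(self.pp0, self.sbp0 - self.dbp0, abs_tol=1e-9):
            raise ValidationError("PP0 must equal SBP0 - DBP0")
        expected_mbp = mean_bp(self.sbp0, self.dbp0, self.mbp_footnote_form)
        if not math.isclose(self.mbp0, expected_mbp, abs_tol=1e-9):
            raise ValidationError(
                f"MBP0={self.mbp0} inconsistent with SBP0/DBP0 (expected {expected_mbp})"
            )

    @classmethod
    def from_cuff_pair(
        cls,
        sbp0: float,
        dbp0: float,
        ptt0: float,
        gamma: float,
        mbp_footnote_form: bool = False,
    ) -> "ModelParams":
        """Build a full parameter set from one (SBP, DBP, PTT) triple,
        deriving PP0 and MBP0."""
        return cls(
            sbp0=sbp0,
            dbp0=dbp0,
            pp0=sbp0 - dbp0,
            mbp0=mean_bp(sbp0, dbp0, mbp_footnote_form),
            ptt0=ptt0,
            gamma=gamma,
            mbp_footnote_form=mbp_footnote_form,
        )

    def with_base(self, sbp0: float, dbp0: float) -> "ModelParams":
        """Copy with new base pressures, re-deriving PP0/MBP0."""
        return ModelParams.from_cuff_pair(
            sbp0, dbp0, self.ptt0, self.gamma, self.mbp_footnote_form
        )


def _check_ptt(ptt) -> np.ndarray:
    arr = np.asarray(ptt, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("PTT must be positive")
    return arr


def mkbh_estimate(ptt, params: ModelParams) -> Tuple[np.ndarray, np.ndarray]:
    """MK-BH estimate of (SBP, DBP) at one or more PTT values in ms.

    SBP decreases affinely in PTT with slope ``-2/(gamma*PTT0)``; DBP is
    SBP minus the Bramwell-Hill pulse-pressure term.  Scalar input returns
    scalar-like 0-d arrays; array input is vectorised.
    """
    arr = _check_ptt(ptt)
    ratio = params.ptt0 / arr
    sbp = params.sbp0 - (2.0 / params.gamma) * (arr - params.ptt0) / params.ptt0
    dbp = sbp - params.pp0 * ratio**2
    return sbp, dbp


def dmkbh_estimate(ptt, params: ModelParams) -> Tuple[np.ndarray, np.ndarray]:
    """dMK-BH estimate of (SBP, DBP) at one or more PTT values in ms.

    DBP is anchored to mean pressure with a logarithmic term; SBP adds the
    pulse-pressure power term, so ``sbp - dbp = PP0*(PTT0/PTT)**2 > 0``
    whenever ``PP0 > 0``.
    """
    arr = _check_ptt(ptt)
    ratio = params.ptt0 / arr
    dbp = (
        params.mbp0
        + (2.0 / params.gamma) * np.log(ratio)
        - (params.pp0 / 3.0) * ratio**2
    )
    sbp = dbp + params.pp0 * ratio**2
    return sbp, dbp


_ESTIMATORS = {"mkbh": mkbh_estimate, "dmkbh": dmkbh_estimate}


def estimate_bp(ptt, params: ModelParams, model: ModelName) -> Tuple[np.ndarray, np.ndarray]:
    """Dispatch to the named model ('mkbh' or 'dmkbh')."""
    try:
        fn = _ESTIMATORS[model]
    except KeyError:
        raise ValidationError(f"unknown model {model!r}; expected 'mkbh' or 'dmkbh'")
    return fn(ptt, params)
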