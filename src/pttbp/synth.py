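"""Synthetic subjects: programmed PTT/BP trajectories, cuff readings, and
optional ECG/PPG waveforms with known beat-level delays.

The generator emulates a rest-plus-exercise-recovery session: a calm
calibration segment (default 5 min) with small autocorrelated PTT
fluctuations, then three treadmill bouts (which produce no data — the
subject is running) each followed by a 7-min seated recovery in which PTT
starts depressed (BP elevated) and relaxes exponentially back to
baseline.  A cuff reading is emitted once per 30-s window.

Ground truth: beat-level PTT is programmed directly; per-beat "true" BP is
the dMK-BH model evaluated at that PTT with the subject's true
parameters; each cuff reading is the model BP at the window's median PTT
plus independent Gaussian device noise.  Because truth is known at every
beat, every downstream stage (peak detection, pairing, windowing,
calibration, estimation, evaluation) can be tested against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .calibration import CalibrationSet, build_calibration_set
from .exceptions import ValidationError
from .models import ModelParams, dmkbh_estimate
from .signals import (
    BeatPTTSeries,
    SampledSignal,
    WindowMedianSeries,
    window_median_ptt,
)

#: Lag-1 coefficient of the rest-state AR(1) PTT fluctuation.
AR1_PHI = 0.9


def _default_true_params() -> ModelParams:
    return ModelParams.from_cuff_pair(sbp0=120.0, dbp0=80.0, ptt0=250.0, gamma=0.017)


@dataclass(frozen=True)
class ProtocolConfig:
    """Session layout and noise levels for one synthetic subject.

    Durations are in s, PTT quantities in ms, pressures in mmHg.  The
    defaults mirror the emulated protocol: 5-min rest, three 3-min
    treadmill bouts of increasing intensity each followed by a 7-min
    recovery, and one cuff reading per 30-s window.  ``exercise_ptt_drop``
    is the PTT depression per intensity step at the start of each
    recovery; ``recovery_tau`` is the exponential relaxation time back to
    baseline.  ``seed`` is mandatory: all stochastic output derives from it.
    """

    seed: int
    rest_s: float = 300.0
    n_tasks: int = 3
    task_s: float = 180.0
    recovery_s: float = 420.0
    cuff_interval_s: float = 30.0
    true_params: ModelParams = field(default_factory=_default_true_params)
    ptt_noise_sd: float = 3.0
    cuff_noise_sd: float = 2.0
    exercise_ptt_drop: float = 30.0
    recovery_tau: float = 120.0
    hr_bpm: float = 70.0
    min_beats_per_window: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory for stochastic output")
        for name in ("rest_s", "task_s", "recovery_s", "cuff_interval_s", "hr_bpm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_tasks < 0:
            raise ValidationError("n_tasks must be >= 0")
        for name in ("ptt_noise_sd", "cuff_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.recovery_tau <= 0:
            raise ValidationError("recovery_tau must be positive")


@dataclass(frozen=True)
class SyntheticSubject:
    """One simulated session with full ground truth."""

    config: ProtocolConfig
    beat_ptts: BeatPTTSeries
    true_sbp: np.ndarray
    true_dbp: np.ndarray
    cuff_times: np.ndarray
    cuff_sbp: np.ndarray
    cuff_dbp: np.ndarray
    #: (start_s, end_s, label) for each data-producing segment
    segments: Tuple[Tuple[float, float, str], ...]

    @property
    def rest_end(self) -> float:
        return self.config.rest_s

    def windows(self, segment: Optional[str] = None) -> WindowMedianSeries:
        """Window medians of the programmed beat PTTs, optionally restricted
        to one segment label ('rest', 'recovery1', ...)."""
        beats = self.beat_ptts
        if segment is not None:
            lo, hi = next((a, b) for a, b, lab in self.segments if lab == segment)
            mask = (beats.beat_times >= lo) & (beats.beat_times < hi)
            beats = BeatPTTSeries(beats.beat_times[mask], beats.ptt[mask])
        return window_median_ptt(
            beats,
            window_s=self.config.cuff_interval_s,
            min_beats=self.config.min_beats_per_window,
        )

    def cuff_in(self, lo: float, hi: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        mask = (self.cuff_times >= lo) & (self.cuff_times < hi)
        return self.cuff_times[mask], self.cuff_sbp[mask], self.cuff_dbp[mask]

    def rest_calibration_set(self) -> CalibrationSet:
        """The calm-segment calibration set (windows, cuff, beat PTTs)."""
        lo, hi = 0.0, self.config.rest_s
        beats = self.beat_ptts
        mask = (beats.beat_times >= lo) & (beats.beat_times < hi)
        rest_beats = BeatPTTSeries(beats.beat_times[mask], beats.ptt[mask])
        ct, cs, cd = self.cuff_in(lo, hi)
        return build_calibration_set(
            self.windows("rest"), ct, cs, cd, rest_beats, duration=hi - lo
        )


def _segment_layout(cfg: ProtocolConfig) -> List[Tuple[float, float, str]]:
    segs = [(0.0, cfg.rest_s, "rest")]
    t = cfg.rest_s
    for k in range(1, cfg.n_tasks + 1):
        t += cfg.task_s  # treadmill bout: no data
        segs.append((t, t + cfg.recovery_s, f"recovery{k}"))
        t += cfg.recovery_s
    return segs


def simulate_subject(cfg: ProtocolConfig) -> SyntheticSubject:
    """Generate one subject's beat-level PTT, true BP, and cuff readings.

    Rest-segment PTT is ``PTT0_true`` plus stationary AR(1) noise
    (lag-1 coefficient 0.9, stationary SD ``ptt_noise_sd``); recovery
    segment ``k`` starts ``k * exercise_ptt_drop`` ms below baseline and
    relaxes exponentially with time constant ``recovery_tau``, with the
    same AR(1) fluctuation superimposed.  True per-beat BP is the dMK-BH
    forward model at the programmed PTT; cuff readings are the forward
    model at each 30-s window's median PTT plus Gaussian noise.  Output is
    fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.true_params
    rr = 60.0 / cfg.hr_bpm
    segs = _segment_layout(cfg)

    beat_times: List[np.ndarray] = []
    ptt_det: List[np.ndarray] = []
    for lo, hi, label in segs:
        t = np.arange(lo, hi, rr)
        beat_times.append(t)
        if label == "rest":
            ptt_det.append(np.full(t.size, p.ptt0))
        else:
            k = int(label.removeprefix("recovery"))
            drop = k * cfg.exercise_ptt_drop
            ptt_det.append(p.ptt0 - drop * np.exp(-(t - lo) / cfg.recovery_tau))
    times = np.concatenate(beat_times)
    ptt = np.concatenate(ptt_det)

    if cfg.ptt_noise_sd > 0:
        n = times.size
        innov_sd = cfg.ptt_noise_sd * np.sqrt(1.0 - AR1_PHI**2)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, cfg.ptt_noise_sd)
        shocks = rng.normal(0.0, innov_sd, size=n - 1)
        for i in range(1, n):
            noise[i] = AR1_PHI * noise[i - 1] + shocks[i - 1]
        ptt = ptt + noise
    ptt = np.maximum(ptt, 1.0)  # guard: PTT must stay positive

    beats = BeatPTTSeries(times, ptt)
    true_sbp, true_dbp = dmkbh_estimate(ptt, p)

    windows = window_median_ptt(
        beats, window_s=cfg.cuff_interval_s, min_beats=cfg.min_beats_per_window
    )
    cuff_sbp_clean, cuff_dbp_clean = dmkbh_estimate(windows.ptt_median, p)
    cuff_sbp = np.array(cuff_sbp_clean, dtype=float)
    cuff_dbp = np.array(cuff_dbp_clean, dtype=float)
    if cfg.cuff_noise_sd > 0:
        cuff_sbp = cuff_sbp + rng.normal(0.0, cfg.cuff_noise_sd, size=cuff_sbp.size)
        cuff_dbp = cuff_dbp + rng.normal(0.0, cfg.cuff_noise_sd, size=cuff_dbp.size)
        bad = cuff_sbp <= cuff_dbp
        tries = 0
        while np.any(bad) and tries < 100:
            warnings.warn(
                f"resampling {int(bad.sum())} cuff reading(s) with SBP <= DBP",
                stacklevel=2,
            )
            cuff_sbp[bad] = cuff_sbp_clean[bad] + rng.normal(
                0.0, cfg.cuff_noise_sd, size=int(bad.sum())
            )
            cuff_dbp[bad] = cuff_dbp_clean[bad] + rng.normal(
                0.0, cfg.cuff_noise_sd, size=int(bad.sum())
            )
            bad = cuff_sbp <= cuff_dbp
            tries += 1
    cuff_times = windows.window_start + cfg.cuff_interval_s / 2.0

    return SyntheticSubject(
        config=cfg,
        beat_ptts=beats,
        true_sbp=np.asarray(true_sbp),
        true_dbp=np.asarray(true_dbp),
        cuff_times=cuff_times,
        cuff_sbp=cuff_sbp,
        cuff_dbp=cuff_dbp,
        segments=tuple(segs),
    )


def synth_waveforms(
    beats: BeatPTTSeries,
    fs: float,
    snr_db: float = 20.0,
    seed: Optional[int] = None,
    duration: Optional[float] = None,
    ecg_sigma_s: float = 0.010,
    ppg_apex_s: float = 0.015,
    ppg_rise_s: float = 0.050,
    ppg_fall_s: float = 0.120,
    ppg_base_amp: float = 0.5,
) -> Tuple[SampledSignal, SampledSignal]:
    """Render ECG/PPG waveforms whose R->PPG-peak delays equal the beat PTTs.

    The ECG is a train of narrow Gaussian templates centred on the beat
    times.  Each PPG pulse is a sharp systolic apex (Gaussian, SD
    ``ppg_apex_s``) riding on a broader asymmetric volume wave (fast rise,
    slow fall), both peaking at ``beat_time + ptt`` — the distinct apex
    keeps the peak's location well-defined under band-pass filtering and
    noise, as in real finger PPG.  White Gaussian noise is added so the
    template peak amplitude sits ``snr_db`` above the noise SD.  Peak
    times are representable exactly only to one sample.
    """
    if fs < 250:
        raise ValidationError(f"waveform synthesis requires fs >= 250 Hz, got {fs}")
    n_beats = len(beats)
    if n_beats > 1:
        min_rr = float(np.min(np.diff(beats.beat_times)))
        width = 3.0 * max(ecg_sigma_s, ppg_fall_s)
        if min_rr < width:
            raise ValidationError(
                f"beat spacing {min_rr:.3f} s below template width {width:.3f} s"
            )
    if n_beats == 0:
        if duration is None:
            raise ValidationError("duration required when there are no beats")
        n = int(round(duration * fs))
        zero = np.zeros(max(n, 1))
        return SampledSignal(zero, fs), SampledSignal(zero.copy(), fs)

    t_end = beats.beat_times[-1] + beats.ptt[-1] / 1000.0 + 0.5
    if duration is not None:
        t_end = max(t_end, duration)
    t = np.arange(0.0, t_end, 1.0 / fs)
    ecg = np.zeros_like(t)
    ppg = np.zeros_like(t)

    def _add_pulse(
        y: np.ndarray, centre: float, sig_l: float, sig_r: float, amp: float = 1.0
    ) -> None:
        lo = max(0, int((centre - 5 * sig_l) * fs))
        hi = min(t.size, int((centre + 5 * sig_r) * fs) + 1)
        seg = t[lo:hi] - centre
        sig = np.where(seg < 0, sig_l, sig_r)
        y[lo:hi] += amp * np.exp(-0.5 * (seg / sig) ** 2)

    for bt, ptt_ms in zip(beats.beat_times, beats.ptt):
        _add_pulse(ecg, bt, ecg_sigma_s, ecg_sigma_s)
        apex = bt + ptt_ms / 1000.0
        _add_pulse(ppg, apex, ppg_apex_s, ppg_apex_s)
        _add_pulse(ppg, apex, ppg_rise_s, ppg_fall_s, ppg_base_amp)

    if np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        noise_sd = 10.0 ** (-snr_db / 20.0)
        ecg = ecg + rng.normal(0.0, noise_sd, size=ecg.size)
        ppg = ppg + rng.normal(0.0, noise_sd, size=ppg.size)
    return SampledSignal(ecg, fs), SampledSignal(ppg, fs)
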