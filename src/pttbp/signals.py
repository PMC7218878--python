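"""Waveform filtering, peak detection, beat pairing, and PTT windowing.

The measurement chain turns synchronously sampled ECG and PPG waveforms
into a beat-level pulse-transit-time (PTT) stream and its 30-s window
medians:

1. zero-phase band-pass filtering (ECG 1-40 Hz, PPG 0.5-20 Hz by
   convention for this acquisition chain);
2. peak detection (ECG R peaks, PPG systolic peaks) with a refractory
   period;
3. pairing each R peak with the earliest following PPG peak inside a
   physiologic delay window — that delay is the beat's PTT;
4. per-window medians of the beat PTTs, one value per non-overlapping
   30-s window.

Peak detection here is a contract, not a fixed algorithm: any detector
that finds one peak per true beat (at adequate SNR) with a >= 250 ms
refractory period is conformant.  The shipped default uses band-limited
energy with a block-adaptive threshold, then refines each candidate to
the local maximum of the filtered waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps

from .exceptions import ValidationError

PeakKind = Literal["R_peak", "PPG_peak"]

# conventional cut-offs for this acquisition chain, Hz
ECG_BAND = (1.0, 40.0)
PPG_BAND = (0.5, 20.0)

#: Minimum separation between successive peaks, s (physiologic refractory).
REFRACTORY_S = 0.25

#: Default physiologic R-peak -> finger-PPG-peak delay bounds, ms.  The
#: lower bound excludes pre-ejection artefacts, the upper excludes capture
#: of the next beat's pulse.
DEFAULT_MIN_DELAY_MS = 100.0
DEFAULT_MAX_DELAY_MS = 600.0

DEFAULT_WINDOW_S = 30.0
DEFAULT_MIN_BEATS = 10


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled waveform (arbitrary units)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValidationError(f"sampling frequency must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D array")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class PeakTrain:
    """Strictly increasing peak times (s) of one kind."""

    times: np.ndarray
    kind: PeakKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BeatPTTSeries:
    """Per-beat (R-peak time, PTT) pairs; times in s, PTT in ms."""

    beat_times: np.ndarray
    ptt: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beat_times", np.asarray(self.beat_times, dtype=float))
        object.__setattr__(self, "ptt", np.asarray(self.ptt, dtype=float))
        if self.beat_times.shape != self.ptt.shape:
            raise ValidationError("beat_times and ptt must have equal length")
        if self.beat_times.size > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValidationError("beat_times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.beat_times.size)


@dataclass(frozen=True)
class WindowMedianSeries:
    """Non-overlapping fixed-length window medians of beat PTT.

    ``window_start`` holds the left edge of each retained half-open window
    ``[start, start + window_s)``; windows with fewer than the configured
    minimum number of beats are omitted entirely.
    """

    window_start: np.ndarray
    ptt_median: np.ndarray
    n_beats: np.ndarray
    window_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "window_start", np.asarray(self.window_start, dtype=float))
        object.__setattr__(self, "ptt_median", np.asarray(self.ptt_median, dtype=float))
        object.__setattr__(self, "n_beats", np.asarray(self.n_beats, dtype=int))
        if not (self.window_start.shape == self.ptt_median.shape == self.n_beats.shape):
            raise ValidationError("window fields must have equal length")
        if self.window_s <= 0:
            raise ValidationError("window_s must be positive")

    def __len__(self) -> int:
        return int(self.window_start.size)


def bandpass_filter(sig: SampledSignal, low_hz: float, high_hz: float) -> SampledSignal:
    """Zero-phase Butterworth band-pass.

    Zero-phase (forward-backward) filtering is used so peak times are not
    lag-shifted by the filter.  The band must sit strictly inside
    (0, Nyquist).
    """
    nyq = sig.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValidationError(
            f"invalid band [{low_hz}, {high_hz}] Hz for fs={sig.fs} Hz "
            f"(need 0 < low < high < {nyq})"
        )
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=sig.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, sig.samples)
    return SampledSignal(filtered, sig.fs, sig.t0)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_peaks(
    sig: SampledSignal,
    kind: PeakKind,
    refractory_s: float = REFRACTORY_S,
    block_s: float = 10.0,
) -> PeakTrain:
    """Detect beat peaks in a filtered waveform.

    Band-limited energy (squared signal smoothed over ~150 ms) is
    thresholded block-by-block at a fraction of the block's energy maximum,
    with a global floor so silent blocks produce nothing.  Candidates are
    separated by at least ``refractory_s``; each is then refined to the
    nearest local maximum of the waveform itself within +-100 ms so the
    reported time is the actual R / PPG peak, not the energy centroid.

    A flat or near-flat signal yields an empty train with a warning rather
    than an error.
    """
    if sig.fs < 100:
        raise ValidationError(f"peak detection requires fs >= 100 Hz, got {sig.fs}")
    x = sig.samples - np.median(sig.samples)
    if x.size < 3 or np.ptp(x) == 0.0:
        warnings.warn(f"flat or empty signal: no {kind} peaks detected", stacklevel=2)
        return PeakTrain(np.empty(0), kind)

    energy = _moving_average(x**2, int(round(0.15 * sig.fs)))
    gmax = energy.max()
    if gmax <= 0:
        warnings.warn(f"zero-energy signal: no {kind} peaks detected", stacklevel=2)
        return PeakTrain(np.empty(0), kind)

    # block-adaptive threshold: 25% of local max, floored by both a global
    # fraction and a robust noise estimate (beats occupy a minority of the
    # record, so the energy median tracks the noise floor)
    noise_floor = 4.0 * float(np.median(energy))
    block = max(1, int(round(block_s * sig.fs)))
    thresh = np.empty_like(energy)
    for start in range(0, energy.size, block):
        seg = energy[start : start + block]
        thresh[start : start + block] = max(0.25 * seg.max(), 0.05 * gmax, noise_floor)

    dist = max(1, int(round(refractory_s * sig.fs)))
    cand, _ = sps.find_peaks(energy, distance=dist)
    cand = cand[energy[cand] >= thresh[cand]]

    # refine to the waveform's own local maximum near each candidate
    half = int(round(0.10 * sig.fs))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    idx = np.unique(refined)
    # re-impose refractory after refinement (keep the larger peak of a close pair)
    keep: list[int] = []
    for i in idx:
        if keep and (i - keep[-1]) < dist:
            if x[i] > x[keep[-1]]:
                keep[-1] = int(i)
        else:
            keep.append(int(i))

    # amplitude consistency: spurious noise candidates sit far below the
    # typical beat amplitude
    if keep:
        med_amp = float(np.median(x[keep]))
        keep = [i for i in keep if x[i] >= 0.4 * med_amp]

    # sub-sample localisation: least-squares parabola over +-8 ms around the
    # apex; averages sampling quantisation and residual noise jitter down
    fit_half = max(2, int(round(0.008 * sig.fs)))
    times = []
    for i in keep:
        lo, hi = i - fit_half, i + fit_half + 1
        if lo < 0 or hi > x.size:
            times.append(i / sig.fs)
            continue
        u = np.arange(lo, hi, dtype=float) - i
        a, b, _ = np.polyfit(u, x[lo:hi], 2)
        offset = -b / (2.0 * a) if a < 0 else 0.0
        offset = float(np.clip(offset, -fit_half, fit_half))
        times.append((i + offset) / sig.fs)
    return PeakTrain(sig.t0 + np.asarray(times), kind)


def pair_beats(
    r: PeakTrain,
    p: PeakTrain,
    min_delay_ms: float = DEFAULT_MIN_DELAY_MS,
    max_delay_ms: float = DEFAULT_MAX_DELAY_MS,
) -> BeatPTTSeries:
    """Match each R peak to the earliest PPG peak in ``(R+min, R+max]``.

    The delay of the matched pair is the beat's PTT (ms).  Each PPG peak is
    used at most once; R peaks with no admissible PPG peak are dropped.
    """
    if not (0 < min_delay_ms < max_delay_ms):
        raise ValidationError(
            f"require 0 < min_delay < max_delay, got ({min_delay_ms}, {max_delay_ms}) ms"
        )
    lo = min_delay_ms / 1000.0
    hi = max_delay_ms / 1000.0
    beat_times: list[float] = []
    ptts: list[float] = []
    j = 0
    ppg = p.times
    for rt in r.times:
        while j < ppg.size and ppg[j] <= rt + lo:
            j += 1
        if j < ppg.size and ppg[j] <= rt + hi:
            beat_times.append(rt)
            ptts.append((ppg[j] - rt) * 1000.0)
            j += 1  # each PPG peak used at most once
    return BeatPTTSeries(np.asarray(beat_times), np.asarray(ptts))


def window_median_ptt(
    beats: BeatPTTSeries,
    window_s: float = DEFAULT_WINDOW_S,
    min_beats: int = DEFAULT_MIN_BEATS,
    origin: float = 0.0,
) -> WindowMedianSeries:
    """Median beat PTT per half-open window ``[origin + k*w, origin + (k+1)*w)``.

    Windows containing fewer than ``min_beats`` beats are omitted.  Medians
    of even-length sets are the mean of the two central values (numpy
    convention).
    """
    if window_s <= 0:
        raise ValidationError(f"window_s must be positive, got {window_s}")
    if len(beats) == 0:
        return WindowMedianSeries(np.empty(0), np.empty(0), np.empty(0, dtype=int), window_s)
    k = np.floor((beats.beat_times - origin) / window_s).astype(int)
    starts, medians, counts = [], [], []
    for kk in np.unique(k):
        mask = k == kk
        n = int(mask.sum())
        if n < min_beats:
            continue
        starts.append(origin + kk * window_s)
        medians.append(float(np.median(beats.ptt[mask])))
        counts.append(n)
    return WindowMedianSeries(
        np.asarray(starts), np.asarray(medians), np.asarray(counts, dtype=int), window_s
    )


def extract_ptt(
    ecg: SampledSignal,
    ppg: SampledSignal,
    min_delay_ms: float = DEFAULT_MIN_DELAY_MS,
    max_delay_ms: float = DEFAULT_MAX_DELAY_MS,
) -> BeatPTTSeries:
    """Full chain: filter both waveforms, detect peaks, pair beats."""
    ecg_f = bandpass_filter(ecg, *ECG_BAND)
    ppg_f = bandpass_filter(ppg, *PPG_BAND)
    r = detect_peaks(ecg_f, "R_peak")
    p = detect_peaks(ppg_f, "PPG_peak")
    if len(r) == 0 or len(p) == 0:
        return BeatPTTSeries(np.empty(0), np.empty(0))
    return pair_beats(r, p, min_delay_ms, max_delay_ms)
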