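# Methods

This note documents the models, the calibration procedures, the synthetic
data generator, and the numerical and design choices behind `pttbp`.

## Estimation models

Both models map pulse transit time (PTT, ms) to blood pressure (mmHg)
given per-subject base values fixed at calibration time.

**MK-BH.**  SBP is affine in PTT with slope `−2/(γ·PTT₀)`; DBP follows by
subtracting the Bramwell–Hill pulse-pressure term `PP₀·(PTT₀/PTT)²`.  The
linear term is implemented as `(2/γ)·(PTT − PTT₀)/PTT₀` so that the PTT
unit cancels: expressing PTT₀ and PTT both in ms or both in s yields
identical pressures.

**dMK-BH.**  DBP is anchored to the base mean pressure with a logarithmic
elasticity term, `DBP = MBP₀ + (2/γ)·ln(PTT₀/PTT) − (PP₀/3)·(PTT₀/PTT)²`,
and SBP adds the pulse-pressure term, so SBP − DBP > 0 whenever PP₀ > 0.

**Mean pressure convention.**  MBP₀ = DBP₀ + PP₀/3, the standard
hemodynamic estimate.  This is the only convention under which the dMK-BH
model satisfies the calibration-point identity — returning exactly
(SBP₀, DBP₀) at PTT = PTT₀ — which the whole calibration logic relies on.
The non-standard variant MBP₀ = (PP₀ + DBP₀)/3 appears in parts of the
literature; it is available behind the `mbp_footnote_form` switch strictly
for comparison and breaks the identity by construction.

**γ.**  The vascular information parameter (1/mmHg) is subject- and
age-dependent and cannot be identified from a single calm segment; no
value is universal.  The package default is 0.017 mmHg⁻¹, a typical
literature magnitude for young healthy adults.  γ is a mandatory,
explicitly logged configuration field: every output file header carries
it.

## Signal chain

* **Filtering** — zero-phase (forward–backward) 4th-order Butterworth
  band-pass; ECG 1–40 Hz, PPG 0.5–20 Hz at 1 kHz sampling.  Zero-phase
  filtering is chosen so peak *times* are not lag-shifted; only the
  cut-offs are contractual.
* **Peak detection** — a contract, not a fixed algorithm: one detected
  peak per true beat at adequate SNR, with a ≥ 250 ms refractory period.
  The shipped detector computes band-limited energy (squared signal
  smoothed over 150 ms), thresholds it block-by-block at 25% of the local
  maximum with a global floor (5% of the global maximum, and 4× the
  energy median as a robust noise floor), enforces the refractory
  distance, refines each candidate to the waveform's local maximum within
  ±100 ms, drops candidates below 40% of the median accepted amplitude,
  and finally localises each peak to sub-sample precision with a
  least-squares parabola over ±8 ms.  Flat signals yield an empty train
  with a warning, not an error.
* **Beat pairing** — each R peak is matched to the *earliest* PPG peak in
  `(R + 100 ms, R + 600 ms]`; each PPG peak is used at most once;
  unmatched R peaks are dropped.  The bounds cover the physiologic
  R-to-finger-PPG delay range and exclude capture of the next beat.
* **Windowing** — non-overlapping half-open windows `[k·30, (k+1)·30) s`;
  a window's PTT median is reported only when it holds ≥ 10 beats.
  Medians of even-length sets are the mean of the two central values.

Units are fixed throughout: time s, PTT ms, fs Hz, pressure mmHg; all
conversions happen at type boundaries.

## Calibration

Calibration runs once per subject on a calm segment (default 5 min, ten
30-s windows, one cuff reading per window); the resulting parameters are
immutable.

* **oPTP** takes a single (PTTᵢ, SBPᵢ, DBPᵢ) triple (default: the first
  window; `pair_index` selects others to reproduce initial-sensitivity
  experiments).
* **mPTP** takes the arithmetic means of the cuff readings and the mean
  of all beat-level PTTs.
* **fPTP** applies the penalty factor `α = Σdᵢ/(n·Σ|dᵢ|)` — a bounded
  (|α| ≤ 1/n), signed relative-bias statistic — to each base value via
  `x₀ = x̄·(1 − α)`.  Step 1 adjusts PTT₀ with deviations of the window
  medians about the beat-level mean.  Step 2 runs the mPTP-calibrated
  model (with mPTP's own PTT₀) over the window medians and uses its
  signed errors against the cuff, separately for SBP and DBP, since the
  two errors generally differ in sign and size.  PP₀/MBP₀ are re-derived
  from the adjusted pressures, and an adjustment that would produce
  SBP₀ ≤ DBP₀ is rejected with the offending α named.

**Penalty-factor form.**  The absolute-deviation denominator is the
canonical form: with signed deviations in both numerator and denominator
the expression degenerates to 1/n (or 0/0), which cannot act as the
intended negative feedback.  The literal degenerate form is retained
behind `literal_eq_form` for auditability.  A zero denominator (all
deviations vanish) returns α = 0 — no adjustment — rather than failing.

**A structural property worth knowing.**  Because mPTP sets SBP₀/DBP₀ to
the cuff means, the mPTP model's *mean* error over the calibration
windows is close to zero by construction; at rest, model
mis-specification (e.g., a wrong γ) produces errors whose sign tracks
`PTTᵢ − PTT̄` and largely cancels.  The fPTP deviations are then
noise-dominated, and since the correction magnitude scales with
`x̄/n` (≈ 12 mmHg for SBP at n = 10) rather than with the size of the
bias, fPTP can move base values *away* from the optimum when no genuine
systematic offset is present in the calm segment.  In the replicate
experiment shipped with the acceptance script (100 synthetic subjects,
dMK-BH truth, calibration with γ inflated 1.5×), fPTP improves on mPTP's
calibration-window MAD in a minority of replicates, while mPTP beats the
worst-pair oPTP in every replicate.  On real calm-segment data carrying
genuine systematic deviations (device offsets, drift), the correction has
a consistent sign to latch onto; the mean-matched synthetic rest segment
deliberately contains none.

## Synthetic subjects

The generator emulates a rest-plus-exercise-recovery protocol: 5 min calm
rest, then three 3-min treadmill bouts of increasing intensity (producing
no data — the subject is running), each followed by a 7-min seated
recovery; one cuff reading per 30-s window (10 calibration pairs, 42
recovery pairs).

* **Rest PTT** — baseline PTT₀ plus stationary AR(1) noise (lag-1
  coefficient 0.9, stationary SD 3 ms): calm-state PTT fluctuates slowly,
  not as white noise.
* **Recovery PTT** — starts `k·30 ms` below baseline for intensity step k
  and relaxes exponentially (τ = 120 s) back, with the same AR(1)
  fluctuation superimposed.
* **True BP** — the dMK-BH forward model at the programmed per-beat PTT
  with the subject's true parameters (default 120/80 mmHg, 250 ms,
  γ = 0.017).  dMK-BH is the forward model so that calibrating the other
  model, or perturbing γ, creates exactly the kind of systematic
  mis-specification the penalty factor targets.
* **Cuff readings** — the forward model at each window's median PTT plus
  independent Gaussian noise (SD 2 mmHg); readings with SBP ≤ DBP are
  resampled with a warning.
* **Waveforms** — ECG as narrow Gaussian templates (SD 10 ms) at the beat
  times; PPG as a sharp systolic apex (SD 15 ms) riding on a broader
  asymmetric volume wave (rise 50 ms, fall 120 ms), both peaking at
  `beat time + PTT`.  The distinct apex keeps the peak location
  well-defined under band-pass filtering and noise, as in real finger
  PPG.  White noise is added at a default SNR of 20 dB relative to the
  template peak.

All stochastic output derives from a mandatory seed; the same seed
reproduces a subject bit-for-bit.

**What the generator does not emulate:** PPG morphology beyond the
two-component pulse (no dicrotic notch), P/T waves and QRS morphology,
motion and contact artefacts, heart-rate variability and HR–BP coupling,
respiratory modulation, and cuff-device systematic offsets.  Passing
tests therefore demonstrate the correctness of the pipeline's logic and
numerics under controlled conditions, not clinical accuracy on real
recordings.

## Evaluation

Differences are `estimate − reference`.  Sample SD (n−1) is used
throughout, matching Bland–Altman convention.  Limits of agreement are
`bias ± 1.96·SD`; the within-agreement percentage counts boundary points
as inside.  Pearson correlation requires ≥ 3 pairs and nonzero variance
(zero variance is an error, not NaN).  The AAMI verdict is
`|mean| ≤ 5 mmHg and SD ≤ 8 mmHg`, bounds inclusive — consistent with
treating 8.58 as failing and 7.79/6.95 as passing.

## Problem sizes

The shipped experiments use desk-scale sizes chosen to exercise every
code path with comfortable statistical margins: 300-beat waveform
renderings for extraction accuracy, 100 seeded subjects for the
calibration-ordering experiment, 10 subjects (420 pooled recovery pairs)
for the cohort evaluation, and 10⁵ differences for the coverage check.

## Known limitations

* γ is fixed, not fitted; age- and disease-dependent γ estimation is out
  of scope.
* Artefact rejection beyond the pairing bounds is not implemented; the
  pipeline expects reasonably clean signals.
* Periodic re-calibration scheduling is not implemented; calibration is
  strictly once per subject.
* The evaluation module does not include ANOVA/post-hoc machinery;
  routine significance testing is left to general-purpose statistics
  packages.
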