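# Methods

`lvadsound` analyzes the sound a continuous-flow left ventricular assist
device (LVAD) makes, heard through the chest wall, to detect significant
aortic regurgitation (AR) during follow-up.  This note records the signal
model, the analysis choices and their rationale, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Signal model

An axial-flow pump rotating at `rpm` revolutions per minute emits a harmonic
stack at the rotation frequency

    f0 = rpm / 60        (10,000 rpm -> 166.7 Hz)

with harmonics at k·f0.  In normal operation the pump runs between 8,000 and
12,000 rpm, so the fundamental lies in 133–200 Hz and the second harmonic in
266–400 Hz.  Devices with an intermittent-low-speed (ILS) mode periodically
drop to ~7,000 rpm (nominally for 8 s every 64 s) so the native aortic valve
can open.

Physiology modulates this carrier:

* **Cardiac frequency modulation.**  The pump's load varies over the cardiac
  cycle, wobbling the rotation speed; the fundamental's instantaneous
  frequency carries a sinusoidal component at the heart rate (~1–1.5 Hz,
  searched in 0.7–3 Hz), with a peak deviation of a few Hz.
* **Respiratory amplitude modulation.**  Breathing modulates the acoustic
  coupling and pump preload, producing amplitude modulation below 0.5 Hz.
* **Non-harmonic noise.**  Broadband sound between the harmonic lines,
  summarized in three bands: below the fundamental ("low"), between the
  fundamental and second harmonic ("middle"), above the second harmonic
  ("high").

The synthetic generator renders exactly this model:

    x(t) = env(t) · Σ_k a_k sin(k·φ(t) + ϑ_k) + a_1 · Σ_b level_b · n_b(t)
    φ(t) = 2π ∫ f0(τ) dτ,   f0(t) = rpm(t)/60 + D(t)·sin(2π f_heart t)

with `rpm(t)` a smooth pulse train (1-s raised-cosine ramps centred on the
nominal ILS boundaries, so the midpoint crossing of the ramp coincides with
the ground-truth boundary), frequency modulation applied through the phase
integral (phase-continuous), respiratory AM `1 + m_resp·sin(2π f_resp t)`
everywhere and cardiac AM `1 + m_ils·w(t)·sin(2π f_heart t)` during ILS, and
band noise shaped brick-wall in the frequency domain with unit RMS per band.
Modulator phases are fixed at zero (the envelope is exactly reconstructible
from ground truth); harmonic and noise phases derive from the seed.  Noise
amplitude scales with the first harmonic, so rescaling the waveform by any
positive gain is a pure gain change — the basis of the a.u. scale-invariance
property tested end to end.

## Time–frequency analysis

Amplitudes from an electronic stethoscope are uncalibrated (coupling and
distance vary), so all amplitudes are expressed in **arbitrary units
(a.u.)**: percent of the largest amplitude within the normalization window
(default: the full recording minus wavelet edge regions; configurable).

The scalogram is an analytic Gabor (Gaussian-windowed) wavelet filter bank,
built in the frequency domain: the analytic signal's spectrum is multiplied
by a unit-peak Gaussian at each analysis frequency f_c with
σ_f = f_c / q (constant-Q) and inverse-transformed; ridge amplitude is the
magnitude.  Defaults:

* frequency grid 20–2000 Hz, 48 bins/octave (4 per semitone), ~319 bins;
* time step 10 ms (track sampling 100 Hz — ample for sub-5 Hz fluctuations);
* q = 39.3, i.e. frequency-domain FWHM ≈ 10 Hz at 167 Hz.  Narrow enough to
  separate harmonics ≥ 117 Hz apart; wide enough (σ_t ≈ 37 ms at 167 Hz)
  that ±1.4 Hz cardiac sidebands merge into one frequency-modulated ridge
  rather than resolving as separate lines;
* the input is decimated to ≤ 5 kHz (polyphase, anti-aliased) — the analysis
  band ends at 2 kHz — and band-limited 20–2000 Hz with a zero-phase
  (forward–backward) Butterworth filter so feature timing stays aligned with
  ground truth;
* the first and last 3 σ_t of the longest wavelet are flagged as edge
  regions and excluded from all feature statistics.

A pure tone of amplitude A yields a Gaussian-shaped ridge of height A, so
log-amplitude parabolic interpolation across three neighbouring bins is an
exact vertex estimate for both ridge frequency and amplitude; this is what
delivers sub-bin (≲0.2 Hz at 167 Hz) frequency accuracy on the log grid.

### Ridge tracking

The fundamental is tracked as the per-frame amplitude argmax within the band
implied by the plausible rpm range (105–213 Hz widened by a 12 Hz modulation
margin).  Harmonics 2 and 3 are tracked hierarchically in a narrow band
(±2 FWHM + 5 Hz) around k× the fundamental track: with band noise present, a
wide search band occasionally locks the third-harmonic tracker onto the
second-harmonic ridge in cardiac-correlated frames, inflating its
frequency-variation estimate.  Frames without a credible peak (below 0.5
a.u., or under 2× the in-band median) are gaps (NaN), never interpolated
silently; fluctuation analysis bridges gaps up to 10% linearly, with a log
note.

### ILS segmentation

Frames whose fundamental sits below a threshold for ≥ 2 s are ILS.  The
threshold is the midpoint of the track's 10th and 90th frequency percentiles
(the protocol keeps ILS occupancy near 12.5%, so the percentiles straddle
the two speed plateaus); when the track shows no bimodality (separation
< 8 Hz) the midpoint of the programmed ILS and minimum-normal fundamentals
is used instead.  The data-driven rule matters because measured ILS speeds
scatter widely around the programmed setting — a fixed protocol midpoint
misses faster-than-programmed ILS dips.  A 0.75-s "transition" guard around
every ILS boundary keeps ramp frames out of segment statistics.  A recording
longer than one protocol period with no detected ILS gets a logged warning
and an all-normal labeling (real recordings can miss the window), not an
exception.

### Fluctuation spectra and variation amplitudes

The frequency and amplitude time courses of a tracked ridge are
mean-detrended, Hann-windowed, zero-padded 4× and Fourier-transformed, with
amplitude scaling 2/Σw so a sinusoidal modulation of peak deviation D reads
D at the modulation frequency.  A "variation amplitude" is the amplitude of
the dominant non-DC spectral peak (not RMS, not peak-to-peak) — the quantity
a strong physiologic modulation produces, in the units of the track (Hz or
a.u.).  Peaks must be local maxima (an in-band argmax on the rising skirt of
an out-of-band component is rejected), exceed an absolute floor, and exceed
4× the spectrum median; otherwise the feature is flagged missing.

Two corrections keep planted modulations recoverable to ~5%:

* **Analysis-smoothing compensation.**  The wavelet's temporal window
  low-passes the ridge track, attenuating a modulation at f_mod by
  exp(−(2π f_mod σ_t)²/2).  Variation amplitudes are multiplied by the
  inverse factor (capped at 3); the factor is ~1.06 for cardiac modulation
  at a 167 Hz carrier.
* **ILS amplitude variation at the cardiac frequency.**  The strong ILS
  frequency sweeps drag the ridge through the analysis band fast enough to
  dip its apparent amplitude twice per cardiac cycle, creating a spurious
  2×-heart-rate amplitude component that can exceed the true cardiac AM.
  The ILS amplitude variation is therefore read at the cardiac frequency
  located on the ILS *frequency* track (±0.2 Hz), and ILS spectra are
  Welch-averaged across all usable ILS windows (trimmed to a common length)
  to beat the short-window noise floor.

Normal-operation fluctuation features use the longest normal segment
(≥ 10 s required — shorter components cannot resolve sub-0.1 Hz structure);
ILS features accept 4-s components, the most two protocol-trimmed 8-s
windows allow.

### Band amplitudes

Non-harmonic band amplitudes are scalogram means over normal-operation
frames with ±2 FWHM neighbourhoods around every harmonic (k·f1 and the
tracked f2) excised.  At ±1 FWHM a full-scale ridge still leaks 6 a.u. at
the excision edge, biasing the middle band by ~18%; at ±2 FWHM the skirt is
< 0.01 a.u. and the recovered amplitude is linear in the planted noise level
to within a few percent.

### The 19 features

Fixed catalogue order: f1, f2, f3 (Hz); frequency-variation amplitudes of
harmonics 1–3 (Hz); harmonic amplitudes 1–3 (a.u.); amplitude-variation
amplitude of harmonic 1 (a.u.); non-harmonic low/middle/high band amplitudes
(a.u.); normal rotational speed (rpm = 60 × median tracked f1); ILS
frequency-variation (Hz), ILS amplitude-variation (a.u.), ILS rotational
speed (rpm); heart rate (bpm), respiratory rate (per minute).  Rotational
speeds are derived acoustically — recordings are the only required input —
with a manifest override available for controller readouts.  Missing values
are NaN plus an explicit `missing` list; a recording without a usable
fundamental raises a structured failure, never a partial vector.

The cardiac search band is 0.7–3 Hz rather than the descriptive 1–1.5 Hz:
cohort heart rates of 84 ± 14 bpm put a meaningful fraction above 90 bpm.

## Synthetic cohorts and the feature-table sampler

`CohortSpec` plants per-recording parameters from per-class Gaussians
patterned on the clinical cohort contrasts (lower ILS speed 7072 vs 7440
rpm, smaller ILS amplitude variation, slightly weaker first harmonic, larger
normal-rotation amplitude variation, heart rate 79 vs 84 bpm), clipped to
physical ranges; an `effect_multiplier` scales every class mean shift for
ablation and null experiments.  Draw floors are physiologic: respiratory AM
≥ 3% (patients breathe), cardiac frequency deviation ≥ 1 Hz.

Default band-noise levels are set so all 19 features remain measurable in a
two-ILS-cycle recording, preserving the clinical low > middle > high band
ordering at roughly a quarter of the clinical band amplitudes; at clinical
noise the 8-s ILS windows cannot support the ILS amplitude-variation
measurement.  Clinical-scale noise remains one parameter away.

`sample_feature_table` draws ready-made 19-feature tables directly from the
per-class feature Gaussians.  Modeling-scale experiments (ranking
replicates, permutation nulls, effect-size sweeps) run on these tables; the
audio path is exercised end to end on single recordings and a 20-recording
recovery cohort.  Extraction recovers planted values to ≈ ±3 rpm (speed),
±0.2 bpm (heart rate), ±0.1/min (respiratory rate) and ≲5% (modulation
depths) under default conditions, so the parametric sampler and the audio
path agree on what the features measure.

What the generator does **not** emulate: beat-to-beat heart-rate
variability, non-stationary noise (speech, rubbing), stethoscope transfer
functions and room acoustics, multiple pump models, or any hemodynamic
mechanism linking AR to the acoustic shifts — class differences are planted
statistically, not simulated physically.  Passing recovery tests therefore
demonstrates that the pipeline measures what it claims on signals with known
truth; they say nothing about clinical discriminability beyond the planted
effect sizes.

## Feature selection and classification

* **Rankings.**  Unpaired equal-variance t-test p-values (ascending) and
  random-forest Gini importance (descending); neighbourhood component
  analysis is available as an optional third route.  Ties break by catalogue
  order — reproducibility over arbitrariness.
* **Filter stage.**  Features join in rank order; after each addition the
  leave-one-out misclassification of linear discriminant analysis is
  recorded (median imputation refitted inside every fold); the subset is the
  earliest prefix at minimum error.  Degenerate within-class covariance
  triggers an automatic shrinkage refit (logged).
* **Wrapper stage.**  Greedy forward selection inside the filter subset,
  same LOOCV criterion, stopping when no addition improves; if the greedy
  path ends worse than the whole filter subset, the filter subset is kept.
* **Benchmark.**  Nine classifiers — linear discriminant analysis, kNN
  (k = 5, distance-weighted), Gaussian naive Bayes, kernel naive Bayes
  (per-feature Gaussian KDE class-conditionals, Silverman bandwidths),
  random forest, linear SVM, RBF SVM, decision tree, and a bagged-tree
  ensemble (100 trees; bagging is the default "ensemble") — on a stratified
  75/25 split.  Hyper-parameters are tuned on the training portion only:
  LOOCV grids for the single models, tenfold stratified CV for the
  forest/ensemble.  Metrics on the untouched test set: accuracy, AUC (rank
  statistic; constant scores give 0.5), true positive rate and true negative
  rate, positive class = AR present.  Class imbalance (~10.6% positives) is
  handled by stratification only — no resampling by default.
* **Anti-leakage.**  Imputation, scaling, tuning and selection all fit on
  training folds only; a canary test plants label information outside the
  training rows and checks training CV stays at chance.

The selection report always carries both full rankings, the filter trace and
both subsets — the number of "important" features is an output, not a
hard-coded count.

## Numerical choices and degenerate inputs

Zero-phase filtering keeps timing unbiased; float32 is used inside the
filter bank (the a.u. scale makes 1e-7 relative error irrelevant);
normalization of an all-zero window raises a degenerate-input error rather
than dividing by zero; silence yields all-gap tracks and an unanalyzable-
recording failure; fluctuation analysis refuses components shorter than its
resolution floor; stratified splits that drop a class (possible only at tiny
n) are redrawn with a logged note.  All randomness flows from explicit
seeds; per-recording sub-seeds derive from the cohort seed by counter, so
any recording can be regenerated in isolation and identical seeds give
bit-identical audio.

## Problem sizes

Default recordings are 128 s at 40 kHz (two ILS cycles); the recovery
cohort is 20 recordings of 64 s at 10 kHz analyzed over 20–700 Hz (the
harmonic band), chosen so the whole suite — including 50-replicate selection
experiments and 20-seed benchmark sweeps at n = 245 — completes in minutes
on one core.

## Known limitations

* The ILS amplitude-variation estimate retains a ~20% upward bias from
  residual frequency-sweep/amplitude coupling at the cardiac rate; the
  planted class contrast (3.9 vs 2.5 a.u.) survives, but absolute values
  are conservative upper estimates.
* Harmonic amplitudes are reported relative to the recording's own maximum,
  so a recording whose loudest event is a transient (not modelled here)
  would scale all a.u. features down together.
* Rotational speed is acoustic; if the fundamental is untrackable (severe
  noise), speed features go missing rather than falling back to telemetry.
* The pipeline assumes one pump; overlapping harmonic stacks (two devices,
  strong mains hum at a harmonic location) are out of scope.
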