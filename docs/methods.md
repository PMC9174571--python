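# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `epibeat`. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The estimation problem

Epicardial accelerometers record the vibrations of the first and
second heart sounds (S1, S2). S1 accompanies atrioventricular valve
closure at systole onset and its intensity tracks contractility
(LV dP/dtmax); S2 accompanies semilunar valve closure and its
intensity tracks the pressure against which the valve shuts (LVPmax).
The package estimates *absolute* LVPmax and dP/dtmax as classes over
contiguous pressure bins, from amplitude/energy/timing features of the
two sounds, using bagged classification trees. Binning turns an
ill-posed absolute-regression problem into a classification problem
whose resolution (bin width) is an explicit, device-friendly knob.

## Synthetic study conditions (the generator)

Because no animal recordings ship with the package, the generator in
`simulate.py` defines the study conditions. It emulates the
*statistical structure* that the downstream stages care about, not
valve mechanics:

- **Cohort.** Five animals; baseline LVPmax ≈ N(97, 5²) mmHg, baseline
  dP/dtmax ≈ N(830, 45²) mmHg/s; per-location sensor gains drawn
  uniformly from 1 ± 0.15 (subject- and location-specific coupling of
  tissue to sensor). Accelerometer noise 0.005 g per sample at
  1 kHz / 16-bit / ±4 g. The noise level is calibrated so that clean
  same-setting beats correlate well above the default 0.95 coherence
  threshold — the screening stage's stated operating point (≥95%
  artifact rejection, ≤5% clean-beat loss) pins this choice.
- **States.** Dobutamine multiplies dP/dtmax by 1.95 (≈2× titration
  target) and LVPmax by 1.25; isoflurane multiplies them by 0.75 and
  0.70. The isoflurane dP/dt depression is limited to 0.75 (not the
  ≈0.5 a deep anesthetic plane can produce) so that every generated
  target stays inside the 60–130 mmHg / 600–1,600 mmHg/s measurement
  ranges that the binning schemes cover; a 2× dobutamine and 0.5×
  isoflurane multiplier cannot both fit a 2.67:1 range.
- **Pacing.** Seven programmes per animal spanning the three states
  (RV and BiV; AV 50–150 ms at HR 100 so that S2 and its ROI fit the
  0.6 s cycle), 60 s per setting, each modulating the targets by a few
  percent (AV/VV penalty, RV < BiV) so targets form many distinct
  clusters across the range. Beat-to-beat variability: respiration
  (0.2 Hz) plus Gaussian jitter (1.2 mmHg / 12 mmHg/s), clipped to the
  measurement ranges.
- **Pressure.** Each cycle is a closed-form template — raised-cosine
  upstroke whose analytic peak slope *is* dP/dtmax and whose crest *is*
  LVPmax, decaying systolic dome, cosine relaxation, diastolic drift —
  so the per-beat ground truth is realized exactly (recovered within
  0.5% through the reference extractor; the template raises an explicit
  error when the requested slope cannot reach the requested peak within
  the cycle).
- **Acceleration.** S1/S2 are Gabor bursts (Gaussian-windowed 32–45 Hz
  carriers, ≈50 ms support, inside the 10–250 Hz analysis band) whose
  peak-to-peak amplitudes are *exactly* gain·g1(dP/dtmax) and
  gain·g2(LVPmax), with linear g1, g2 by default (1.0×10⁻³ g per
  mmHg/s; 8.0×10⁻³ g per mmHg) and a sigmoid alternative for
  robustness experiments. Burst timing is load-independent with
  sub-millisecond jitter (0.3/0.5 ms): larger carrier-phase jitter
  would push clean-beat correlations below the coherence threshold,
  and a strong timing→pressure coupling would be gain-invariant and
  hence erase the personalized-vs-generalized gap the study design
  probes. Consequence: the hemodynamic information lives in
  amplitudes/energies, and the timing features act as controls the
  feature selection is expected to neglect — which is also the
  qualitative finding the selection stage reproduces.
- **Devices.** The hemodynamic recorder (ECG + pressure, 2 kHz) and
  the accelerometer unit (1 kHz) share only a 1 Hz broadcast square
  pulse; the accelerometer clock starts 250 ms late and runs 30 ppm
  fast, X/Y axes are attenuated noisy copies of Z, and artifact beats
  (amplitude-inverted or 80 ms-late bursts, flagged in the ground
  truth) are injected at a configurable rate (default 2%).

What the generator does **not** emulate: PV-loop physiology, valve
mechanics, load-dependent ejection time, ectopy with electrical
signature, environmental/lung noise, sensor detachment. Passing tests
therefore demonstrate the *pipeline's* correctness and the method's
behavior under monotone amplitude coupling — not clinical performance.

## Acquisition

- **Alignment.** Rising pulse edges (half-amplitude threshold) are
  matched across devices by order with a small shift search; the offset
  is the median pairwise onset difference, and a piecewise-linear map
  through the pulse pairs corrects constant skew and locally irregular
  sampling (logged as repairs). A ≥2-pulse count mismatch is rejected
  as ambiguous: a periodic train identifies the offset only modulo its
  period. All channels are linearly resampled to the fastest device's
  rate (2 kHz).
- **Filtering.** Zero-phase 4th-order Butterworth; acceleration fixed
  at 10–250 Hz, ECG 0.5–150 Hz. The upper ECG edge keeps enough pacing-
  spike slope energy for the detector; both bands are configurable.
- **Spike detection.** Candidates are peaks of |dECG/dt| above 5× its
  scaled median absolute deviation (20 ms candidate refractory),
  back-tracked to the rise onset; atrial/ventricular labels come from
  pairing candidates at the programmed AV delay ±10 ms, with a 200 ms
  refractory on the atrial train. A flat refractory of 200 ms on *all*
  candidates would veto ventricular spikes whenever AV < 200 ms, which
  the pacing protocol allows.
- **Segmentation.** ECG/acceleration beats are [spike_k, spike_k+1);
  spacings outside 0.2–3 s are dropped and logged. Pressure is cut at
  the midpoints between successive diastolic minima (found on a lightly
  smoothed trace), fully independent of the ECG annotations; each
  pressure beat is assigned the cycle whose atrial interval contains
  its systolic peak.

## Coherence QC

Per setting and signal kind, beats are linearly resampled to the modal
sample count (ties → smaller length), zero-meaned, unit-normalized, and
compared by maximum cross-correlation over lags of ±5% of the beat
length. Beats form a graph with edges at correlation ≥ 0.95 (default);
the kept set is the exact maximum clique for ≤15 beats and otherwise a
deterministic greedy quasi-clique seeded at the highest-degree beat.
A beat survives only if kept in ECG, acceleration and pressure
simultaneously. The exact-vs-greedy pairing doubles as an internal
oracle in the tests.

## Features

Shannon transforms use the natural logarithm (the base only rescales
features, which is irrelevant to tree splits) and the convention
0·log 0 = 0; the energy form is computed as −2x²ln|x| to avoid
underflow of x² inside the logarithm. Normalization for the Shannon
transforms divides by the maximum |signal| over the *pacing setting*,
not the single beat, preserving the beat-to-beat amplitude ordering
that carries the hemodynamic signal; A–C are computed on the raw
(filtered) signal and scale linearly with it, D–G are scale-invariant
under per-setting scaling, H–J are times. D and F are scalarized as ROI
maxima (their integrals are E and G). I and J are measured on S1 by
default (configurable): the feature count stays at 17 (7×2 ROI
features + H + I + J). ROI search windows — S1 in (v, v+200 ms], S2 in
(v+250, v+500 ms], ±75 ms windows clipped to non-overlap — come from
standard S1/S2 physiology at paced rates and are configurable.

## Reference extraction and binning

LVPmax is the beat's maximum sample; dP/dtmax the maximum of a 5-point
central-difference derivative after two 5 ms moving-average passes
(a triangular smoother). The smoothing suppresses catheter noise that
the difference stencil would otherwise amplify by ~fs while biasing
the upstroke slope by well under 0.5%. Beats whose maximum sits on the
window edge, or with ≠1 systolic peak (local maxima in the upper half
of the beat's range, merged over 100 ms — prominence-based counting
fails when the mid-relaxation cut raises one base), are excluded.
Bins are half-open, anchored at the range minimum, n_bins =
⌈range/width⌉; out-of-range values clip into the edge bins (logged)
so beat counts stay comparable across schemes.

## Trees, bagging, selection, validation

Splits maximize Gini gain over midpoints of consecutive distinct
feature values; every tie (gain, feature, frontier node, vote) breaks
toward the lower index/threshold, so a fixed seed yields a
bit-identical model. Growth is best-first under a split budget of
4×n_bins: with pooled multi-subject data and subject-specific gains a
pressure bin occupies non-contiguous feature-space regions, so trees
need more leaves than bins (2×n_bins stumps under-fit exactly the
structure of interest). No pruning; complexity is governed by the
split budget and the 3-feature cap. Bagging draws N-with-replacement
resamples from a seeded generator; prediction is majority vote. The
split scan is JIT-compiled with numba when available; a pure-numpy
implementation of the identical algorithm is the fallback and the
cross-checked reference.

Cross-validation is stratified 10-fold ("10 × k-fold" is read as
10-fold, optionally repeated; `repeats` defaults to 1). The greedy
wrapper fixes one seeded fold assignment for all candidate subsets,
evaluates all single features, then tries additions and
member-for-unused swaps, accepting only strict improvements of the
chosen metric (accuracy, or loss for loss-optimized models — reported
afterwards by their accuracy). The stratified holdout draws
min(⌈5%·n_c⌉, max(0, n_c − 10)) beats per class, shrinking for scarce
bins. LOSO reruns the greedy search per held-out subject on the
remaining subjects only. The one-way ANOVA helper (classical
F = MS_between/MS_within) compares per-fold accuracies across bin
widths and personalized-vs-generalized runs.

## Problem sizes

The package's reference experiment is 5 subjects × 7 settings × 60 s
(≈3,200 retained beats) at one sensor location (mitral valve); the
acceptance script and the study-level tests use this size, with
smaller 2–4-subject, 8–12 s cohorts for component-level checks and the
seed-replicated comparisons. Search-stage ensembles use 10 trees
(ranking subsets needs less smoothing than final estimates); final
models use 50.

## Known limitations

- The acoustic couplings g1, g2 are stand-ins with documented shapes,
  not estimates of any animal's transfer function; absolute accuracy
  numbers on synthetic data say nothing quantitative about in-vivo
  accuracy.
- The pooled "personalized" model may implicitly identify the subject
  from its gain signature; the LOSO mode exists precisely to expose
  that effect.
- Pressure segmentation assumes a unique diastolic minimum per cycle;
  non-paced rhythms, ectopy with electrical signature, and R-peak
  detection are out of scope.
- The greedy wrapper's CV metric is not nested; feature-selection
  optimism is accepted by design (the holdout and LOSO modes provide
  the out-of-selection checks).
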