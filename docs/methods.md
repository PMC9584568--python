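# Methods

This note documents the models, numerical choices and limitations of
`somnohr` — what each stage assumes, which knobs matter, and what the
synthetic test bed does and does not demonstrate about real data.

## Signal quality index

The quality contract is a per-sample SNR,
`SNR[i] = 20·log10(A_signal[i] / A_noise[i])` dB, with `A_signal` a sliding
3-s maximum filter over the absolute ECG signal component and `A_noise` the
√2-scaled sliding 10-s RMS of the background component, both windows
advanced one sample at a time. Rejection semantics are exact: an epoch is
rejected when **≥ 50%** of its samples are **strictly below 5 dB**; a
recording is excluded when **≥ 10%** of its epochs are rejected; retained
recordings are scored over all epochs, rejected ones included.

The signal/background split is a stationary wavelet transform (`sym4` by
default), reconstructing the detail levels whose dyadic passbands
`[fs/2^(j+1), fs/2^j]` intersect the QRS energy band (5–32 Hz default);
background is the residual. Design choices made where the procedure was
genuinely open:

* **Window placement** — the 3-s and 10-s windows are *centered* on the
  sample, with reflect padding at the record edges so the SNR series has
  full length.
* **Degenerate ratios** — `A_noise` is floored at a machine-epsilon-scaled
  amplitude and the SNR clipped to [−40, +80] dB. A record whose background
  component is exactly zero therefore sits at the +80 dB ceiling; with the
  wavelet split a clean ECG's residual is small but nonzero, so clean
  records sit near 25 dB — comfortably accepted, but below the ceiling.
  The closed-form behaviors (20 dB ratio, ceiling, floor) are therefore
  tested through the pluggable decomposition hook, and the wavelet path is
  tested for acceptance, scale invariance (the transform is linear) and
  noise localization.
* The decomposition is a hook (`compute_snr(..., decomposition=...)`)
  precisely so the ratio-and-threshold machinery is testable independently
  of any particular wavelet choice.

## R-peak detection and tachogram

A Pan–Tompkins-family detector: zero-phase 5–25 Hz band-pass, squaring,
150-ms moving-window integration, peak picking with a 300 ms refractory
distance, and a **block-local** adaptive threshold (30% of the 95th
percentile of the integrated energy per 10-s block, linearly interpolated
between blocks). The local threshold matters: a half-minute noise burst
must not raise the detection level for the rest of the night. Polarity is
resolved by majority vote over the detected complexes, and each beat time
is refined by a parabolic fit through the local extremum of the band-passed
waveform, giving sub-sample precision (~0.15 ms MAE on clean 256 Hz
synthetic ECG against a ± 4 ms budget; the zero-phase filtering keeps the
symmetric QRS template's apex unshifted).

Spurious-beat correction flags an RR interval that falls more than 30%
short of an 11-beat running median (both knobs configurable), removing the
terminating beat — preferring the removal that merges two short intervals
back into a median-consistent one, the ectopic-insertion signature. Gaps
longer than 1.3× the local median are bridged by evenly spaced beats
flagged `interpolated`. The operation is idempotent and never emits RR
outside [300, 2000] ms. The cleaned series is cubic-spline interpolated
onto a uniform 4 Hz grid (RR anchored at the later beat of each pair),
clamped to the same bounds.

## Features

Per 30-s epoch: mean HR, SDNN and RMSSD from the epoch's tachogram window;
LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) band powers and their ratio from a
Welch estimate over a 5-min window centered on the epoch — the shortest
conventional window for LF estimation; respiration as the dominant HF-band
frequency of the same window (respiratory sinus arrhythmia), undefined when
the band holds no energy. The in-bed score marks an epoch out-of-bed only
when its modal body position is upright; with no position channel all
epochs are in-bed (logged). Epochs outside the tachogram span carry NaN,
never fabricated values. The model tensor stacks the standardized
tachogram window, a validity mask, and the scalar features broadcast along
time (9 channels); standardization uses fixed physiological scales so the
network sees O(1) inputs regardless of cohort.

## Classifier

Stage 1 (per-epoch encoder): 1×1 stem to a 200-channel trunk; three
inception-residual blocks, each running parallel kernels {3, 5, 7} at
branch width 39, a 1×1 merge back to the trunk and a residual add; global
average pooling; a linear embedding of dimension 333; and an auxiliary
4-class head. Stage 2 (sequence refiner): the embedding concatenated with
the auxiliary posterior (337 channels per epoch) passes a 1×1 stem to width
161, six residual blocks of two k=3 convolutions (161→81→161) at dilations
{1, 2, 4, 8, 16, 32} — a receptive field of 253 epochs, over two hours of
context — then a 1×1 projection to 81 channels and the 4-class head.

Both stages expose closed-form trainable-parameter counts, verified against
brute-force enumeration of the weight tensors. The default widths
(200/39/333 and 161/81/81) were found by integer search over that formula
so the default model reports **492,420** (stage 1), **538,796** (stage 2)
and **1,031,216** (total) parameters exactly; `calibrate_widths()` exposes
the search and raises with the nearest achievable counts when a target is
unreachable. `width_multiplier` scales every width (with small floors) for
desk-scale training; the count formula tracks the effective widths.

Training: Adam (1e-3 default) on class-weighted cross-entropy over the
stage-2 head plus 0.3-weighted auxiliary loss on the stage-1 head; class
weights default to inverse frequency of the training labels. The cohort is
split 80/20 **at the participant level** (guarded against leakage), one
recording per gradient step, and the weights with the smallest held-out
error are retained; the per-iteration train/test accuracy curve is logged
on the model. The engine is plain numpy with hand-derived gradients
(strided-view conv1d + einsum), validated by central finite differences.

Label semantics: class order (W, Light, Deep, R); argmax ties break toward
the earlier class. Collapses sum posteriors within groups
({Light, Deep}→NREM; {Light, Deep, R}→Sleep; W→W always) and recompute the
argmax — which can legitimately differ from collapsing the 4-level argmax.
QC rejection flags are carried alongside predictions, never used to mask:
every epoch of a retained recording is scored.

## Evaluation

Confusion matrices (rows = reference, columns = predicted) at each
granularity; the 5-class AASM reference collapses as N1, N2→Light, N3→Deep.
Accuracy = trace/total; Cohen's κ with the chance term from the marginals;
SE/SP/PPV/NPV one-vs-rest per class with zero-denominator cells undefined
(NaN), never zero-filled. Subject-level metrics are computed from
per-subject confusion matrices (not by averaging per-epoch indicators) and
then averaged to cohort level — the more defensible reading of
within-then-across-participant averaging; epoch-pooled metrics remain
available as `pooled_metrics`. Cohort CIs use the normal approximation
(± 1.96·SD/√n); undefined subject values are excluded with `n` adjusted.
Covariate analysis fits one OLS per metric × factor (age, AHI, sex;
references age ≤ 40, AHI none/minimal, female), dummy-coded, reporting
betas, 95% CIs, two-sided p-values and 0.05/0.01/0.001 significance stars.

## Alignment

Two devices are placed on a common 30-s grid anchored at the earlier
lights-off time (defaulting to the recording start when no diary- or
position-derived value exists). Epochs a device does not cover are labeled
W and flagged padded — at the ends *and* across interior dropouts, a
documented extension. Sub-epoch offsets are snapped to the nearest epoch
boundary with the (< 15 s) residual logged; clock synchronization itself is
out of scope.

## Synthetic data model

The generators define the study conditions for every test:

* **Hypnograms** — first-order Markov chains over {W, N1, N2, N3, R}. The
  default transition matrix is a sticky, ergodic chain with adult-night
  structure (long N2 runs, deep sleep entered through N2, consolidated REM
  episodes).
* **RR dynamics** — within a stage, RR(t) = baseline + LF sinusoid (0.095–
  0.105 Hz, random phase) + respiratory sinusoid at the stage's rate
  (phase-continuous under rate changes) + white jitter; sinusoid amplitudes
  are √(2·power) so each contributes its configured band power, and jitter
  carries sdnn² − LF − HF. Stage boundaries cross-fade linearly over 30 s
  so the classifier cannot exploit discontinuities. Beats arise by
  integrate-and-fire on RR(t), strictly increasing with a 300 ms floor.
  Default per-stage values (e.g., mean RR 1000 ms / SDNN 40 ms in N2,
  REM with LF 1400 / HF 300 ms² vs N3's 100 / 400 ms²) are
  literature-plausible adult figures expressing the REM-vs-NREM LF/HF
  contrast; they live in config, not code.
* **ECG** — one Ricker pulse of configurable width at each beat time
  (evaluated analytically, so sub-sample beat positions are honored),
  plus 0.3 Hz baseline wander and segment-local Gaussian noise. No PQST
  morphology: the pipeline is HR-only by design, so template realism is
  irrelevant to what is being tested.
* **Cohorts** — metadata strata (3 age groups × 3 AHI groups × 2 sexes)
  assigned round-robin so every stratum stays populated; optional planted
  effects degrade a group's planted prediction accuracy by flipping a
  binomial fraction of collapsed reference labels (plus N(0, 0.02)
  subject-level heterogeneity), making regression recovery and type-I
  behavior directly testable.

What passing tests show — and what they do not: the synthetic regime has
genuinely stage-separated HRV (an "easy regime"), stationary noise, and no
arrhythmia, apnea-driven HR patterns, movement artifact or electrode-contact
loss. End-to-end recovery (held-out 4-level accuracy ≥ 0.70 on a 20-subject
cohort of 2-h nights with the width-0.1 model, ~11k parameters, against a
~0.39 majority rate) therefore demonstrates that the pipeline and training
machinery work, not that real-night accuracy of any particular level is
achieved; real-data performance requires training on real cohorts at full
width. Problem sizes in the test suite (240-epoch nights, 20 subjects,
15 training iterations; 100–200 cohorts of 18 subjects × 120 epochs for the
regression studies) were chosen as the smallest sizes at which the measured
properties are stable.

## Known limitations

* The wavelet signal/background split is one reasonable instantiation of
  an unpublished decomposition; exclusion *counts* on any particular
  dataset will depend on it, which is why the thresholds — not the counts —
  are the tested contract.
* The spurious-beat rule is a standard median filter, not an arrhythmia
  classifier; runs of ectopy longer than the median window can survive.
* Respiration derives from RSA only; it fades where vagal modulation is
  weak (e.g., high sympathetic tone) and is undefined on metronomically
  constant rhythms.
* The numpy training engine is single-threaded and desk-scale by intent;
  full-width training on large corpora is out of scope.
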