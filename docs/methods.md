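# Methods

This note documents the models behind `edaflow`, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and
do not establish about real recordings.

## Sensor front end

The device model is a DC-exosomatic constant-current source: a reference
resistor `Rref` from the `VDD` rail fixes the skin current at
`I = ½·VDD/Rref` (2.0 μA at the defaults `VDD = 3.3 V`,
`Rref = 825 kΩ`), and the front-end output voltage maps to skin
resistance as `R_skin = (1 − 2·Vout/VDD)·Rref`. Conductance is its
reciprocal. With the full 10 mm disc electrode contact the current
density is 2.546 μA/cm², a factor ~4 under the 10 μA/cm² limit that
protects the sweat-gland ducts; `current_density` reports the value and
the safety flag. The amplifier/filter stages between the sensing node
and the ADC are folded into one linear gain (default 1.0) because only
the end-to-end transfer matters downstream. The ADC reference is taken
equal to the 3.3 V rail, which the hardware description leaves
unstated. Output voltages above `VDD/2` would mean negative resistance;
they are clamped to zero with a loud warning, since they can only come
from a sensor fault. Quantization is uniform mid-rise at 12 bits; codes
are decoded at bin centres, so the round-trip error is at most half an
LSB (≈0.4 mV, ≈0.01 μS near a 5 μS operating point).

## Filtering

Raw 10 Hz recordings pass through an order-32 linear-phase FIR low-pass
with 1.5 Hz cut-off — the upper edge of the phasic band. The design
method (not fixed by the hardware description) is a Hamming-windowed
sinc, renormalised to unity DC gain; it attenuates 4 Hz by far more
than 20 dB. Application is a causal convolution with zero pre-padding,
so the first 32 output samples are a start-up transient; the protocol's
5 s lead-in keeps that transient out of every analysis window.

The filter's constant group delay (16 samples = 1.6 s) **is compensated
by default** (`compensate_delay=False` restores strictly causal
output). This choice is load-bearing: the SCR windows are defined in
stimulus time as +1 to +6 s after picture onset, sized for a 1–3 s
sudomotor latency plus a 1–2 s rise. An uncompensated 1.6 s lag pushes
the response peak to the window edge, where the baseline spline absorbs
roughly half of each response; in simulation this inverts the expected
calm < distress ordering of the mean-level features. With compensation
the ordering and the response mass are preserved.

## Decomposition

One SCR window per picture, `[onset+1 s, onset+6 s)`, half-open,
0-based sample indices. The tonic `l[n]`:

- equals the filtered signal at every non-window sample;
- inside windows, is bridged by a cubic spline through baseline knots.

Knots are one per 1 s block of consecutive non-window samples, taken at
the **block minimum**. With stimuli 7 s apart and a ~2 s SCR decay
constant, the inter-window gaps still carry the decaying tail of the
previous response; subsampled knots would sit on those tails and pull
the baseline above the true tonic (turning the phasic residual negative
on average), while block minima track the lower envelope. The spline is
anchored at the window edges and at the record endpoints, so it never
extrapolates (an SCR window touching the record end otherwise produces
a divergent bridge).

Two phasic estimators are provided:

- **additive** (default): `r = ŷ − l`, the conventional residual
  decomposition. It is zero outside the windows by construction, and
  each in-window excursion reflects one sudomotor activation.
- **spectral**: treats the tonic as the kernel of a multiplicative
  model `ŷ = r ⊛ l` and inverts it by Tikhonov-regularised division
  `R(f) = conj(L)·Y/(|L|² + ε)` on a power-of-two FFT grid, with
  `ε = 10⁻⁸·max|L|²` by default (scale-invariant). The round trip —
  deconvolving a known circular convolution — is exact to ≤10⁻⁴
  relative error. As a decomposition of realistic recordings, however,
  the problem is ill-posed: an estimated tonic is spectrally near-flat
  across the 0.05–1.5 Hz band where SCRs live, so the division has
  essentially no gain there and the recovered driver is neither
  stimulus-locked nor amplitude-faithful (measured: injected-mass
  correlation 0.74 vs 0.98 for the additive route; responded windows
  not separable from empty ones). The spectral route is therefore an
  option with well-defined contracts, not the default.

The returned phasic is re-baselined by subtracting its median over
non-window samples. `count_scrs` scores a window as "responded" when
the largest trough-to-peak rise inside it reaches 0.05 μS — the
conventional minimum SCR amplitude. Interpolation artifacts in an empty
window flanked by large responses can occasionally reach that
criterion, so counts are accurate to ±1 typically and ±2 rarely.

The phasic band is nominally 0.05–1.5 Hz, but a biexponential response
with a 2 s decay necessarily has spectral mass below 0.05 Hz (its first
pole sits at ~0.08 Hz); spectral contracts on the generated phasic are
therefore stated against the 1.5 Hz upper edge only. No explicit
low-pass is applied to the tonic estimate.

## Features

All 21 features are computed on the phasic series of one 70 s condition
segment (not per window), matching one value per condition per subject.
Definitions are in the README; numerical conventions:

- standard deviations and central moments are population (divide by N);
- derivatives are first differences in per-sample units
  (`derivative_scale="per_second"` rescales by fs); arc length uses
  unit sample spacing, so `ALSC ≥ N−1`;
- `RMSC = √APSC` (the printed "normalised RMS" formula is read as the
  root of the mean square);
- ELSC divides RMSC by ALSC on the literal "ratio between INSC and RMSC
  with ALSC" reading; `elsc_numerator="apsc"` covers the energy
  reading;
- the central moment order is configurable (default 3);
- skewness/kurtosis on a zero-variance segment are reported as NaN,
  never as 0;
- band powers use an FFT periodogram normalised so the one-sided bin
  sum equals the segment's mean square (Parseval), summed over
  half-open `[low, high)` bands;
- two source acronym collisions (SDSC doubling as the second-derivative
  std, KUSC listed twice) are resolved by naming the second-derivative
  statistics SMSC/SSDSC.

## Evaluation

Per-feature screening is a two-group one-way ANOVA (p < 0.05);
Shapiro–Wilk and Levene checks are computed as advisories and never
gate the test. Classification treats each segment as an independent
sample: the two segments of one subject may land in different CV folds,
matching the unpaired screening analysis (`group_by_subject=True`
switches to leakage-free folds; on the synthetic cohort the subject-
level responsiveness factor is shared across a subject's two segments,
so the default folds are mildly optimistic). Folds are stratified by
dealing each class round-robin after a seeded shuffle of rows sorted by
(subject, condition) — per-fold class counts differ by at most one
sample and the assignment is independent of row order. Thresholds scan
the midpoints of consecutive sorted unique scores plus sentinels, both
directions, maximising training accuracy with ties broken toward higher
sensitivity then the lower threshold. Sensitivity is the distress
detection rate; all metrics are percentages averaged over 10 folds × 5
repeats, reported separately for learning and test phases.

## Decision tree

CART with exhaustive (feature, midpoint) scans and weighted Gini
impurity decrease; ties break on feature name order, then the lower
threshold; comparisons are `≤` left / `>` right. A node becomes a leaf
when pure, when it holds fewer than 20% of all samples that entered
`grow`, or when no split separates the values; leaf classes are the
majority with ties to distress (missing distress is the costlier
error). There is no pruning. Note the stopping rule bounds the *split*
node, not the children, so small leaves can exist — with ~90 samples
the rule yields depth-2/3 trees whose learning accuracy (~87–93%) sits
well above their honest cross-validated accuracy (~70–80%); `tree_cv`
reports both phases so the gap is visible. The standard impurity
`1 − Σp²` is the default; a Lorenz-curve variant `2·min(p, 1−p)`
(pure → 0, 50/50 → 1) is available because the Lorenz formulation of
the Gini index is sometimes quoted with the (0, 1] range that the
standard impurity cannot reach.

`reference_tree` is the fixed two-threshold model: SDSC at 4.4830, and
SKSC at 3.1102 within the low-SDSC subgroup. Which subgroup carries the
second split and the leaf classes are not pinned down by the published
description; the defaults (high SDSC → distress; low SDSC refined by
SKSC, high SKSC → distress) are configurable via `flip` and should not
be read as the original model's orientation. Its absolute thresholds are on the
μS scale of the recordings the model was derived from and do not
transfer to the synthetic generator's scale.

## Synthetic data generator

The generator emulates the two-condition affective-picture protocol:
per condition, ten 6 s pictures each preceded by a 1 s blank (70 s
segments, 140 s of stimulation), separated by a stimulus-free
distractor gap (default 60 s — the original pause length is not
documented), with a 5 s lead-in and a 5 s tail. Conductance is

`g(t) = tonic(t) + (driver ⊛ bateman)(t) + noise`

- **Tonic**: a subject-level baseline drawn from 2–8 μS plus a drift
  synthesised strictly below 0.05 Hz (rms 0.3 μS), floored at 0.1 μS.
- **Driver**: per picture, with a condition-specific response
  probability, one impulse at onset + U[1, 3] s with log-normal weight
  (μS·s); a per-subject log-normal responsiveness factor (σ = 0.5)
  multiplies both conditions of a subject.
- **Kernel**: the Bateman biexponential
  `exp(−t/τ₂) − exp(−t/τ₁)`, τ₁ = 0.75 s, τ₂ = 2.0 s, unit area — the
  standard SCR shape from the broader EDA literature; it is simulation
  scaffolding, not part of the device pipeline. A unit driver weight
  produces a ~0.28 μS peak.
- **Noise**: white Gaussian, σ = 0.01 μS, comparable to the ADC step
  near 5 μS.

Rendering goes through the true inverse sensor map and the 12-bit
quantizer, so downstream code sees genuine device output.

Condition effects (defaults): calm — response rate 0.70, amplitude
median 0.45 μS·s, log-σ 0.35; distress — rate 0.90, median 0.60 μS·s,
log-σ 0.85. Distress responses are thus more frequent, larger on
average, and much more dispersed (occasional large bursts). These
values were fixed once to effect sizes typical of picture-induced
distress on palmar EDA: the distress/calm ratio of mean phasic level is
≈2.2, and the per-feature Cohen's d comes out ≈1.1 for SDSC, ≈1.25 for
SKSC and ≈0.8 for F2SC. The amplitude dispersion asymmetry is what
realises the expected skewness ordering:
SKSC is invariant to the subject responsiveness factor, so it carries
class signal on an axis independent of overall amplitude.

What the generator does **not** model: nonspecific (spontaneous) SCRs
between stimuli, motion and pressure artifacts, electrode drift,
habituation across the picture sequence, responses to the blanks, and
any dependence on picture content. Passing tests therefore show that
the chain is correct under clean, stimulus-locked physiology with
known ground truth — not that the classifier accuracies would transfer
to field recordings, which are noisier in ways that specifically hurt
the shape features.

## Study-scale results on the generator

With the default cohort (50 enrolled − 4 screening − 1 technical = 45
valid, 90 segments) and 10-fold CV repeated 5 times: most features are
ANOVA-significant; informative single-feature test accuracies fall in
the 70–85% band (SDSC averages ≈74% over seeds); the grown tree reaches
≈87–93% learning-phase accuracy, exceeding the best single feature's
test accuracy in essentially every seed, while its own cross-validated
accuracy is ≈70–80%. The learning/test gap of the tree is an inherent
property of growing with stopping rules alone on ~90 samples and is
reported, not hidden.

## Problem sizes in the test suite

Tests run the cohort at its natural size (45 valid subjects, 205 s
recordings at 10 Hz); the study-scale evaluation test uses 8 generator
seeds, the recovery contracts 10–50 seeds, and the brute-force oracles
100–500 random instances. The whole suite completes in a couple of
minutes on one core.
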