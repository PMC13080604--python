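# Methods

This note documents the models, conventions and numerical choices behind
`vibroscreen`, and what the synthetic experiments do and do not show.

## The screening problem

The package implements a dual-instrument screening analysis for
depression and anxiety in an outpatient setting. Two instruments score
every subject in parallel:

* an **AI risk scorer** operating on short grayscale videos of the
  head–neck region, exploiting the vestibulo-emotional-reflex signal:
  involuntary micro-movements in the 0.1–10 Hz band with amplitudes of
  roughly 10–1000 μm, whose spectral profile shifts in affective
  disorders (more low-frequency energy, less spectral complexity);
* the **Zung self-rating scales** (SDS for depression, SAS for
  anxiety), 20 four-point items each.

The gold standard is a clinician's narrative diagnosis quantified on
two independent 1–5 severity axes via severity-defining keywords
(highest matching keyword wins; unmatched text is subclinical, level 1).
Severity ≥ 3 defines the high-risk binary label; {1,2}/{3}/{4,5} map to
three actionable tiers (routine follow-up / adjustment or follow-up /
specialty referral), so tier ≥ 2 coincides with the binary label by
construction.

## Classical vibration imaging

For a video cube `U[t, y, x]` at frame rate `fs`:

* **Amplitude map** `A(x,y) = (1/N) Σ_i |U_i − Ū|`, the mean absolute
  deviation within an N-frame window. With T > N the cube is cut into
  non-overlapping windows and the per-window maps are averaged (the
  windowing scheme is a package convention; only the single-window
  formula is canonical). A trailing partial window is dropped.
* **Frequency map** `F(x,y) = argmax_{f ∈ B} |STFT{s_xy}(f)|` over the
  band B = (0.1, 10) Hz. The STFT uses Hann windows of 4 s by default
  (0.25 Hz native resolution), 50% overlap, segments fully inside the
  signal, magnitudes averaged across segments. The DC bin is never a
  candidate; argmax ties break toward the lowest frequency; a pixel
  with zero in-band power gets a NaN sentinel.
* **Region statistics**: mean, population variance, and Shannon entropy
  (bits) of a 16-bin equal-width histogram over masked, defined pixels.
* **Spectral features** of a single series: low-frequency energy ratio
  (periodogram power below `low_cut`, default 1 Hz, over total in-band
  power) and spectral entropy normalised to [0, 1] by `log2` of the
  number of in-band bins. "Signal complexity" has no canonical
  definition in this setting; normalised spectral entropy is the
  package's declared proxy.

Both maps are shift-invariant; the amplitude map is homogeneous of
degree one in intensity and the frequency map is scale-invariant. These
invariants are enforced by tests.

## CNN–BiLSTM risk scorer

The learned scorer consumes raw frame stacks (vibration maps can also be
fed through the same interface, since inputs are plain arrays): each
*time slice* is 8 consecutive frames presented as convolution channels,
so the first layer can compute temporal differences. The encoder is a
small residual stack — stride-2 stem, one residual block, stride-2
widening convolution, one residual block, global average pooling —
producing `z_t ∈ R^32` per slice. Depth and width are configuration;
the shipped defaults (d = 32, m = 32, two residual blocks) are a desk
scale chosen so the full synthetic experiment trains in minutes on one
CPU. A bidirectional LSTM (hidden size m = 32 per direction) reads the
slice sequence; the concatenation of final forward and backward states
`h ∈ R^64` feeds four parallel heads: two sigmoid classification heads
(`p_dep`, `p_anx`) and two linear regression heads trained on the 1–5
severities rescaled to [0, 1].

Training minimises `BCE_dep + BCE_anx + 0.5·MSE_dep + 0.5·MSE_anx`
(declared weights) with Adam (lr 3e-3, step-decayed ×0.3 at two-thirds
of the epochs), mini-batches of 16, all randomness seeded. The network
is implemented directly in NumPy with explicit backward passes
(im2col convolutions, hand-unrolled BPTT); gradients are verified
against finite differences in the test suite. Input normalisation
subtracts each video's mean and applies a fixed 1/10 scale — it is
deliberately *not* per-video standardisation, because between-video
amplitude differences carry signal.

## Calibration, thresholds, tiers

Temperature scaling fits a single `T > 0` minimising the NLL of
`σ(logit(p)/T)` (bounded scalar optimisation on [0.05, 20];
probabilities clipped to [1e−6, 1−1e−6] before the logit). It is
strictly monotone, so AUC is unchanged — tested.

Operating points maximise the Youden index `J = sens + spec − 1` over
midpoints of adjacent sorted unique scores, ties toward the lowest
cutpoint. Two tier cutpoints come from applying the procedure twice:
against the severity ≥ 3 binarization (t1) and against severity ≥ 4
(t2). How two thresholds should derive from one index is genuinely
open; this dual-binarization construction is the package's declared
choice. If the two fits coincide or invert (possible when scores carry
little severity gradient), t2 moves deterministically to the next
candidate cutpoint above t1. Tier intervals are left-closed:
p < t1 → tier 1, t1 ≤ p < t2 → tier 2, p ≥ t2 → tier 3.

## Scale scoring

Reverse-keyed items contribute `5 − v`; raw totals (20–80) are
multiplied by 1.25 and rounded **half-up** to the integer standard
score (the exact product is also retained; whether fractional scores
should be kept is unsettled, so the rounding rule is declared, and the
canonical Zung reverse keys ship as overridable defaults since item
keys are conventions of the instrument, not of this package).
Severity bands follow the Chinese norms — SDS: <53 none, 53–62 mild,
63–72 moderate-to-severe, >72 severe; SAS: <50, 50–59, 60–69, ≥70.
A screen is positive at or above the first cut (53 / 50). The SAS uses
the same ×1.25 multiplier as the SDS.

## Diagnostics

Confusion-matrix metrics use the standard definitions with **undefined
ratios reported as `None`**, never silently 0. AUC is the rank
(Mann–Whitney) statistic with ties at 1/2 (sklearn's trapezoidal ROC
serves as an independent oracle in tests, not as the implementation).
Macro-F1 averages one-vs-rest per-class F1 with equal weights; a class
absent from both margins contributes 0 with a warning. Bootstrap
intervals are percentile, B = 1000 by default, seeded, class-stratified
for metrics that need both classes; a resample on which the statistic
is undefined is redrawn with a capped, reported redraw count. Decision
curves use net benefit `TP/n − FP/n · pt/(1−pt)` against treat-all and
treat-none references. The logical-OR combined screen is positive when
either instrument is positive; structurally its sensitivity dominates
and its specificity is dominated by the components (property-tested).
Relative gains are `(combined − single)/single × 100`.

No continuous combined-model ROC is computed: the reference analysis
does not state how its combined curve was constructed, and the package
reports the combined screen only at its operating point.

## Reference fixtures

Six screening confusion matrices (n = 98; 73 depression-positive, 52
anxiety-positive) are reconstructed from the reference cohort's
reported sensitivities, specificities, precisions and unique-detection
counts: depression AI (70, 24, 3, 1), SDS (61, 14, 12, 11), combined
(72, 25, 1, 0); anxiety SAS (24, 26, 28, 20), AI (23, 26, 29, 20),
combined (36, 34, 16, 12) as (TP, FP, FN, TN). The reported SDS
precision (0.792) and F1 (0.813) are arithmetically inconsistent with
the reported SDS specificity (44.0% of 25 negatives → FP = 14 →
precision 0.813, F1 0.824); both readings are preserved — the
specificity-based matrix in the main fixture list, the
precision-consistent one (FP = 16, TN = 9) as a separately exposed
alternative — and the combined-vs-SDS F1 gain is consistent with the
precision-based baseline (4.1%). Neither reading is reconciled away.

## Synthetic data: what it emulates, what it does not

`generate_video` renders sums of masked sinusoids (μm amplitudes mapped
to intensity by a declared linear scale, 0.01 intensity/μm; no camera
model) plus i.i.d. Gaussian sensor noise on a constant baseline.
Defaults: 32 fps (Nyquist 16 Hz comfortably above the 10 Hz band
ceiling), 32×32 px — the reference acquisition's frame rate and
resolution are not public, so these are declared, not inferred.

`generate_cohort` draws fixed-count class labels (exactly the requested
positives — the reference cohort reports fixed observed counts, so
binomial sampling would make exact-count tests impossible), severities
consistent with the ≥ 3 cutoff, AI probabilities and scale items from
correlated Gaussian latents with requested standardised separations
(defaults: effect size 1.5 on both instruments, instrument-noise
correlation ρ = 0.3 — moderate discrimination with partial overlap,
the regime in which an OR combination is clinically interesting), and a
narrative diagnosis string whose worst keyword matches the overall
severity.

`generate_labeled_videos` realises the affected micro-vibration
phenotype as two cues: the 0.7 Hz component's amplitude shifted up by
`effect_size` SDs (increased low-frequency energy) and the 4 Hz
component attenuated by half that effect on the log scale (spectral
concentration, i.e. reduced complexity). The half-scale coupling of the
secondary cue is a declared convention.

What passing synthetic tests **does not** show: performance on real
faces (no texture, illumination, head pose, blink or expression
artefacts), robustness to acquisition variation, or that the reference
platform's accuracy is reproducible. The synthetic experiments validate
the machinery — that the pipeline recovers class structure it is known
to contain, and stays at chance when there is none.

## Problem sizes of the shipped experiments

The end-to-end recovery experiment trains on 150 of 200 synthetic
videos (2 s at 32 fps, 32×32 px, 8 slices of 8 frames) for 18 epochs
and evaluates AUC on the held-out 50; the null-effect check averages
AUC over 10 seeds at 60 videos / 5 epochs. Bootstrap coverage is
checked at B = 300 over 200 simulated datasets. These sizes are the
package's desk-scale defaults, chosen so the full suite runs in a few
minutes on a single CPU.

## Known limitations

* The NumPy network is CPU-bound and desk-scale; it is not a route to
  the reference platform's trained weights (out of scope).
* Keyword matching is exact, case-insensitive substring search —
  English only, no negation handling.
* The three-class (tier) F1 machinery is implemented and tested against
  oracles, but no reference per-class counts exist to validate against.
* The dual-binarization tier-threshold construction and the combined
  screen's lack of a continuous score are declared conventions where
  the underlying procedure is unspecified.
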