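# Methods

## Problem setting

Single-channel respiration-like waveforms sampled at 16 Hz are divided into
fixed-length segments (60 s for long free-breathing recordings, 30 s for
protocol recordings) and classified as *clean* or *noisy*. Two populations
are modelled: a *source* population used to pre-train the classifiers and a
*target* population — different subjects, different breathing behaviour — on
which the pre-trained models are evaluated and adapted. The target protocol
contains six breathing patterns (spontaneous Sp, chest Ch, shallow Sh,
abdominal Ab, slow Sl, fast Fa) separated by a breath hold, and results are
reported per pattern.

## Preprocessing

- Band-pass: Butterworth design of order 4 with cutoffs 0.05 and 0.70 Hz
  (3 and 42 breaths/min). "Order" follows the MATLAB/scipy `butter`
  convention: the design (prototype) order is 4, so the band-pass transfer
  function has order 8. This is the reading under which the stopband
  meaningfully suppresses cardiac-range content (|H(2 Hz)| ≈ 0.0096; a
  literal order-4 transfer function only reaches ≈ 0.097). The filter runs
  as a single forward pass by default; `zero_phase=True` switches to
  forward–backward filtering.
- Trimming: the first 3 s and last 1 s of each recording are dropped
  (acquisition transients); both lengths are parameters since conventions
  differ between systems.
- Segmentation: non-overlapping segments of exactly the requested length;
  the grid restarts after each excluded interval (breath holds are excluded
  by pattern tag) and remainders are dropped. A segment spanning two
  patterns is tagged with the pattern occupying the majority of its span.
- Normalization: z-score with the sample (N−1) standard deviation,
  idempotent; (numerically) constant segments are rejected rather than
  scaled by rounding noise.

## Features (SVM input)

Seven descriptors are computed per window:

- **ACF**: Ap1 and Ap2, the amplitudes of the first and second non-negative
  local maxima of the unbiased, lag-0-normalized autocorrelation at lags
  corresponding to 3–42 breaths/min (prominence ≥ 0.01), and their ratio.
  Restricting to non-negative maxima is deliberate: quasi-periodic
  breathing has positive ACF peaks at multiples of the breath period, and
  it makes Ap1 decay monotonically as broadband noise is added instead of
  jumping to a negative noise wiggle.
- **PSD**: the half-maximum band around the dominant peak of a single
  Hann-tapered full-window periodogram, with band edges (f_low, f_up)
  interpolated at the half-maximum crossings; bandwidth = f_up − f_low; and
  the power integrated over that region (crossing bins included) divided by
  the total power in 0.05–0.70 Hz. The full-window periodogram (rather
  than an averaged short-window Welch estimate) is a deliberate choice: on
  60-s segments a 256-sample Welch estimate has only ~6 averages, and its
  variance lets broadband noise masquerade as a concentrated band, erasing
  the contrast the normalized-power feature exists to encode. With fine
  resolution a breathing tone keeps ≥ 90% of band power inside its narrow
  main lobe while noise spreads over many independent bins (typically
  10–35%). Averaged windows remain available via `nperseg`; when used,
  window start positions are placed symmetrically so the estimate is
  exactly invariant under time reversal (hence under the mirror
  augmentations).

Descriptors are computed for the whole segment and for 15-s sub-segments
(no overlap on 60-s segments → 4 windows; 10-s overlap on 30-s segments →
also 4), and the sub-segment mean and sample standard deviation of each
descriptor complete a 21-value vector. The classifier uses a fixed 5-value
subset — whole-segment Ap1, std of sub-segment Ap1, whole-segment f_low,
mean sub-segment bandwidth, mean sub-segment normalized power — originally
identified by maximum-relevance minimum-redundancy selection; a greedy
MRMR implementation (mutual information on quantile-binned features,
relevance-minus-mean-redundancy criterion) is included for re-selection on
new data.

## Classifiers

**SVM.** RBF-kernel C-SVM on standardized features. C and γ are chosen by
Bayesian optimization (Matern-5/2 GP, expected improvement, 25 evaluations,
log-uniform over [1e−3, 1e3]²) of the 5-fold cross-validated
misclassification error, then refit on all training data. Decision values
are mapped to clean-class probabilities by a Newton-fitted logistic
(Platt-style); the map is monotone, so ranking metrics (AUC) are unaffected.

**CNN.** Fixed architecture: conv(1→10, k=32, stride 2) → ReLU →
conv(10→10) → ReLU → conv(10→5) → ReLU → conv(5→5) → ReLU → global average
pool → dense(5→2) → softmax, with edge-replication "same" padding, 5,962
trainable parameters in total. Stride-2 convolutions give a pre-pooling map
of 5 × ceil(N/16) steps, and global average pooling makes the network
length-agnostic. Forward and backward passes are implemented directly in
numpy — at this parameter count a deep-learning framework adds nothing.
Training: Adam (1e−3), batch 32, cross-entropy, up to 50 epochs with early
stopping on a stratified 10% validation split (patience 5, best weights
restored). Loss, optimizer and schedule are this package's choices; they
are exposed in `CnnHyper`.

**Heuristic baseline.** A rule-based index in the spirit of classic
breath-morphology SQIs: breaths are detected as prominent peaks/troughs of
the z-scored signal; a segment is *high* quality iff (a) the coefficient of
variation of plausible breath durations (1.43–20 s) is ≤ 0.25, (b)
plausible breaths that contain a trough between their bounding peaks cover
≥ 60% of the segment, and (c) breaths resampled to a common length
correlate with their mean template at ≥ 0.75 on average. All thresholds are
package conventions in `HeuristicConfig`, not a replication of any
published index's internals. Coverage (b) is defined as time covered by
well-formed breaths divided by segment duration, so a half-segment dropout
fails even though the surviving breaths are individually regular.

## Data augmentation

Four label-preserving transforms: mirroring about the x-axis (sign flip)
and y-axis (time reversal); amplitude modulation by
m(i) = sin(π i / (N−1)) (period twice the segment length, maximal at the
centre, optional floor to avoid exact zeros at the ends); slow-down
(remove floor(0.05 N) samples per end, Fourier-resample the central 90%
back to N — a 10% slower rate, below the 16.6% coverage that would change
a quality annotation); and speed-up (concatenate two same-label,
same-recording segments and resample 2N → N; partner chosen at random,
self-concatenation as fallback). ACF and PSD are invariant under both
mirrors, so mirrored variants have identical feature vectors — a designed,
tested property.

Balancing: every minority-class original contributes all variants the
policy allows (mirror → 2, each other method → 1); majority-class originals
are augmented one randomly chosen original at a time while the majority
total stays ≤ the augmented minority total. The final class difference is
at most the per-original variant count. For 30-s protocol data only
mirroring and modulation are used, so the rate-changing methods cannot blur
the distinction between breathing patterns.

## Transfer learning

**Adapted SVM.** The adapted decision function is the frozen source
function plus a learned perturbation,
f(x) = f_src(x) + Σᵢ αᵢ yᵢ (K(xᵢ, x) + 1), found by maximizing the dual
Σ αᵢ (1 − yᵢ f_src(xᵢ)) − ½ ΣΣ αᵢ αⱼ yᵢ yⱼ K′(xᵢ,xⱼ) subject to
0 ≤ αᵢ ≤ C_a, with K′ = K_rbf + 1 (the +1 absorbs a regularized bias
shift). This trades new-domain classification error against dissimilarity
from the source model: C_a → 0 recovers the source model exactly, and the
perturbation's RKHS norm is non-decreasing in C_a. The dual is solved by
box-constrained coordinate ascent (no equality constraint, so updates are
exact per coordinate); the source model's kernel scale and feature scaler
are reused since source and target share a feature space.

**CNN transfer.** Stage 1 copies the network and retrains only the dense
classification layer (convolutional weights bit-identical afterwards);
optional fine-tuning then un-freezes everything for a few epochs at a
lower rate (defaults 1e−4, 5 epochs vs. 1e−3 stage 1).

## Evaluation protocol

Splits are drawn at the recording level: 70% of recordings (rounded to
nearest) to train, 30% to test, 10 independent repeats, identical splits
reused for every model variant. Metrics: AUC (equals the Mann–Whitney
concordance probability, ties ½), plus accuracy / sensitivity /
specificity at threshold 0.5 with *clean* as the positive class (the
operating point is configurable; percentiles use linear interpolation).
Variants are compared with the two-sided Wilcoxon signed-rank test, exact
null distribution for n ≤ 25, zero differences dropped, all-zero
degenerating to p = 1. `run_experiment` assembles the full table: per
breathing pattern and classifier, the Original (pre-trained, no
augmentation), DA (pre-trained with augmentation) and TL+DA (DA model
adapted on the augmented target training split, per pattern) variants plus
the heuristic baseline, with median [25th–75th] summaries and pairwise
p-values. Pattern groups whose test split lacks a class are skipped with a
warning; a pattern whose training split lacks a class falls back to
adaptation on all patterns.

## Synthetic data

No public corpus of annotated wearable respiration exists, so the
generator emulates the study conditions. Breathing is a train of
raised-cosine breath cycles: inspiration rises as ½(1 − cos(π t/Tᵢ)),
expiration falls as ½(1 + cos(π t/Tₑ)), with pattern-specific
inspiration fraction (abdominal 0.35, chest 0.50, otherwise 0.42),
amplitude (shallow × 0.3) and rate ranges (Sp/Ch/Ab 10–16, Sh 12–18,
Sl 4–7, Fa 25–40 breaths/min — inside the filter passband). Per-breath
periods and amplitudes carry lognormal jitter (σ = 0.05 and 0.1); two slow
sinusoids (0.005–0.02 Hz, amplitude 0.15) model baseline wander and white
noise (σ = 0.02) models the sensor floor. Breath holds are flat baseline.
All randomness flows through explicit seeds; identical (spec, seed) gives
bit-identical output.

Artefacts are injected into known windows: additive baseline steps, white
noise bursts, amplitude dropouts (with a 2% residual, since real contact
loss retains sensor noise), motion spikes (~1/s at ± severity·σ) and
clipping. A segment's ground-truth class is *noisy* exactly when artefact
windows cover ≥ 16.6% of its length — the same time-coverage guideline
human annotators apply. The default noisy mixture of the study corpora
uses noise bursts, dropouts and spikes in equal shares (severity uniform
in [1, 3], coverage 25–60%): these reliably destroy breath structure (the
heuristic index rejects ≥ 90% of fully corrupted segments), whereas
baseline steps and clipping at comparable severities often preserve breath
timing and would not merit a noisy annotation.

What the generator does **not** model: bio-impedance electronics, electrode
placement, reference airflow channels, annotator disagreement, or the
noise statistics of any particular clinical corpus — artefact severities
are uncalibrated placeholders. Passing tests therefore demonstrate that
the pipeline's machinery behaves as specified and that the transfer
mechanism recovers a constructed domain shift; they do not certify
clinical performance numbers.

## Study sizes and numerical conventions

The reproduction script and the end-to-end tests use a source corpus of 20
subjects × 21 minutes (≈ 420 60-s segments, 10–16 breaths/min) and a
target corpus of 20 subjects × 10.5 minutes (≈ 420 30-s segments, 25–40
breaths/min), half of each corrupted — sizes chosen to mirror the order of
magnitude of a per-pattern clinical subset while keeping a full run around
a minute on one CPU. Bayesian optimization uses 15 evaluations there (25
by default elsewhere). Ties in AUC count ½; MRMR discretizes into 8
quantile bins and breaks score ties by column order; the coordinate-ascent
dual solver stops when the largest α update falls below 1e−8·max(C_a, 1)
or after 200 passes; CNN training is reproducible to ≤ 1e−6 under a fixed
seed (exactly reproducible in practice on one thread).

## Known limitations

- The adapted-SVM probability map is refit on adaptation data; with a tiny
  C_a the hard predictions equal the source model's but calibrated
  probabilities may differ slightly.
- The heuristic index needs ≥ 3 detected peaks; 30-s segments of very slow
  breathing (≤ 5 breaths/min) can be called *low* despite being clean —
  consistent with the general difficulty of quality assessment for slow
  patterns.
- Majority-class balancing adds whole per-original variant groups, so
  exact count equality is only guaranteed up to the variant count.
- The CNN trains on equal-length segments (a clear error otherwise);
  mixed-length inputs are supported at inference thanks to global average
  pooling.
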