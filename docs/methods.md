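# Methods

## Ordinal symbolization

A series x_1..x_T is embedded with dimension D and delay τ: segment s starts
at sample t and contains x_t, x_{t+τ}, …, x_{t+(D−1)τ}, for t = 1..T−(D−1)τ
(stride 1, so segments overlap).  Each segment maps to the permutation of
ranks of its samples, written time-ordered with 0 the smallest — an
increasing segment is [0123], a decreasing one [3210].  Ties are broken by
temporal order (the earlier sample gets the lower rank), the standard
Bandt–Pompe convention; it is deterministic and matches common
implementations.  Patterns are enumerated lexicographically over rank
tuples, so indices are stable across runs and platforms.  The defaults
D = 4, τ = 1 on 3000-sample epochs give 2997 segments over 24 patterns,
ample for stable frequencies.

## Generalized weighted probabilities

Segment weights are the population variance of the D raw samples (the
"local variance" convention of weighted permutation entropy; sample variance
would only rescale all weights by D/(D−1) and cancel in the ratio, so the
choice is immaterial to results).  Weights enter as w^{q/2}; the exponent is
evaluated in log space so extreme |q| (up to 10 by default, i.e. w^±5)
neither overflows nor underflows.

Zero-variance segments need a convention because w^{q/2} is 0^x:

- q = 0: every segment contributes weight 1 (w⁰ := 1), which reduces the
  formula exactly to relative pattern counting.
- q > 0: weight 0 — flat segments carry no amplitude information.
- q < 0: the weight diverges; such segments are excluded from numerator and
  denominator and counted in `PatternDistribution.n_degenerate`.  If *all*
  segments are flat and q ≠ 0, a `DegenerateSignalError` is raised rather
  than fabricating an epsilon-dependent distribution.  Physiological EEG
  never triggers this; it matters only for synthetic or clipped inputs.

## Entropy, disequilibrium, complexity

All logarithms are natural.  H = S / ln(D!) and C = Q·H are ratios/products,
so the base cancels anywhere results are compared.  The disequilibrium is
Q = Q₀ · JSD[P, P_uniform] with the Jensen–Shannon divergence
JSD[P,U] = S[(P+U)/2] − (S[P]+S[U])/2 and

    Q₀ = −2 { ((M+1)/M) ln(M+1) − 2 ln(2M) + ln M }⁻¹,   M = D!,

the closed-form inverse of the divergence between a point mass and the
uniform distribution.  Q is therefore exactly 1 for a fully ordered pattern
distribution and 0 for the uniform one; tests verify both by direct
evaluation.  A probability vector counts as normalized when |Σp − 1| ≤ 1e−9.

## Epoch preparation

Raw hypnogram labels follow the Rechtschaffen–Kales dialect of Sleep-EDF
annotation files; stages 3 and 4 are merged into N3 (AASM five-class
scheme), "Movement time" and unscored epochs are dropped with a logged
count.  Sample indices are 0-based and epoch windows half-open, so adjacent
epochs share no sample; trailing partial epochs are discarded.

Rebalancing runs in a fixed order: (1) the N2 class is downsampled by
retaining ⌈n/2⌉ uniformly sampled epochs (seeded, without replacement);
(2) N1 and W are augmented with one epoch per pair of exactly contiguous
same-stage epochs, cut from the continuous signal starting halfway into the
first of the pair (origin marked `augmented`); (3) at every stage
transition between consecutive epochs, the two flanking epochs are removed
— augmented epochs that survive to this step are treated like originals.
Gapped same-label pairs are never augmented, and augmentation never crosses
recording boundaries.  Short stage runs can vanish entirely at step (3);
with realistic hypnograms this prunes mostly N1 and W transitions, which is
why step (2) precedes it.

## Classifiers

The split is stratified by stage (15% test); N1 and W scarcity makes
unstratified splits unstable.  Hyperparameters are tuned by randomized
search — 75 candidates and 5-fold CV by default — scored on accuracy, with
the winning configuration refit on the full training split.  The search
spaces (tree counts/depths/learning rates; SVM C and γ on log-uniform
grids) are package defaults exposed in `classify.SEARCH_SPACES`; reported
CV accuracy ± sd is that of the best configuration, while the held-out
split feeds the confusion matrices.  XGBoost uses exact greedy split
finding: at the few-hundred-epoch scale histogram binning can place
thresholds at cluster edges instead of margin midpoints.  Feature
importance is total split gain normalized to sum 1 (gain has no analogue
for the SVM, which raises `UnsupportedModelError`).  Cross-validation folds
are drawn at the epoch level; with a single synthetic subject per run there
is no subject boundary to respect, but on multi-subject data this measures
within-distribution accuracy, not leave-subject-out generalization.

## Synthetic data

Epochs are synthesized in the frequency domain: a 1/f^slope amplitude
spectrum plus per-band boosts (delta 0.5–4 Hz, theta 4–8, alpha 8–12, sigma
12–16, beta 16–30), seeded uniform random phases, inverse FFT, rescaled to
the stage's amplitude (µV) and zero-meaned.  N2 additionally receives
Gaussian-enveloped 13.5 Hz spindle bursts (~3 per epoch) and sparse
biphasic K-complex-like transients; counts are Poisson with the archetype's
rate.  The default archetypes follow textbook stage physiology — N3
delta-dominated at ~3× wake amplitude, N1 theta at intermediate amplitude,
REM mixed theta/beta, wake low-amplitude alpha/beta — and were fixed once
so that the q = 0 entropy ordering H(N3) < H(N2) < H(W), H(R) and the
monotone-pattern dominance of N3 hold, as they do in real sleep EEG.

Hypnograms come from a 5-state Markov chain parameterized by mean run
lengths (self-transition 1 − 1/run) with successor weights encoding the
usual stage graph (W→N1, N1→N2, N2→{N3,R}, N3→N2, R→{N1,N2,W}); defaults
give a stationary distribution of roughly 7% W, 10% N1, 54% N2, 16% N3,
14% R.  Short recordings are bursty — stage proportions fluctuate strongly
about these values — which is realistic and exercised in the tests.

What the generator does **not** emulate: inter-subject variability,
artifacts and electrode noise, sleep-cycle (ultradian) structure beyond the
Markov chain, stage-transition dynamics inside an epoch, and the substantial
class overlap of real EEG.  Synthetic stages are therefore far more
separable than real ones: classifiers reach ≳0.95 accuracy here versus
~0.7–0.8 on real polysomnography.  Passing tests validate the machinery and
the direction of the effects (amplitude-weighted features ≥ unweighted,
deep-sleep monotone-pattern dominance), not real-data accuracy levels.

The planted benchmark (`make_benchmark_dataset`) isolates the amplitude
channel: every epoch is unit-variance white noise carrying equal numbers of
monotone-ramp and zigzag transients, and the two classes differ only in
*which* transient type is large-amplitude.  Ordinal frequencies at q = 0
are class-identical by construction (verified distributionally), so
unweighted PDF features classify near chance while any |q| > 0 separates
the classes — the cleanest possible demonstration that the entropic index
adds information orthogonal to pattern order.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the full pipeline at desk
scale: 3 synthetic subjects × 220 epochs (about 480 epochs after
rebalancing), 5 seeds × 120 epochs for the pooled qualitative checks, a
5-candidate random search for the XGBoost comparison, and 100 epochs per
class in the benchmark.  These sizes leave every stage dozens of test
epochs while keeping a full run in a few minutes; all sizes are constants
at the top of the script.  Seeds are threaded explicitly everywhere (no
global random state); feature tables are bit-for-bit reproducible given
(epochs, config, seed).

Known limitations: EDF writing supports exactly the dialect the package
itself produces (single channel, 16-bit, 1-s records, one annotation
record); amplitudes quantize to the 16-bit range on writing; the boundary
between "near chance" and "informative" in the benchmark assertions is
necessarily a judgement call; and no artifact rejection or filtering is
applied anywhere — by design, since the ordinal statistics are themselves
robust to monotone amplitude distortions.
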