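# sleepops

Ordinal-pattern complexity features for EEG sleep staging.

Sleep stages (wake W, light sleep N1/N2, deep sleep N3, REM R) differ in the
balance between order and randomness of the EEG: deep sleep is dominated by
high-amplitude slow waves, wakefulness by low-amplitude fast activity, N2 by
transient spindles and K-complexes.  `sleepops` turns each 30-s epoch of a
single EEG channel into features built from **generalized weighted ordinal
patterns** and uses them to classify the five stages.  It is aimed at
researchers who want interpretable, feature-engineered sleep staging rather
than black-box models, and at anyone studying amplitude-sensitive ordinal
statistics of physiological time series.

## The statistics

Each epoch x_1..x_T (T = 3000 at 100 Hz) is sliced into overlapping segments
of D = 4 samples, delay τ = 1.  A segment's ordinal pattern π is the
permutation ranking its samples; its weight w is the population variance of
its samples.  The generalized weighted probability of pattern π_i at entropic
index q is

    p(π_i, q) = Σ_{s : π_s = π_i} w_s^{q/2}  /  Σ_s w_s^{q/2}

so q = 0 recovers plain Bandt–Pompe pattern counting (permutation entropy,
PE), q = 2 the variance-weighted variant (WPE), negative q emphasizes
low-amplitude segments and positive q high-amplitude ones.  From any pattern
distribution P the package computes Shannon entropy S, normalized entropy
H = S / ln(D!), the disequilibrium Q = Q₀ · JSD[P, uniform] (Jensen–Shannon
divergence, normalized so Q = 1 for a fully ordered distribution), and the
statistical complexity C = Q · H, which vanishes for both perfectly ordered
and perfectly random signals.

Sweeping q over the integers −10..10 (21 values) gives four feature sets per
epoch: `PE_C` (H and C at q = 0; 2 features), `GWPE_GWPEC` (H and C per q;
42), `PDF` (the 24 pattern probabilities at q = 0), and `GWPDF` (all 24 × 21
= 504 generalized probabilities).  Epochs are rebalanced before training:
the dominant N2 class is randomly halved, scarce N1/W epochs are augmented
with windows cut at the midpoint of consecutive same-stage epochs, and the
two epochs flanking every stage transition are dropped.  Random forest, RBF
SVM and XGBoost classifiers are tuned by randomized search (75 candidates,
5-fold CV) on a stratified 85/15 split.

## Worked example

```python
from sleepops.ordinal_core import OrdinalConfig, ordinal_distribution, statistical_complexity
from sleepops.synthetic_data import DEFAULT_ARCHETYPES, generate_epoch

config = OrdinalConfig()  # D=4, tau=1, q = -10..10
for stage in ("W", "N2", "N3"):
    epoch = generate_epoch(DEFAULT_ARCHETYPES[stage], seed=42)
    dist = ordinal_distribution(epoch, config, q=0.0)
    point = statistical_complexity(dist)
    mono = dist.probs[0] + dist.probs[23]
    print(f"{stage}: H={point.H:.3f}  C={point.C:.3f}  p[0123]+p[3210]={mono:.3f}")
```

prints

```
W: H=0.957  C=0.054  p[0123]+p[3210]=0.170
N2: H=0.810  C=0.184  p[0123]+p[3210]=0.428
N3: H=0.648  C=0.251  p[0123]+p[3210]=0.649
```

Deep sleep's slow waves make the monotone patterns [0123] and [3210]
dominate, driving entropy down and complexity up, while the wake epoch is
close to the random corner (H ≈ 1, C ≈ 0) — the separation the classifiers
exploit.

A command-line interface wraps the same pipeline:

```
sleepops simulate --n-epochs 200 --seed 1 --out-dir data/
sleepops train --feature-set GWPDF --model gradient_boosted_trees \
         --seed 1 --out report.json
```

## Layout

- `sleepops.ordinal_core` — patterns, generalized weighted distributions, H/Q/C.
- `sleepops.sleep_io` — EDF signal + EDF+ hypnogram reading (MNE), epoch tiling,
  feature-table CSV schema, minimal EDF writer for fixtures.
- `sleepops.feature_pipeline` — rebalancing, the four feature sets, stage-median
  q-profiles.
- `sleepops.classify` — split/tune/evaluate harness, confusion matrices,
  total-gain feature importance.
- `sleepops.synthetic_data` — stage archetypes, hypnogram Markov model,
  planted benchmark.

See `docs/methods.md` for the modelling details and limitations.
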