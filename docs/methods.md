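# Methods and design notes

## Scope and data model

The pipeline operates on *sessions*: per-neuron spike timestamps (seconds,
strictly ascending) with region/hemisphere/waveform metadata, plus a trial
event table (pedal release, outcome onset, choice side, outcome label, a
bilateral-movement flag). Waveform measurements (spike duration/width) are
inputs, not computed here; pedal-position traces are not modelled — release
is a single event timestamp produced upstream.

Trials enter the analysis only if the outcome is defined (rewarded or
nonrewarded — immature trials received no feedback) and only one forelimb
moved after the action. Laterality is relative to the recorded hemisphere:
a trial is *contra* when the choice side is opposite the hemisphere. All
windows are half-open `[start, end)` in ms relative to the trigger; a spike
exactly at the trigger belongs to the post window.

## Feature vector (88 entries)

8 fundamental + 4 conditions (AC, AI, OC, OI) × (8 timing + 12 rate).

* Timing and rate features for **action** conditions are computed on the
  pre-action side `[-500, 0)` ms around release; **outcome** conditions on
  the post-outcome side `[0, 500)` ms around reward/error-cue onset. The
  post-action and pre-outcome epochs are movement-contaminated and enter
  only through each condition's opposite-side mean rate and the FRc index
  (FR_pre over `[-500, 0)`, FR_post over `[0, 500)`). A config switch
  (`outcome_timing_window="full"`) extends outcome timing features to the
  full ±500 ms instead.
* Estimator conventions (fixed, testable defaults): sample SD (n−1);
  skewness g1 = m₃/m₂^1.5; Pearson (non-excess) kurtosis m₄/m₂²; quartiles
  by linear interpolation; KS D on spikes pooled across the condition's
  trials.
* Mean rates are pooled counts / (n_trials × window length). Peak rates are
  maxima of 10 ms bins tiled from the window start — 10 ms divides every
  canonical window, which guarantees peak ≥ mean on the same window.
* ACG: 1 ms positive-lag bins to 250 ms, zero-lag self-pairs excluded,
  normalized by (n_spikes × binwidth) to a coincidence rate; the three
  biases are medians of the normalized values over 0–100, 0–50 and
  50–250 ms. PETHs use 20 ms bins and satisfy the conservation identity
  Σ(rate × binwidth × n_trials) = total aligned spikes.
* Ongoing rate = spike count / span between first and last spike.
* Missing data are masked (NaN), never silently substituted: timing/KS
  features require ≥10 pooled spikes (`min_spikes`); a neuron-condition row
  requires ≥5 trials (`min_trials`), otherwise the row is excluded.
* Lv uses the squared ratio term 3/(n−1)·Σ((Iᵢ−Iᵢ₊₁)/(Iᵢ+Iᵢ₊₁))²; this is
  the form with the documented limits (0 for regular trains, expectation 1
  for Poisson trains), which the tests verify by simulation.

### Trial-count matching

By default (`match_trial_counts=True`) the feature builder equalises
rewarded/nonrewarded trial counts within each choice side by randomly
subsampling the majority outcome (deterministic per session). Rationale:
at ~72% correct performance rewarded rows would otherwise be built from
~2.5× more trials than nonrewarded rows, and estimators with
sample-size-dependent bias (KS D, peak rate, kurtosis) would encode that
imbalance — a classifier can then separate the conditions even when firing
statistics are identical. Matching removes this artifact at the cost of
noisier rewarded-row features; switching it off reproduces the
use-all-trials convention.

## Synthetic study generator

The generator defines the study conditions under which the pipeline is
tested. The task simulator produces block-structured self-initiated trials:
holding ≥1 s (1 s + exponential extra, mean 0.5 s), reward delay drawn
uniformly from {0.3, …, 0.7} s, correct probability 0.72, blocks alternating
after >30 correct with 80% accuracy over the last 10 trials (or 100
rewards), 5% immature trials, 5% bilateral-movement flags.

Spike trains are inhomogeneous renewal processes sampled by time-rescaling:
unit-rate gamma(k, 1/k) increments in rescaled time mapped through the
inverse cumulative intensity (k = 1 is exactly inhomogeneous Poisson;
E[Lv] ≈ 3/(2k+1)). Intensities are baseline (log-normal across neurons,
median ≈ 4–5 Hz) plus per-trial modulation on rewarded trials — a Gaussian
bump (amplitude/latency/width per region) and/or a box-car suppression —
while nonrewarded trials receive only a mean-preserving cosine
redistribution of rate within the 500 ms outcome window ("timing shift",
one full period, random phase per neuron). Regional presets encode the
motifs the interpretation stage must recover:

| region | motif | key parameters (before gradient scaling) |
|---|---|---|
| dCA1 | strong early bump | 10 Hz, 60 ms latency, 40 ms width, 70% of neurons |
| vCA1 | small bump + deep suppression | 3 Hz bump; depth 0.7 from 150 ms for 350 ms, 70% |
| LEC | suppression-dominant (negative FRc) | depth 0.65 from 100 ms for 400 ms, 80%; 1.5 Hz bump, 25% |
| PPC | excited/suppressed mixture, burstiness-linked | 4 Hz bump 40% / depth 0.5 35%; shift 0.2 |
| M2 | rate-silent timing shift only | shift 0.8 |
| M1 | weak bump + direction-dependent timing | 2 Hz bump 30%; shift 0.4; contra gain 1.5 |

An `EffectGradient` (dCA1 1.0, vCA1 0.95, LEC 0.65, PPC 0.6, M2 0.35,
M1 0.3) multiplies all three modulation terms, encoding the hypothesized
hierarchy; a zero gradient yields label-exchangeable data. Population
realism comes from per-neuron jitter (log-normal amplitude ×exp(N(0,0.4)),
latency ±15 ms, width ×exp(N(0,0.2)), suppression depth ×U(0.7,1)),
per-neuron timing-shift phase, and per-trial log-normal gain (σ = 0.3) on
the modulation. The preset amplitudes are calibration choices that
reproduce the qualitative regional ordering at the simulated scale; they
are not estimates of real effect sizes, and absolute accuracies from the
generator should not be compared to values measured on real recordings.
What the generator does **not** emulate: cross-neuron correlations and
shared population states, learning dynamics across blocks, non-stationary
baselines, and realistic waveform-feature/cell-type structure — so passing
tests demonstrate pipeline correctness and sensitivity, not biological
fidelity of any particular number.

## Preprocessing cascade

Fit on the training split only, replayed on held-out rows from stored
statistics: mean imputation → z-scoring (zero-variance and all-missing
features dropped with recorded reasons) → greedy collinearity pruning
(pairs in descending |r|; of a pair with |r| > 0.80 the feature less
point-biserially correlated with the label is removed; ties remove the
lexicographically later name; a 1e-12 guard keeps pairs constructed at
exactly the threshold) → importance selection (LightGBM split-gain ranking,
top ceil(20%) retained — ceil so selection is never empty). SMOTE
(k = 5 nearest minority neighbours, synthetic rows x + u·(x_nn − x),
u ~ U(0,1)) balances classes inside training fits only, never evaluation
data; the cascade is refit inside every cross-validation fold.

## Decoding protocol

Per region: stratified 80/20 split per repeat seed (default 3 repeats);
optional stratified 10-fold comparison of a roster (three gradient-boosted
variants — LightGBM, XGBoost, sklearn GradientBoosting — plus logistic
regression, LDA, random forest, k-NN, naive Bayes and a stratified dummy);
randomized hyperparameter tuning (default 20 candidates over fixed,
documented grids, stratified 5-fold, objective = mean accuracy, the default
configuration retained unless beaten); final fit on the oversampled
training split and evaluation on the untouched test split. Accuracy uses
the 0.5 probability threshold; AUC is the Mann–Whitney concordant-pair
fraction with ties counted half, which the tests verify equals the
trapezoidal area under the constructed ROC. Study-scale runs default to
`n_iter=0` (no tuning) so the full 6-region × 3-architecture report stays a
sub-minute computation; tuning is a per-call option.

## Statistical validation

* **Permutation test**: with the model's test-set predictions held fixed,
  labels are permuted (class counts preserved exactly) 1,000 times; the
  one-sided p is max(#{null ≥ observed}, 1)/1,000 — the floor gives the
  1/1,000 resolution limit, and Bonferroni correction with
  m = regions × architectures (18 in the full design) makes 0.0180 the
  smallest attainable corrected p. Repeats are aggregated by pooling their
  test-set predictions (an averaging switch exists).
* **Two-way ANOVA** on held-out accuracies (region × architecture, repeats
  as replicates) from closed-form balanced sums of squares — exactly
  testable against hand-worked examples and statsmodels, with no hidden
  contrasts. Degenerate all-equal inputs report F = 0, p = 1 by convention.

## Interpretation

Attributions are exact path-dependent tree-Shapley values in margin
(log-odds) units. LightGBM and XGBoost supply native per-feature
contributions; for sklearn gradient boosting the package computes, per
tree, the cover-weighted conditional expectation v(S) for every subset of
the features the tree uses (vectorized over subsets) and combines them with
the classical Shapley weights — validated against an all-subsets brute-force
oracle and a closed-form single-split decomposition. Additivity
(base + Σφ = f(x)) holds to double precision for the sklearn path and to
float32 rounding (~1e-6 relative) for the boosters' native contributions.

Per region the best architecture (highest mean test accuracy; ties to the
lower repeat id) is attributed across its repeats; features are ranked by
mean |φ| and the *consistent set* is the intersection of the top-9 across
repeats. The strategy report tags consistent features as
fundamental/timing/rate × action/outcome; the probability summary gives
per-region, per-class quartiles and a polarization index (fraction of
predicted probabilities outside [0.25, 0.75]).

## Numerical and testing choices

* All randomness flows through explicit seeds (numpy Generators,
  SeedSequence spawn keys per region/session); identical configs reproduce
  reports byte-for-byte on the same platform.
* Cv returns exactly 0 for constant ISIs (short-circuit before the floating
  division); Lv is exactly 0 there because adjacent differences vanish.
* Renewal sampling uses a 1 ms intensity grid; trapezoid-level accuracy is
  sufficient because modulation widths are ≥40 ms.
* Test problem sizes: the hierarchy property uses 5 study seeds at
  100 neurons/region (two 120-trial sessions), LightGBM only, 2 repeats;
  the type-I-error property uses 10 zero-gradient seeds at 60
  neurons/region; mechanism recovery reuses the first three hierarchy
  seeds with 3 repeats. These desk-scale sizes keep the full suite under
  five minutes while leaving the planted ordering statistically resolvable.

## Known limitations

* Neurons are simulated independently; decoders can exploit only
  single-neuron statistics, matching the neuron-by-neuron design but not
  testing population decoding.
* The two rows of one neuron can fall on opposite sides of a split;
  fundamental features shared by both rows therefore allow mild
  memorization. This mirrors the row-level splitting convention of the
  protocol rather than a neuron-level group split.
* Hyperparameter grids are package choices; the comparison/tuning machinery
  is seed-deterministic but grid contents are not prescribed anywhere.
* With ~200 rows per region, held-out test sets are small (~40 rows);
  per-repeat accuracies are correspondingly noisy, which is why validation
  aggregates over repeats.
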