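# rewarddecode

Neuron-by-neuron decoding of trial outcome (rewarded vs nonrewarded) from
single-unit spike-train features, across six brain regions recorded in rats
performing a self-initiated left–right pedal choice task: primary and
secondary motor cortex (M1, M2), posterior parietal cortex (PPC), lateral
entorhinal cortex (LEC), and dorsal/ventral hippocampal CA1 (dCA1, vCA1).

The package is aimed at systems neuroscientists who want to quantify and
compare *how much* reward information a region's typical neuron carries and
*what kind of code* it uses (firing-rate changes vs spike-timing structure),
using interpretable machine-learning models rather than hand-picked response
metrics.

## The analysis

Each neuron contributes two samples to a region's dataset — its averaged
activity profile under rewarded trials and under nonrewarded trials — each
described by 88 features:

* **fundamental spiking properties** (constant across a neuron's two rows):
  ongoing rate, spike duration/width, ISI variability
  (Cv = SD(ISI)/mean(ISI) and the local variation
  Lv = 3/(n−1) · Σᵢ [(Iᵢ − Iᵢ₊₁)/(Iᵢ + Iᵢ₊₁)]², both 0 for regular firing and
  ≈1 for Poisson firing), and three autocorrelogram biases (medians of the
  normalized ACG over 0–100, 0–50 and 50–250 ms lags);
* **task-related spike-timing properties** per trial condition
  (action/outcome × contra/ipsilateral): moments (mean, SD, skewness,
  kurtosis), quartiles (Q1, Q2, Q3) and the Kolmogorov–Smirnov distance D of
  aligned spike times from temporal uniformity;
* **task-related firing-rate properties** per condition: mean rate in six
  windows, peak rate in five windows, and the rate-change index
  FRc = (FR_post − FR_pre)/(FR_post + FR_pre) over ±500 ms around the
  trigger.

A leakage-free cascade (mean imputation → z-scoring → |r| > 0.80 collinearity
pruning → top-20% importance selection, with SMOTE oversampling inside
training fits only) feeds gradient-boosted classifiers evaluated on stratified
80/20 splits over repeated seeds. Performance is validated by a 1,000-fold
label-shuffle permutation test (Bonferroni-corrected across
regions × architectures) and a balanced two-way ANOVA on held-out accuracies;
each region's code is characterized by exact tree-Shapley attributions in
log-odds units, the cross-repeat consistent top-9 features, and the
polarization of predicted probabilities.

Because the original recordings are not publicly deposited, the package ships
a synthetic study generator (`synthetic_data`) that emulates the task
(≥1 s holding, 0.3–0.7 s reward delays in 0.1 s steps, ~72% correct, block
structure) and the six regions' qualitative response motifs — dCA1 transient
post-reward excitation, vCA1 peak-plus-suppression, LEC suppression-dominant
responses, PPC excited/suppressed mixtures, M1/M2 rate-silent timing effects —
with a configurable effect gradient encoding the hypothesized hierarchy
dCA1/vCA1 > LEC/PPC > M2/M1.

## Worked example

```python
from rewarddecode import RunConfig, run_study

report = run_study(RunConfig(seed=0))   # 6 regions x 100 neurons, 3 models
print(report.to_text())
```

This simulates the study, extracts features, trains LightGBM/XGBoost/sklearn
gradient boosting per region over three repeated splits, and prints (excerpt):

```
region architecture  mean_accuracy  sd_accuracy  mean_auc  sd_auc  n_repeats
   LEC     lightgbm         0.7583       0.0878    0.8333  0.0761          3
    M1     lightgbm         0.4667       0.0382    0.4850  0.0974          3
  dCA1     lightgbm         0.6917       0.0144    0.8458  0.0115          3
  vCA1     lightgbm         0.7583       0.0382    0.8208  0.0425          3

region architecture  observed_accuracy  p_uncorrected  p_corrected  significant
  dCA1     lightgbm             0.6917         0.0010       0.0180         True
...
region       0.5861  5.0000 0.1172 35.0450 0.0000
```

Hippocampal and entorhinal regions decode reward at ~0.69–0.76 accuracy and
beat all 1,000 label shuffles (the corrected p of 0.0180 is the resolution
limit of 1,000 permutations × 18 comparisons), motor cortex sits near chance
at this simulation scale, and the ANOVA's region main effect (F(5,36) = 35.0,
p < 10⁻³) confirms the planted hierarchy. The consistent top-Shapley features
recover each region's generative mechanism — post-reward spike-timing
statistics for dCA1 (`oc_timing_kurtosis`, `oc_timing_mean_ms`), the
firing-rate-change index for LEC (`oc_frc`, `oi_frc`).

A command-line interface mirrors the library:

```bash
rewarddecode simulate --out sessions/ --seed 0
rewarddecode features --sessions sessions/ --out features.csv
rewarddecode run-study --seed 0 --out report/
```

## Layout

```
src/rewarddecode/
  core_io.py         session/trial/neuron types, CSV session format, alignment
  synthetic_data.py  task simulator and region-archetype spike generator
  spike_features.py  Cv/Lv/ACG/PETH/KS/FRc and the 88-feature matrix
  preprocess.py      impute/scale/prune/SMOTE/select cascade
  decode.py          rosters, CV comparison, tuning, repeated evaluation
  inference_stats.py permutation test, Bonferroni, balanced two-way ANOVA
  interpretation.py  tree-Shapley attributions, rankings, strategy reports
  orchestrator.py    end-to-end study runner and fixtures
  cli.py             click-based command-line interface
docs/methods.md      modelling and design notes
```
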