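# Methods

## Problem setting

A morphological-profiling screen measures, for each compound and each
imaging concentration, a feature vector of Z-scores against vehicle
control ("profile"). A sparse compound × assay matrix of potencies
(pIC50 = −log10 IC50[M], or a toxicity ratio) provides labels; the
fill rate is around 5%. The goal is to retrieve the rare highly
potent compounds (pIC50 ≥ 7) in each assay, for hit prioritisation or
liability flagging.

Training a high-threshold classifier directly suffers from label
imbalance. The concentration-shift method instead trains at a
moderate threshold (pIC50 ≥ 5) on high-concentration (20 μM)
profiles, where both signal and positives are plentiful, and performs
inference on low-concentration profiles of the same compounds. The
physical carrier of the method is the dose-response law: a compound's
phenotype amplitude at imaging concentration *c* scales with
`c / (c + IC50)`, so lowering *c* silences moderately potent
compounds while highly potent ones keep most of their signal. An
Active call on a low-concentration profile therefore implies high
potency.

## Model and calibration

**Classifier.** An ensemble of 8 feed-forward networks (default
hidden layers 256/128, ReLU, dropout 0.25, per-task sigmoid heads)
maps one profile to per-assay activity probabilities. Loss is masked
binary cross-entropy: unobserved (compound, task) cells contribute
exactly nothing to value or gradient. Optimisation is Adam;
minibatches are drawn with replacement. Ensemble members differ only
in seed-derived initialisation and batch order; predictions are the
arithmetic mean of member probabilities (the combination rule was an
open choice; the mean keeps the output a probability and is the
standard default). The networks are implemented directly in numpy
with hand-written gradients: no installed training framework handles
per-cell label masking in a multitask head, the models are small
enough to train in seconds on a CPU, and explicit code keeps training
bit-reproducible for a given seed.

**Conformal calibration.** Mondrian cross-conformal prediction over
k = 5 scaffold-grouped folds. For each fold, an ensemble is trained
on the other four; the held-out fold supplies per-(task, class)
conformity scores `CM(label, output) = |1 − label − output|`, and the
*same fold model* scores the test compounds, so each fold's
calibration scores and test scores are exchangeable. P-values use the
inclusive, unsmoothed counting formula (fraction of calibration
scores ≤ the test score) and are averaged over folds; a fold whose
calibration set lacks a class for a task is skipped in that task's
average, and if every fold is skipped the decision is Uncertain. The
common `(count+1)/(n+1)` smoothing is available behind a flag but off
by default. Decisions at significance ε (default 0.05): Active iff
`p₁ > ε` and `p₀ ≤ ε`; Inactive symmetrically; Uncertain otherwise.
The full-data ensemble is trained separately and its mean probability
kept as the ranking score for AUC metrics (p-values are fold-averaged
order statistics and make poorer rankers; probabilities vs `p₁` vs
`p₁ − p₀` are all exposed in the prediction table).

Calibration happens once, on training-concentration profiles;
concentration-shift inference is a pure prediction pass, so one
fitted calibrator serves the whole concentration grid.

## Dataset operations

- **Binarization** is inclusive (value ≥ threshold → 1); unobserved
  cells stay masked everywhere downstream.
- **Test-set selection**: compounds with a maximum *observed* potency
  ≥ 8 whose scaffold occurs in no training compound; capped at 5% of
  the library by seeded sampling of whole scaffold groups (keeping
  the scaffold sets of the two sides disjoint). Uniqueness within the
  test set is not required.
- **Folds**: scaffold groups are allocated whole, largest first, each
  to the currently smallest fold (ties to the lowest index; group
  order seeded). Fold sizes then differ by at most the largest group.
- **Assay eligibility**: an assay enters the evaluation when it has
  enough labelled data at *both* potency thresholds on both sides of
  the split, plus a model-quality gate — the moderate model's
  out-of-fold (5-fold cross-validated) AUC-ROC must reach 0.7. The
  production-scale counts (train ≥ 100 labelled with ≥ 25 per class;
  test ≥ 10 with ≥ 5 per class) are the function defaults. At the
  desk scale used here (~100 labelled cells per assay) those absolute
  counts are unattainable by construction, so the packaged study
  conditions use proportionally scaled counts (train ≥ 50 labelled,
  ≥ 10 per class — ≥ 4 in the rare-tail regime, which is exactly the
  regime under study; test ≥ 8, ≥ 3 per class).

## Evaluation

High-potency precision and recall are computed from the conformal
decisions against the high threshold, reported with their counts
(TP / Active calls and TP / actual positives); zero Active calls is
reported as precision 0 with counts (0/0), and recall is undefined
without actual positives. AUC-ROC is the Mann–Whitney statistic
(ties half-credited), AUC-PR is step-wise average precision (both via
scikit-learn), and AUC-PR is additionally RIPtoP-rescaled,
`(AUC-PR − baseline)/(1 − baseline)`, with the baseline equal to the
assay's test-set active fraction at the high threshold, so values are
comparable across assays with different imbalance. Model-vs-model
deltas are computed on AUC-ROC and on the RIPtoP-corrected (not raw)
AUC-PR, on identical test-compound and assay sets. Compounds without
a measured value for an assay are excluded from that assay's metrics.
Displayed precisions are rounded half-up to 3 decimals.

## Synthetic screen

The generator emulates the structure the method relies on, not images:

- **Latent potency.** Each compound has an engagement rate
  (Beta(2, 3)) deciding which assays it touches; engaged cells draw
  pIC50 from a two-component truncated normal mixture on [4, 9]
  (weights 0.7/0.3, means 5.2/6.9, SDs 0.6/0.9) plus a per-compound
  offset (SD 0.7) shared across assays. The offset creates broadly
  potent compounds and also raises the engagement rate (coupling
  0.25) — the frequent-hitter behaviour of real screening actives,
  and what makes a potency-selected evaluation set informative at
  desk scale. Non-engaged cells get potency in [2.5, 4): inactive at
  every tested dose.
- **Profiles.** Per assay, a sparse ±1 signature over 20% of the 100
  features, scaled by a per-assay magnitude (3 ± 30% in noise-SD
  units at saturation). A profile at concentration *c* is
  `Σ_assays effect(pIC50, c) × signature + N(0, 1)` per feature —
  already-normalised Z-scores, so no plate effects are modelled.
- **Observation.** Cells are observed at the 5% base fill rate;
  cells whose latent potency reaches 7 are observed at 3× that rate,
  emulating confirmatory dose-response follow-up of actives (this is
  how sparse pharma activity matrices arise, and at desk scale it
  keeps enough observed high-potency labels to select a test set and
  calibrate the high-threshold baseline). The dense latent matrix is
  returned alongside and used *only* as evaluation truth — emulating
  a fully measured evaluation panel — never for training,
  calibration or selection.
- **Scaffolds.** Integer group labels with rank^(−0.7) sizes over
  1400 scaffolds per 2000 compounds: a few large chemical series and
  a long tail of near-singletons. Scaffolds are assigned
  independently of potency, which keeps random scaffold-disjoint
  splits exchangeable (needed for the conformal-validity checks);
  real scaffolds correlate with activity, so real-data conformal
  validity will be somewhat weaker than the synthetic check shows.

What passing tests on this screen do show: the dose-response
mechanism, the calibration machinery, and the imbalance advantage all
behave as designed when the data-generating assumptions hold. What
they cannot show: performance on real morphological features
(correlated, batch-structured, ~800-dimensional), on potency
distributions unlike the assumed mixture, or under scaffold-activity
correlation.

## Study conditions and problem sizes

Frozen in `concshift.presets`. The default screen is 2000 compounds ×
10 assays × 100 features at concentrations {0.16, 0.8, 4, 10, 20} μM.
Desk training budgets are 4 members × 800 Adam steps with hidden
layers 64/32 (3 × 600 × 48/24 for multi-seed repeats): on this
low-dimensional clean-signal data, larger budgets change runtimes,
not conclusions, and the production-scale configuration (8 members,
34000 iterations, 256/128) remains available through `TrainConfig`.
The rare-tail screen down-weights the upper potency component to
0.12, lowers its mean to 6.8 and removes the follow-up observation
bias, putting fewer than 5% of labelled cells above pIC50 7 —
the regime where the conventional high-threshold model is
positive-starved.

## Numerical choices and degenerate inputs

- p-values: inclusive comparison via binary search on sorted scores;
  empty calibration classes raise at the function level and are
  skipped (with warning) at the pipeline level.
- Probabilities are clipped to [1e−12, 1 − 1e−12] at the ensemble
  output (sigmoid underflow) and inside the loss.
- Masked BCE over zero unmasked cells is defined as 0 with a warning.
- `riptop` rejects baseline 1 (an assay whose test set is all
  positives carries no ranking information).
- Ties in fold allocation and decision boundaries are deterministic:
  equal fold sizes resolve to the lowest fold index, and decision
  boundaries follow the strict/non-strict inequalities given above.
- Everything stochastic is driven by explicit integer seeds through
  numpy `SeedSequence` spawning; identical inputs give bitwise
  identical outputs on one machine.

## Known limitations

- Hill slope is fixed at 1 and IC50 is concentration-independent;
  real dose-response curves vary in slope and can saturate or turn
  toxic at high dose.
- The simulator's additive assay signatures ignore feature
  correlation and nonlinearity of real morphological responses.
- Cross-conformal p-value averaging gives empirical, not exact,
  class-conditional validity; the suite checks it within 3 binomial
  SEs at ε = 0.05.
- "Structurally closest" fold construction is approximated by
  scaffold-grouped greedy balancing; no chemical similarity is
  computed anywhere (scaffold labels are taken as given).
- At desk scale the per-assay test sets are small (tens of
  compounds), so per-assay metrics are noisy; conclusions in the
  tests and the reproduction script rest on medians across assays
  and on multi-seed repeats.
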