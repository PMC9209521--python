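# exporf

Random-forest identification of longitudinal exposome predictors of a
binary health outcome.

Population cohorts increasingly measure dozens of exposures — demographic,
lifestyle, environmental, biological — repeatedly over decades, and ask
which of them predict a later health state. `exporf` implements a
six-stage workflow for that question, built for epidemiologists who want
machine-learning prediction *and* interpretable output:

1. **Trajectory summaries.** Each repeatedly measured exposure is reduced
   per subject to its Area-Under-the-Exposure (AUE), the time-average of
   the piecewise-linear trajectory over observed rounds, and its
   Trend-of-the-Exposure (TOE), the mean slope between consecutive
   observed rounds. Categorical exposures use the proportion of rounds in
   a state (AUE) and a directed transition indicator (TOE, e.g. married →
   widowed/divorced). Both remain defined under missed visits.
2. **Random forest.** An ensemble of CART trees on bootstrap samples; the
   predicted risk is the fraction of trees voting for the outcome class.
3. **Tuning.** Grid search over mtry/ntree/nodesize/maxnodes with
   stratified k-fold cross-validation on an 80/20 stratified split,
   maximizing CV AUC.
4. **Importance.** Permutation variable importance: the mean decrease in
   out-of-bag accuracy (MDA) when a feature's column is permuted, per
   tree, averaged over trees.
5. **How many predictors?** The number of retained top-ranked features q
   is treated as a tuning parameter; a cross-validated AUC-versus-q curve
   is computed and the smallest q within ε of the curve's maximum is
   selected ("flattening" rule, ε = 0.005 by default).
6. **Effect curves.** Partial-dependence (PDP) and accumulated-local-
   effects (ALE) curves, restricted to the 5th–95th percentiles, describe
   how each selected predictor relates to the predicted risk, including
   non-linear (threshold, U-shaped) relations.

Evaluation reports the Mann-Whitney AUC with a DeLong 95% CI, sensitivity
and specificity at the Youden-optimal ROC threshold and at 0.5,
calibration-in-the-large and a decile calibration curve, plus a **domain
ablation** table (test AUC without each exposome domain).

Because real cohorts of this kind are typically not shareable, the package
includes a first-class synthetic-cohort generator
(`default_study_spec`): 3419 subjects, 5 exposure rounds, 96 summary
features from 51 exposures across the four domains, ~16% outcome
prevalence, round-dependent missingness, and 9 planted signals (linear,
threshold and U-shaped effects on true AUE/TOE values) with a ground-truth
ledger, so every pipeline stage can be validated against known structure.

## Worked example

```python
from dataclasses import replace
import exporf
from exporf import RFHyperParams, RunConfig

spec = replace(exporf.default_study_spec(seed=42), n_subjects=800)
cohort, ledger = exporf.generate_cohort(spec)
config = RunConfig(
    cv_folds=3,
    tuning_grid=(RFHyperParams(mtry=9, ntree=100, nodesize=5),
                 RFHyperParams(mtry=19, ntree=100, nodesize=10)),
    q_grid=(2, 4, 6, 9, 12, 24, 96),
    seed=7,
)
results = exporf.run_pipeline(cohort, config=config)
print(results.summary())
```

prints

```
Exposome random-forest pipeline
================================================================
subjects: 800   features: 96   prevalence: 0.146
split: 640 train / 160 test (test fraction 0.2)
tuned parameters: mtry=19 ntree=100 nodesize=10 maxnodes=None
----------------------------------------------------------------
full model   test AUC 0.730 (95% CI 0.608-0.852)
  sens/spec at optimal threshold: 0.522/0.861   mean risk 0.118 vs prevalence 0.144
selected q = 12 (epsilon 0.005)
reduced model test AUC 0.778 (95% CI 0.663-0.893)
----------------------------------------------------------------
top predictors (mean decrease in accuracy):
   1. bmi.AUE                                       +0.0020
   2. chol_ratio.TOE                                +0.0014
   3. crp.AUE                                       +0.0012
   4. loneliness.raw                                +0.0011
   5. marital.TOE.married_to_widowed_divorced       +0.0010
   ...
```

Reading the output: the full 96-feature model separates poor from good
outcomes with a held-out AUC of 0.73; the AUC-versus-q curve flattens at
12 predictors, and the reduced 12-feature model performs comparably. Five
of the planted signals (`bmi.AUE`, `chol_ratio.TOE`, `loneliness.raw`,
`marital.TOE...`, `bmi.TOE`) already head the ranking at this reduced
cohort size — at the full 3419 subjects the planted features fill the top
ranks. `results` also carries the tuning table, the q-curve, PDP/ALE
curves per selected predictor, the calibration bins and the domain-ablation
table; `results.save(out_dir)` writes everything as CSV plus a JSON
manifest with checksums, and `exporf.recovery_report(...)` scores the run
against the ledger.

The same workflow is available from the shell:

```sh
exporf simulate --spec default --seed 3 --out data/
exporf run --cohort data/cohort.csv --outcome data/outcome.csv \
           --schema data/schema.yaml --config config.yaml --seed 7 --out results/
exporf report --manifest results/
```

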