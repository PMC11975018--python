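# mlbpsp

Two-step longitudinal biopsychosocial phenotyping as a tested, reusable
pipeline, together with a synthetic cohort generator so every stage can be
exercised against ground truth.

**Step one** fits each longitudinal feature (square-root transformed, time
coded in 6-month visit units) with a linear mixed model carrying fixed and
random intercept, linear, and quadratic time terms, estimated by maximum
likelihood on all observed rows (no imputation). The empirical-Bayes
predictions of the three subject-level effects become participant features
(3 per longitudinal feature; 51 for the default 17-feature roster).

**Step two** z-scores those features, compresses them with PCA to the
smallest component count explaining ≥ 85% of variance, clusters participants
with k-means (k chosen by the elbow of the within-cluster sum-of-squares
curve over k = 1..9), and orders cluster labels by baseline severity so
label 1 is always the healthiest group.

Downstream modules characterize the phenotypes (ANOVA / Pearson chi-square
with Benjamini–Hochberg-adjusted pairwise contrasts; random-intercept
outcome trajectory models), model baseline predictors of membership
(univariable multinomial logistic screening at p ≤ 0.10, multivariable fit
with iterative backward elimination at p ≤ 0.05, education always forced,
Wald odds-ratio inference), and classify phenotype from baseline scores
alone (4-class random forest and binary healthy-vs-other logistic
regression, both with stratified 10-fold cross-validation).

## CLI

```bash
mlbpsp simulate --out-dir out/ --seed 1 --n 506
mlbpsp fit-trajectories --panel out/panel.csv --out out/
mlbpsp cluster --features out/random_effects.csv --panel out/panel.csv \
    --threshold 0.85 --kmax 9 --seed 1 --out out/
mlbpsp characterize --baseline out/baseline.csv --labels out/labels.csv --out out/tables.tsv
mlbpsp predict --baseline out/baseline.csv --labels out/labels.csv --out out/predictors.tsv
mlbpsp classify --baseline scores.csv --labels out/labels.csv --task binary --out report.json
mlbpsp run --out-dir out/ --seed 1          # whole pipeline on a simulated cohort
```

Panels are long-format CSV (`pid,visit_month,<feature...>`, empty cells =
missing); labels and baseline covariates are CSVs keyed by `pid`; configs
are YAML. Every run writes a `manifest.json` with seeds and content hashes.

## Layout

- `src/mlbpsp/synthetic_cohort.py` — archetype mixture simulator, visit/item missingness, baseline covariates
- `src/mlbpsp/trajectory_features.py` — per-feature mixed models, BLUP extraction
- `src/mlbpsp/phenotype_clustering.py` — PCA, k-means, elbow, label ordering, agreement
- `src/mlbpsp/phenotype_characterization.py` — group comparisons, BH, outcome trajectory models
- `src/mlbpsp/predictor_models.py` — multinomial logistic screening/selection, Wald CIs
- `src/mlbpsp/baseline_classifiers.py` — cross-validated RF and logistic classifiers
- `src/mlbpsp/io_cli.py`, `src/mlbpsp/cli.py` — formats, config, driver, CLI
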