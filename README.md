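# serosig

Serum-biomarker signature discovery for case-control diagnostic studies,
built around the analysis design of a multiplex-ELISA autism (ASD vs TD)
biomarker study: ~1,000 immune/inflammation-related serum proteins measured
in quadruplicate on ~200 children, reduced to a ~10-marker logistic
signature under class-preserving 10-fold cross-validation.

The package is for biostatisticians who want this pipeline as tested,
reusable code — to audit its statistical behavior (leakage, FDR control,
chance-level calibration), to rerun it on new panel data, or to study its
operating characteristics on synthetic cohorts with known ground truth.

## The method

For a subjects × markers concentration matrix `X` (pg/ml, exact zeros =
below detection) with labels `y` (1 = case), each cross-validation fold
trains on ~90% of subjects and is evaluated on the held-out ~10%:

1. **Mostly-zero filter (P1).** Discard marker *m* when
   `#{i in train : X[i,m] = 0} > P1`, with `P1 = floor(p1 · n_train)`
   (default `p1 = 0.25`). The removal count is the fold's F(P1).
2. **Correlation clustering (P2).** Connect markers with squared Spearman
   correlation ρ² ≥ P2 (default 0.5); clusters are the connected components
   (transitive closure); only the member with the highest mean ρ² to the
   rest of its cluster survives. Removals are the fold's F(P2).
3. **Ranking and selection.** Survivors are ranked by the univariate
   regression F statistic `F = (n−2) r² / (1−r²)` (r = Pearson correlation
   of marker with label); the top 1% of the *original* marker count
   (1,000 → 10 features) is selected.
4. **All-in logistic model.** `logit p(x) = β₀ + Σ βₘ zₘ` fit by maximum
   likelihood (IRLS) on Z-transformed training data; held-out subjects are
   Z-scored with training parameters and classified as case when
   `p ≥ 0.5` (boundary inclusive).

Reported per fold: F(P1), F(P2), accuracy, sensitivity, specificity, F1 and
Mann-Whitney AUC; aggregated as mean ± sample sd over the k folds, with a
marker-recurrence table, pooled held-out predictions, a one-sample t-test of
fold accuracies against chance (the majority-class proportion), and
chi-square tests of prediction accuracy against covariates. Cohort-level
statistics (volcano table: pooled-variance t, Benjamini-Hochberg adjusted p,
log2 fold change of group means) and the diagnostic sample-size formula
`n = ⌈z² p(1−p)/e²⌉` per group complete the toolkit.

Because no real serum dataset ships with the package, a synthetic cohort
generator (`serosig.synthetic`) emulates the assay: log-normal baselines,
planted log2-scale group effects, latent-factor correlated marker blocks,
per-marker zero inflation and quadruplicate replicate noise — with the
planted truth returned for recovery checks.

## Worked example

```
$ serosig simulate --out panel.csv --meta meta.csv --truth truth.json --seed 1
wrote 199 x 1000 panel to panel.csv

$ serosig run-cv --panel panel.csv --meta meta.csv --out report.json --seed 1
accuracy 0.99 ± 0.02  sensitivity 1.00 ± 0.00  specificity 0.99 ± 0.03  AUC 1.00 ± 0.00
report written to report.json

$ serosig volcano --panel panel.csv --out volcano.csv
12 of 1000 markers significant at adjusted p <= 0.05 (10 down, 2 up in cases)

$ serosig samplesize --p 0.8 --conf 0.95 --error 0.08
n per group: 97
n total: 194
```

The simulated cohort (102 cases / 97 controls) plants 12 informative
markers; the volcano stage flags exactly those 12 (10 decreased, 2 increased
in cases), and the cross-validated pipeline recovers 11 of them in its
recurrence-≥2 list, 9 selected in all 10 folds. `report.json` holds the
per-fold grid — e.g. fold 1: F(P1)=84, F(P2)=95, accuracy 1.00 — each fold's
fitted logistic equation, and the accuracy-by-gender/site chi-square tests.
The planted effects here are strong (|log2 FC| ≥ 1.5 at noise sd 1), so
near-perfect metrics are the expected outcome, not an optimistic bias; null
cohorts, by contrast, score at chance (see the test suite's calibration
checks).

## Layout

| module | contents |
| --- | --- |
| `serosig.panel` | `MarkerPanel` container, CSV/TSV read/write, validation |
| `serosig.synthetic` | cohort generator, `GroundTruth`, structure verification |
| `serosig.preprocessing` | replicate aggregation, train-fit Z-normalization |
| `serosig.feature_selection` | P1/P2 filters, Spearman clustering, F ranking |
| `serosig.model` | IRLS logistic fit, 0.5-cutoff metrics, ROC/AUC |
| `serosig.cv` | stratified folds, per-fold pipeline, aggregation, reports |
| `serosig.stats` | volcano t/BH/FC, chi-square, one-sample t, sample size |
| `serosig.cli` | `serosig simulate / run-cv / volcano / samplesize` |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
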