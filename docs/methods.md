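# Methods

## The discovery pipeline

The package implements a diagnostic-signature discovery procedure for
high-dimensional serum panels: per cross-validation fold, a mostly-zero
filter, a Spearman correlation-clustering filter, univariate F ranking with
top-fraction selection, and an "all in" multiple logistic regression on
Z-transformed concentrations, evaluated on the held-out fold at a 0.5
probability cutoff. The procedure assumes concentrations are nonnegative
with exact zeros meaning below-detection censoring (zeros are structural,
never missing data), that redundancy among markers is well captured by
monotone association (hence Spearman), and that ~10 retained features on
~180 training subjects keep unpenalized maximum likelihood well posed.

### Filter semantics and tie-breaks

* P1 threshold: `floor(p1_zero_fraction × n_train)`; removal requires a zero
  count **strictly** greater than the threshold. `p1_zero_fraction`
  defaults to 0.25 — the threshold itself is a free parameter of the
  original design (only its downstream removal counts are published), so it
  is exposed in `FilterConfig` and recorded in every report.
* "ρ² ≥ P2" thresholds the **square** of Spearman's rho (so |rho| ≳ 0.707 at
  P2 = 0.5); a flag (`p2_on_rho`) thresholds raw |rho| instead for
  sensitivity analyses. Zero-variance vectors are assigned ρ = 0: no
  monotone association is measurable.
* Clusters are connected components of the threshold graph — transitive
  closure, so chained markers merge even when their direct correlation is
  subthreshold. The representative maximizes the mean ρ² against the other
  members; exact ties (certain for two-member clusters) go to the
  lexicographically smallest marker id. All tie-breaks are lexicographic for
  determinism.
* Selection size is `ceil(top_fraction × original marker count)`, applied to
  the pre-filter count: 1% of a 1,000-marker panel is always 10 features
  regardless of how many survived filtering.

### Ranking split

Feature ranking defaults to the **training** split of each fold
(`ranking_split="train"`). Ranking on the held-out split is implemented
(`ranking_split="test"`) because the original description can be read that
way, but it lets test labels influence model content, so any report produced
under it carries `leakage_flag: true`. The leakage-free default is the
defensible choice and is what all calibration guarantees below refer to.

### Normalization

Z-parameters (per-marker mean, sample sd with n−1) are fit on each fold's
training rows and applied to its test rows; `normalization="global"` fits
once on the whole cohort for comparison with single-pass analyses.
Zero-variance markers map to z = 0 and are excluded from ranking.

### Logistic fit

Newton/IRLS with step halving (the penalized log-likelihood never
decreases), convergence at max |score| < 1e-8, cap 100 iterations. No
penalty by default; an optional ridge term (slopes only) is available for
separable folds. Complete separation is flagged when the coefficient norm
diverges (|β| > 15 on the z scale — odds ratios beyond e^15 per sd have no
finite-sample meaning); coefficients at the cap are still reported, flagged.
The per-fold fitted equation is emitted in the JSON report in readable form.

### Metrics

Confusion counts at the inclusive cutoff (p = 0.5 → case); AUC by the
Mann-Whitney pair formula with ties counted half, which the test suite
verifies equals the trapezoidal area under the threshold-swept ROC. The
headline AUC is the across-fold mean ± sample sd; a pooled-prediction AUC
over all held-out subjects is reported alongside. Chance accuracy is
computed as the majority-class proportion of the analyzed cohort (0.513 for
102/199) and printed with the one-sample t-test of fold accuracies — note
that a fixed reference of 0.52 sometimes quoted for this design is not
exactly the majority-class proportion; the report always states the
definition it used.

## Cohort statistics

Volcano rows use the pooled-variance two-sided Student t (Welch by flag) and
Benjamini-Hochberg step-up adjustment applied jointly across **all** panel
markers. Log2 fold change is `log2((mean_case + ε)/(mean_control + ε))` with
ε = 1e-6 × grand mean, keeping zero-inflated means finite; both-zero means
give FC = 0. The chi-square independence test is Pearson's without
continuity correction (zero-margin levels dropped with a warning). The
sample-size formula `n = ⌈z² p(1−p)/e²⌉` per group computes the normal
quantile rather than hard-coding 1.96, so any confidence level works.

## Synthetic cohorts

`generate_cohort` draws, per subject s and marker m on the log2 scale,

    mu_m + delta_m·[s is case] + lambda_b·Z_{s,b} + eps_{s,m}

with `mu_m ~ N(mu0, tau²)`, block factors Z shared within a block
(`lambda_b = sigma_e·sqrt(rho_b/(1−rho_b))` yields within-block Pearson
correlation rho_b), then exponentiates, zeroes each cell with per-marker
probability pi_m (censoring **after** effect injection — zeros are nuisance,
not signal, unless `group_dependent_zeros` is set), and draws replicates
with multiplicative log-normal noise at the stated CV whose mean is the
reported value.

Defaults, chosen once to emulate the target assay and cohort:

| parameter | default | rationale |
| --- | --- | --- |
| n_case / n_control | 102 / 97 | study cohort arms |
| n_markers, n_replicates | 1000, 4 | assay panel, quadruplicates |
| mu0 (log2 pg/ml), tau | 6, 2 | ~64 pg/ml typical serum cytokine, wide dynamic range |
| sigma_e (log2) | 1 | ~2-fold biological within-group variation |
| replicate_cv | 0.1 | typical technical CV for sandwich ELISA arrays |
| informative markers | 12 = 4 × |Δ|2.0 + 8 × |Δ|1.5; 10 down / 2 up | a recoverable signature with a down-regulation bias |
| zero rates | 0.02 background; 10% of free markers U(0.4, 0.8) | reproduces mostly-zero removal counts near the published 86 ± 3 |
| blocks | ~3.6% of panel in blocks of 4 at rho 0.8 | exercises the clustering filter at ρ² ≈ 0.6 |

Informative markers are placed outside correlated blocks and at the
background zero rate: the generator studies recovery of clean planted
signal; masking by censoring or redundancy can be configured explicitly.

What the generator does **not** emulate: plate/batch effects, site drift
between collection countries, covariate-dependent marker levels, non-log-
normal heavy tails, or assay saturation. Passing recovery tests therefore
show the pipeline is correct and calibrated under its own assumptions — not
that the original cohort's numbers are reproducible (its raw data are not
publicly deposited, so they are explicitly out of reach).

## Calibration evidence (computed by the test suite)

* Null cohorts (no planted effects, 50 simulations at 200 markers): mean
  held-out accuracy within 0.10 of the majority-class proportion and mean
  AUC within 0.10 of 0.5 — the anti-leakage guard.
* 100 null panels of 1,000 markers: mean false-discovery proportion of the
  volcano stage at BH-adjusted p ≤ 0.05 stays ≤ 0.05.
* Label-independent scores on a 102/97 cohort: mean AUC 0.5 ± 0.02 over 500
  simulations.
* Planted signatures (12 markers, |Δ| ≥ 1.5, sigma_e = 1): mean held-out
  AUC ≥ 0.80 and ≥ 8/12 recovered at recurrence ≥ 2, in ≥ 4 of 5 seeds.

Problem sizes in the suite (50–100 simulations, 200-marker null panels,
5 full-scale planted runs) were chosen as the smallest that make these
stochastic bounds statistically comfortable.

## Numerical notes and limitations

* Panel CSV IO writes `%.17g` and parses with round-trip float precision, so
  write→read is bit-exact; zeros are serialized explicitly.
* Fold assignment shuffles within each class and hands each class's
  remainder to the folds with the smallest running totals (random order on
  ties), making per-class *and* overall fold sizes differ by at most one.
* The univariate F uses the label-as-response regression identity
  `F = (n−2)r²/(1−r²)`; a perfectly label-aligned feature gets +inf and
  sorts first.
* Degenerate statistics carry sentinels rather than NaNs: t = 0/p = 1 for
  identical constant groups, p = 0 with a warning for zero-variance
  separation, ρ = 0 for constant vectors.
* Fold-level metrics on 19–20 held-out subjects are coarse (steps of ~0.05);
  sample sds across folds are accordingly large. This mirrors the design
  being modelled rather than a defect of the implementation.
* With strong planted effects the logistic fit frequently separates on
  training data; the separation flag in the report is the intended signal
  that coefficient magnitudes (not predictions) are unreliable in such folds.
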