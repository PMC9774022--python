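# Methods note

This note records the statistical models implemented in `microbiodx`, the
parameter choices and their defaults, the design of the synthetic cohort
generator, numerical decisions, and known limitations.

## 1. Data structures and conventions

- `FeatureTable` stores counts as features × samples (OTUs in rows), with
  optional Silva-style lineage strings. Relative abundances are per-sample
  column normalizations.
- `CohortMetadata` restricts groups to `{HC, IgAN, n_IgAN}` with subtypes
  only on `n_IgAN`, and carries eleven clinical variables (HB, BUN, Scr,
  UA, ALB, T-CHO, TG, HDL, LDL, eGFR, 24hTP) plus age and sex.
- `MetaboliteBatch` stores samples × metabolites intensities with a unique
  injection order and requires at least three QC injections and strictly
  positive intensities.
- Every stochastic routine takes an explicit seed and uses
  `numpy.random.default_rng`; reruns are bit-identical.

## 2. Community analysis

**Alpha diversity.** Bias-corrected Chao1
(S_obs + F1(F1−1)/(2(F2+1))), ACE, Shannon (natural log), and
Gini–Simpson (1 − Σp²), computed via `skbio.diversity.alpha`. Estimators
requiring integer counts are only reported for integer tables.

**UniFrac.** Unweighted and weighted (Lozupone-normalized) UniFrac via
scikit-bio. The test suite validates the wrapper against an independent
brute-force per-branch enumeration of the definitions (1e-12 agreement on
random trees), so the dependency is treated as verified rather than
trusted.

**PCoA.** Classical scaling by eigendecomposition. Negative eigenvalues
(non-Euclidean dissimilarities) are reported as-is; explained-variance
fractions are taken over the positive spectrum only.

**ANOSIM.** Implemented in-package: R = (r̄_between − r̄_within)/(M/2) on
the ranked dissimilarities, with a seeded label-permutation p-value
(count + 1)/(n_perm + 1). The statistic matches scikit-bio to 1e-12 in the
tests; the in-package version exists to guarantee seeded reproducibility
of the permutation null.

**Differential abundance.** Two groups: Wilcoxon rank-sum
(exact null when max(n1, n2) ≤ 25 without ties, asymptotic with tie
correction otherwise); three or more: Kruskal–Wallis. BH FDR throughout.
Constant features get p = 1 with a `degenerate` flag rather than an error.

**LDA effect size.** A LEfSe-style score: features surviving a
Kruskal–Wallis screen (α = 0.05) are scaled to 10⁶ per sample; 30 rounds
of balanced two-thirds subsampling each fit a one-component linear
discriminant, and the effect size is log10(1 + mean discriminant gap),
reported for features with score ≥ 3.0 (the conventional cutoff, settable).

## 3. Diagnostic marker model

The model class is `MicrobiomeDiagnostic`; `.fit(seed)` returns a
`DiagnosticResults`.

1. **Split.** Stratified 2:1, train count = ceil(2/3 × n) per group. This
   ceiling convention reproduces the standard splits, e.g. 150 → 100/50
   and 117 → 78/39.
2. **Screen.** Wilcoxon rank-sum on training relative abundances at
   α = 0.05 (training samples only — the held-out set is never touched
   before final evaluation; a poisoning canary in the test suite enforces
   this).
3. **Ranking.** Mean decrease in impurity averaged over five random-forest
   refits on the training data.
4. **Size selection.** Candidate sizes 1..min(30, n) then a ×1.3 geometric
   ladder; per size, stratified 5-fold cross-validated misclassification
   error (100-tree forests inside CV). The chosen size is the smallest
   whose CV error falls below cutoff = min error + SD at the argmin
   (one-SD rule), favoring compact marker panels.
5. **Final model and POD.** A 500-tree random forest on the chosen
   markers. The POD index of a sample is the fraction of trees voting for
   the disease class — a vote proportion, not the smoothed
   `predict_proba`.
6. **Evaluation.** ROC AUC of POD on train, held-out test, and an
   optional independent cohort. AUC is computed by trapezoid over the ROC
   and checked in tests against the exact Mann–Whitney identity
   U/(n1·n0); percentile bootstrap CIs (2000 resamples) and a
   Mann–Whitney p-value against AUC = 0.5 are attached.

## 4. Metabolomics

**QC-RLSC.** Per metabolite, a robust LOESS curve (degree 1, tricube
weights, span default 0.75, three robustifying iterations; statsmodels
`lowess`) is fit to the QC intensities against injection order; every
injection is divided by the curve value at its order (linear
interpolation, clamped at the first/last QC) and rescaled by the QC
median. Curves dipping to ≤ 0 mark the metabolite uncorrectable; it is
left unchanged and reported, never silently altered. The default span
suits noisy QC series; on noise-free data a finer span tracks the drift
exactly.

**Reproducibility filter.** Metabolites with QC RSD (ddof = 1) ≥ 30% are
removed.

**OPLS-DA.** One predictive component after orthogonal signal correction
(default one orthogonal component): w ∝ X'y; orthogonal weights
w_o = p − (w'p)w with deflation X ← X − t_o p_o'. Default unit-variance
scaling (Pareto and centering available). R2X counts modelled variance of
predictive plus orthogonal components; R2Y the fitted response variance.
Q2 is estimated by seeded 7-fold cross-validation with full refits —
scaling centers, orthogonal filtering, and weights are all re-derived
inside each fold and applied to the left-out rows.

**VIP.** For the single predictive component VIP_j = sqrt(p · w_j² / Σw²),
so mean(VIP²) = 1 exactly; variables with VIP > 1 carry above-average
projection weight.

**Permutation validation.** Class labels are permuted (≥ 20 times;
degenerate permutations that reproduce the original labeling are
excluded), the model refit per permutation, and regression lines fit
through (|label correlation|, R2Y) and (|label correlation|, Q2) including
the unpermuted point at correlation 1. The verdict passes when both
intercepts fall below min(R2Y, Q2) of the unpermuted model. Because
Q2 ≤ R2Y, this requires the permuted-model trend to undercut the
cross-validated Q2 — the criterion that actually separates structure from
overfit: on pure noise the unpermuted R2Y is exchangeable with the
permuted ones, so any test comparing the R2 intercept only against R2Y
would pass noise about half the time.

**Differential metabolites.** The combined call is VIP > 1 and rank-test
p < 0.05 on corrected (unscaled) intensities, reported with fold change,
log2 fold change, BH q-values, and direction; the full table is returned
for volcano-style inspection, with significance as a column rather than a
pre-filtered view.

## 5. Integration

**Spearman correlations.** `scipy.stats.spearmanr` with average ranks; for
n ≤ 9 without ties the two-sided p-value is exact, from the enumerated
permutation distribution of rho (cached per n). Pairs with fewer than 5
complete observations or a constant vector are reported as skipped with a
reason, not dropped silently. BH q-values span all computed pairs.

**Networks.** Edges with p (or q) below threshold and |rho| above an
optional floor form an undirected graph (networkx); isolated nodes are
dropped. An empty network is a legitimate result, not an error.

**Cohort table.** Continuous variables are reported mean ± SD with a
t-test (ANOVA for ≥ 3 groups) when every group passes Shapiro–Wilk
normality at α = 0.05, otherwise median [IQR] with a rank test.
Categorical variables get chi-square, or Fisher's exact test for 2×2
layouts with any expected cell below 5. Percentages are rounded to one
decimal.

## 6. Synthetic cohort generator

The generator is the package's ground-truth instrument; its realism
choices:

- **OTU counts.** Per-feature log-normal mean abundances
  (μ ~ N(0, 1.5²), σ = 0.8) give the heavy-tailed rank-abundance profile
  of stool communities; planted effects multiply disease-group means by
  the effect size (a log-shift); final counts are multinomial draws at a
  fixed depth, so column sums are exactly the nominal sequencing depth
  and sampling zeros arise naturally for rare taxa.
- **Phylogeny.** A random bifurcating tree over the features with
  exponential branch lengths.
- **Clinical phenotypes.** Realistic marginals per variable with additive
  disease-group shifts (e.g. raised Scr and 24hTP, lowered eGFR and ALB in
  IgAN); optional taxon–phenotype links are induced through a Gaussian
  copula calibrated so the target *Spearman* correlation is hit
  (ρ_pearson = 2 sin(π ρ_s / 6)).
- **Metabolome.** Log-normal baselines, multiplicative fold changes on
  planted metabolites, a smooth injection-order drift (linear plus
  sinusoid), mean-corrected log-normal measurement noise (CV 0.10), and a
  QC schedule of three leading injections plus every fifth study
  injection.
- A `CohortTruth` record carries planted identities, effect sizes, and
  links for downstream validation.

## 7. Numerical decisions

- Exact small-sample nulls wherever feasible (Wilcoxon without ties up to
  n = 25, Spearman up to n = 9), asymptotics with tie corrections
  otherwise.
- AUC by trapezoid, tested against the exact pair-counting identity with
  ties (1e-12).
- Permutation p-values use the (count + 1)/(n + 1) estimator, which is
  never zero and exactly calibrated for rank tests.
- PCoA keeps negative eigenvalues visible instead of clipping silently.
- Forest sizes: 500 trees for final models, 100 inside cross-validation
  loops (error-curve shape is stable well below that; the smaller size
  keeps nested CV tractable).
- All randomness flows from explicit integer seeds through
  `default_rng`; nothing reads global RNG state.

## 8. Limitations

- The generator plants multiplicative mean shifts; it does not model
  compositional spurious correlations, batch effects across cohorts, or
  phylogenetically clustered effects, so methods are validated for
  calibration and recovery, not for robustness to those confounders.
- OPLS-DA is limited to two classes and one predictive component (the
  discriminant case); multi-class OPLS and multiple predictive components
  are out of scope.
- LDA effect sizes use a simplified one-stage screen (Kruskal–Wallis only)
  rather than the full class/subclass consistency hierarchy of the
  original LEfSe formulation.
- QC-RLSC assumes drift smooth at the QC sampling scale; drift faster than
  the QC spacing is aliased and cannot be corrected, and metabolites whose
  LOESS curve crosses zero are deliberately left uncorrected.
- The cohort-table normality gate (Shapiro–Wilk at α = 0.05) is a
  convention, not an inference guarantee; with very large groups it tends
  to push variables into the rank-test arm.
- The random-forest pipeline reports ROC on a single stratified split per
  seed; cross-seed variability of the held-out AUC is the intended way to
  assess stability (the acceptance script aggregates 20 seeds).
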