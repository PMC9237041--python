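# Methods

`decanal` implements a variance-centred analysis of fasting glycemia in adult
survey microdata. The guiding idea is *phenotypic decanalization*: under
chronic environmental stress, the physiological buffering that keeps a trait
near its optimum erodes, so affected groups show a **larger phenotypic
variance** — and hence more individuals with extreme values — even when group
means barely move. Mean-regression approaches are structurally blind to this
signal, which motivates each of the components below.

## The analysis chain

1. **Age adjustment.** Glycemia rises with age, so the analysis works with
   residuals `r_i` of the OLS regression of glycemia (mg/dL) on age (years),
   fitted on complete-case rows. Absolute residuals are categorized with
   lower-closed cuts: Normal (`|r| < 40`), Outlier (`40 ≤ |r| < 80`), Extreme
   (`|r| ≥ 80`). Because the categorization is two-sided in the residual, the
   Outlier/Extreme groups capture *variability* around the age expectation,
   not elevated means — exactly the quantity decanalization predicts.

2. **Socioeconomic embedding (optimal-scaling PCA).** The explanatory
   covariates are mostly ordered categories, so classical PCA's interval
   assumption fails. We fit a single-rank PRINCALS-style alternating least
   squares: each variable's categories receive numeric quantifications,
   constrained monotone (weighted isotonic regression, pooled-adjacent-
   violators) for ordinal variables, unrestricted for nominal (sex), and
   fixed at the standardized raw values for numeric variables. Object scores
   `X` (n × p, centered, unit variance per column) minimize

       L(X, q, a) = (1/nm) Σ_j ‖X − t_j a_jᵀ‖²,   t_j = q_j[codes_j],
       q_jᵀ D_j q_j = n,

   with `D_j` the category counts. The object-score update is the orthogonal
   Procrustes optimum, so the loss is non-increasing by construction (a hard
   test assertion). With all variables numeric the fit equals classical PCA
   of the standardized data to 1e−6 (tested against an independent
   eigendecomposition oracle). Loadings are correlations between quantified
   variables and components; variance accounted for per component is the
   mean squared loading. Component signs follow a fixed convention (largest
   |loading| positive), making fits bit-reproducible. Defaults: 8 retained
   components, relative loss tolerance 1e−6, 200 iterations.

3. **Running SD.** For each respondent, the k nearest neighbors (Euclidean,
   in a chosen component subspace — default planes (1,2) and (3,4)) define a
   "socioeconomic neighborhood", and the n−1 sample SD of glycemia within it
   is the local decanalization estimate. k-NN windows rather than
   fixed-radius balls keep each estimate's sampling precision constant
   across dense and sparse regions; default `k = max(50, ⌈0.05 n⌉)`.
   Distance ties break by ascending row index; an exact brute-force search
   implements that rule for n ≤ 2048 (and on request), a k-d tree serves
   larger continuous-score inputs where ties have probability zero. An
   optional two-pass variant subtracts the first-pass running mean before
   computing the SD; it is off by default and both passes are reported when
   on. A local-linear Gaussian-kernel smooth of the SD field over a grid is
   provided for display only.

4. **Inference.**
   * *Gradient test*: Spearman correlation between the running SD and a
     covariate axis. Because running SDs of overlapping neighborhoods are
     strongly autocorrelated, the p-value comes from a permutation null that
     re-assigns glycemia values to positions and recomputes the entire SD
     field over the fixed neighborhoods (sparse membership-matrix
     recomputation; two-sided).
   * *PERMANOVA* on residual categories' positions in the full component
     space: `SS_total = (1/n)Σ_{i<j} d²_ij`, within-group analogue per
     group, pseudo-F referred to unrestricted label permutations. In the
     Euclidean case the score-based centroid identity is used (identical
     result, much faster). Groups with fewer than two members are dropped
     from this stage and recorded in the report.
   * *Dispersion check* (equal multivariate spread, the PERMANOVA
     assumption): ANOVA F on distances to group centroids, permutation p
     with full recomputation under each relabeling. With two-member groups
     both points are equidistant from their centroid, so the within-group
     variance of distances is exactly zero and F is reported as infinite by
     convention; the permutation p remains well defined.
   * *Pairwise comparisons*: PERMANOVA per group pair, Bonferroni
     (`min(1, m·p)`).
   * *G-test of independence* on income×education rows vs residual-category
     columns: `G = 2 Σ_{O>0} O ln(O/E)`, chi-square reference with
     (r−1)(c−1) df, no continuity/Williams correction; zero cells contribute
     0 (the `x ln x → 0` limit). Per-cell contributions `2 O ln(O/E)` sum
     exactly to G and carry the sign of `O − E`; Pearson residuals are also
     provided since the "relative contribution" display in this literature
     is not pinned to one formula. Empty row/column combinations are dropped
     with a log entry before testing.
   All permutation p-values use `(1 + exceedances)/(1 + B)` (default
   B = 999), so they are strictly positive and valid at any B.

5. **Descriptive outputs.** Coefficients of variation (`s/x̄`, n−1 SD) per
   income×education cell (singleton cells keep their n but report a missing
   CV); glycemia levels 1–6 from configurable mg/dL edges (defaults
   70/100/126/160/200 — standard clinical breakpoints for hypoglycemia,
   normal, prediabetic and increasingly severe hyperglycemic ranges — echoed
   into every report); a covariate summary table; and the R² of a plain
   linear model of glycemia on all covariates, reported as the
   mean-modelling baseline the variance analysis is contrasted with.

## Synthetic data: what it emulates, what it does not

The generator draws a one-dimensional latent disadvantage axis
`d ~ N(0, 1)` per respondent and builds:

* ordinal covariates by thresholding `loading·d + noise` at the empirical
  quantiles of configurable marginal level shares (defaults match a
  published national risk-factor survey summary: education 8/34/58%,
  working time 38/22/23/16%, etc.);
* household income as a lognormal with log-location decreasing in `d`
  (defaults give mean ≈ 23,400 and SD ≈ 18,300 currency units);
* continuous covariates (density, utilities, sedentarism, fruit/vegetable
  portions) as rescaled, clipped linear-plus-noise functions of `d`;
* age uniform on (18, 82), independent of `d` by default so age adjustment
  and socioeconomic structure stay separable (a config knob adds
  correlation);
* glycemia = `beta0 + beta1·age + ε`, `ε ~ N(0, σ_i)` with
  `σ_i = σ0 · exp(γ·d_i)`.

`γ` (log-SD per unit disadvantage) is the single decanalization effect
size: `γ = 0` is exactly homoskedastic; the multiplicative form guarantees
positive SDs. Defaults `beta0 = 77`, `beta1 = 0.4` mg/dL/yr, `σ0 = 15`
mg/dL give a realistic adult mean (~97 mg/dL at age 50) and marginal SD
(~20 mg/dL); the default `γ = 0.3` is a moderate effect. Missingness is
completely at random at a configurable per-cell rate (the pipeline only
drops incomplete records, so MCAR suffices). One master seed drives a fixed
SeedSequence spawning order (latent axis, age, sex, one stream per
covariate, glycemia noise, missingness), so identical seeds give bitwise
identical tables and each sub-draw is independently reproducible.

What the generator does **not** emulate: complex-survey design (multi-stage
sampling, weights, household clustering), reporting heaping in income,
treated/diagnosed subpopulations, or any geographic structure. Passing the
recovery tests therefore shows the estimators work when the latent
structure is real and one-dimensional; it does not certify behavior under
informative sampling or multi-axis disadvantage.

## Problem sizes and numerical choices

Recovery and calibration studies use n = 4000 respondents and k = 200
neighborhoods (roughly 5% of n), 200 null replicates at B = 99 permutations
for the gradient-test size, 500 replicates at B = 199 for PERMANOVA size,
and 100 replicates for G-test power — sizes at which the Monte-Carlo bands
are informative while a full study run stays in seconds. Tolerances:
relative loss change 1e−6 (PCA), SS partition identity asserted at 1e−8
relative, G contribution sum at 1e−10. Degenerate inputs are handled
explicitly: constant variables are rejected by the PCA with the variable
named; constant axes are rejected by the gradient test; a zero-variance
subspace triggers a warning (all neighborhoods identical); collinear score
planes downgrade the display smoother to 1-D with a warning.

## Known limitations

* The optimal-scaling fit is the single-rank ordinal variant; no spline
  quantifications, no missing-data optimal scaling, no multiple-nominal
  copies. Numerical equality with other Gifi implementations is not
  promised — normalization conventions differ — only the reductions and
  invariants tested here.
* The running-SD estimator has no adaptive bandwidth; k is a user choice
  reported in all outputs, and the subspace used (2-D planes vs the full
  component space) is configuration, not doctrine.
* The G-test's chi-square reference is asymptotic; with very sparse cells
  it runs slightly conservative in our calibration measurements, and the
  package deliberately drops empty strata rather than smoothing them.
* Survey-weighted estimation is out of scope; results on real survey files
  describe the sample, not the weighted population.
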