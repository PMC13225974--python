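# Methods

This note records the models, numerical choices and limitations behind
the package, in the spirit of a statistical appendix.

## The ImmuScore

Diagnostic flow panels report each antigen as a categorical intensity.
The encoder normalizes labels (case- and whitespace-insensitive;
"positive"/"pos" are synonyms of "part", "neg" of "negative") and maps

| category | score |
|---|---|
| bright | 1.0 |
| part (general positive) | 0.5 |
| dim, partdim | 0.2 |
| negative | 0.0 |

Unknown labels raise an error rather than being scored silently. The
ImmuScore is the sum over CD11b, CD123 and HLA-DR (marker names matched
case-insensitively with punctuation stripped, so "HLA-DR" ≡ "HLADR"),
hence a value in [0, 3]. Patients missing any of the three markers are
left unscored by default — imputing "missing = negative" is available
as an explicit sensitivity flag but conflates assay dropout with
biology.

Dichotomization is at the cohort median with the **inclusive** rule
(score ≥ median → High); a fixed cutoff (default 1.2, the value used in
the discovery analysis) applies the same inclusive convention, since
the median rule is stated inclusively and the fixed cutoff's
inclusivity is otherwise unspecified. Both modes are exposed; neither
is asserted to be "the" canonical rule.

Marker contrasts between CR and R/R use the two-sided Wilcoxon rank-sum
with the **asymptotic** normal approximation, tie correction and
continuity correction (the estimator reported with the marker panels),
with BH adjustment across antibodies. An exact-enumeration mode exists
and is used by the tests to confirm the asymptotic p approximates the
exact permutation p at small n.

## Survival machinery

All fits are Newton–Raphson with step-halving, at most 50 iterations,
convergence when the step's max absolute component falls below 1e-8 or
the relative log-likelihood change below 1e-9; iteration counts and a
convergence flag are always exposed, and a non-converged fit is
returned flagged rather than silently.

* **Kaplan–Meier** groups tied deaths; subjects censored at an event
  time are counted at risk for that time. Greenwood variance is
  carried on the curve.
* **Log-rank** is the k-sample O−E statistic with multivariate
  hypergeometric covariance, χ² with k−1 df.
* **Cox** uses the Efron tie correction by default (the conventional
  default of the R survival ecosystem); Breslow is available by flag.
  Time is in months throughout.
* **Firth Cox** maximizes `l*(β) = l(β) + ½ log det I(β)`. The penalty
  gradient is obtained by central differences of the log-determinant
  (step 1e-5) combined with the exact score; the unpenalized
  information serves as the Newton curvature, whose O(1/n) error does
  not affect the fixed point. This avoids hand-coding third
  derivatives of the Efron likelihood while remaining a Newton
  iteration on the modified score.
* **Firth logistic** uses the standard hat-value-adjusted working
  response `U*(β) = X'(y − π + h(½ − π))`, giving finite estimates
  under complete separation and the closed-form intercept-only solution
  p̂ = (k+½)/(n+1).
* **Confidence intervals** for Firth fits are profile penalized
  likelihood by default (the drop is χ²₁(0.95)/2, roots bracketed
  outward from the estimate and refined by Brent), falling back to Wald
  with a tag when bracketing fails. For univariable Firth-Cox fits the
  p-value is the penalized likelihood-ratio test of β = 0; otherwise
  Wald.
* **Univariable screening** performs one single-variable fit per
  candidate and reports a forest-style table sorted by p. No
  multiplicity adjustment is applied by default, matching how such
  screens are conventionally reported; a BH column is optional. Failed
  variables become annotated rows, never exceptions.

## Evaluation statistics

* **Harrell's C** uses original pair counting: a pair is usable iff its
  order is determined under censoring; tied risks count ½. (Uno's IPCW
  weighting is deliberately not used, matching the era of the C-index
  comparisons this mirrors.)
* **Time-dependent AUC** is the cumulative/dynamic estimator at a fixed
  horizon (default 36 months) with IPCW weights from the Kaplan–Meier
  estimate of the censoring distribution, cases weighted by 1/G(T−) and
  controls by 1/G(t). The AUC is computed as the trapezoid area of its
  own ROC, making the two self-consistent by construction; without
  censoring it reduces exactly to the rank-sum AUC of
  event-by-horizon status.
* **IDI / NRI** operate on predicted event probabilities for subjects
  whose horizon status is determinate. The NRI is the continuous
  (category-free) variant since no risk categories are defined.
  Bootstrap CIs are percentile, 1000 resamples by default, seeded;
  resamples without both outcome classes are redrawn.
* **Decision curves** under censoring estimate TP/n and FP/n from the
  KM event probability at the horizon within the predicted-positive
  stratum; without censoring this equals direct counting.
* **Confusion accuracy** maps High→CR, Low→R/R by default (CR cases
  cluster in the High-score group); the mapping is configurable.
* **Power** is the standard Schoenfeld events formula with n obtained
  from an overall event probability. Its inputs (HR, α, power,
  allocation, event probability) are required arguments — no defaults
  are asserted for the unpublished assumptions of any particular
  power analysis.

## Expression analysis

TPM matrices are transformed once as log2(TPM+1); the transform flag
prevents double application. The moderated t follows the
empirical-Bayes variance-shrinkage approach: per-gene residual
variances are shrunk toward s₀² with prior df d₀ estimated by moment
matching on log sample variances (trigamma inversion by Newton;
variances are floored at 1e-5 × median before hyperparameter fitting;
when the log-variance spread is no larger than expected under a common
variance, d₀ = ∞ and s₀² is the mean variance). The total df is capped
at the pooled residual df. The implementation reproduces R limma's
`lmFit`+`eBayes` t and p values on shared fixtures to ≤ 1e-4 / 1e-6,
and limma serves as an independent oracle in the test suite. DE calls
are strict: |log2FC| > 1 **and** adjusted p < 0.05.

The LASSO-Cox path is fitted by the coordinate-descent elastic-net
solver of scikit-survival (l1_ratio = 1) on internally standardized
predictors, coefficients reported on the original scale. The λ grid is
log-spaced downward from λ_max (100 points, ratio 0.01) unless
supplied. Cross-validation uses event-stratified, seeded fold
assignment (so no fold is event-free) and the Verweij–van Houwelingen
partial-likelihood deviance `−2[l_all(β̂_(−k)) − l_train(β̂_(−k))]`
with Breslow ties; λ_min minimizes the mean CV deviance with ties
broken toward the larger penalty. The risk score is the linear
functional of transformed expression over the non-zero genes,
median-split with the same inclusive convention as the ImmuScore; an
all-zero model yields a flagged degenerate split rather than an error.

The 2^(−ΔΔCt) helper is plain arithmetic on Ct means:
ΔΔCt = (Ct_target − Ct_ref)_case − (Ct_target − Ct_ref)_control.

## Drug sensitivity

Responses are opaque reals (the assay may report AUC or IC50);
orientation is fixed by convention: higher Z = reduced sensitivity.
Standardization is per compound with sample SD (n−1), pairwise
deletion of missing values, never imputation; constant or <2-
observation compounds are dropped with a warning. Group contrasts are
the same asymptotic Wilcoxon as for markers, BH-adjusted across
compounds (raw-p mode by flag), with significance stars at
0.05/0.01/0.001/0.0001 and a direction flag naming the more-sensitive
(lower-median-Z) group.

## Synthetic cohort generator

The generator defines the study conditions for every simulation-based
test; its defaults are fixed once:

| parameter | default | rationale |
|---|---|---|
| frac_rr | 0.4 | R/R fraction of a mixed treated cohort |
| marker probs (CR) | [.15,.15,.10,.40,.20] over negative…bright | mostly positive phenotype |
| marker probs (R/R) | [.40,.25,.15,.15,.05] | the R/R downshift of all three markers |
| hr_high_vs_low | 0.38 | the reported High-vs-Low hazard ratio |
| baseline_hazard | 1/24 per month | median OS ≈ 17 months in the Low group |
| censor_rate, admin_cutoff | 0.01 /mo, 60 mo | ≈25–35% censoring, 5-year follow-up |
| n_drugs, drug_shift | 20, +0.8 Z in Low | clearly resolvable resistance shift |
| n_genes, n_prognostic | 200, 2 | a MAP3K15-like gene (up in R/R) plus a second, down-shifted one |
| prognostic_log2fc | 2.0 | comfortably beyond the |log2FC| > 1 threshold |
| expression_dispersion | 1.0 | log2-scale biological spread |

Survival is exponential with the hazard multiplied by `hr_high_vs_low`
for patients whose **realized** ImmuScore is at/above the cohort
median — tying truth to the quantity the pipeline estimates makes the
true log-HR exactly recoverable (the parameter-recovery test finds the
mean estimate within 10% of log 0.4 at n = 500). Censoring is the
minimum of an independent exponential and the administrative cutoff.
One root seed drives fixed per-table sub-streams, so adding a table
never shifts another and regeneration is byte-identical.

What the generator does **not** emulate: co-mutation structure,
cytogenetics, batch effects, dose–response curve shapes, and any direct
gene→hazard link (prognostic genes associate with survival only through
the response→score→hazard chain; the LASSO recovery simulations that
need a known per-gene log-HR construct survival directly from a Cox
model instead). Passing tests therefore demonstrate statistical
correctness of the machinery under the assumed structure, not fidelity
to any real cohort.

## Problem sizes and reproducibility

Simulation-based checks use 200 replicates at n = 500 for parameter
recovery, 1000 replicates at n = 200 for type-I error (per-drug
Wilcoxon calibration pooled over 250 of them), and 20 seeded runs for
LASSO selection recovery — sizes at which the Monte-Carlo error is
well inside the asserted bands while the whole suite stays
interactive. All randomness flows from explicit seeds: generator
sub-streams, CV folds, bootstraps. The pipeline writes outputs under a
directory keyed by a hash of the semantically meaningful configuration
fields and produces byte-identical files on re-execution.

## Known limitations

* The Firth-Cox penalty gradient is finite-difference; for tens of
  covariates an analytic trace expression would be faster, but
  screening here is univariable or low-dimensional.
* Profile CIs assume a unimodal penalized likelihood; pathological
  shapes trigger the Wald fallback (tagged on the fit).
* No time-varying covariates, stratified Cox, competing risks or
  proportional-hazards diagnostics.
* The five-marker score variant (adding CD58/CD71) is not implemented;
  the three-marker score plus a configurable marker list covers the
  intended use.
* Cohort-level published figures (AUC ≈ 0.72/0.75, accuracy 67.65%/
  93.88%, HR 0.38) depend on cohorts this package does not ship; they
  parameterize the generator defaults and are not reproduction targets.
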