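# immuscore

Immunophenotype-based risk stratification for *ASXL1*-mutated acute
myeloid leukemia (AML).

*ASXL1* mutation is classified as an adverse-risk lesion, but outcomes
within the mutated group are heterogeneous: patients reaching complete
remission (CR) behave very differently from relapsed/refractory (R/R)
patients despite an identical driver lesion. Routinely reported flow
cytometry markers — CD11b, CD123 and HLA-DR — are systematically lower
in R/R patients, and a composite of their intensities separates the two
trajectories. This package implements that workflow as a tested,
reusable library for biostatisticians and translational hematologists:

* **ImmuScore** — categorical marker intensities are encoded
  semi-quantitatively (bright = 1.0, part = 0.5, dim/partdim = 0.2,
  negative = 0) and summed over the three markers, giving a score in
  [0, 3]. Patients with score ≥ the cohort median (or a fixed 1.2
  cutoff) form the High-score (favourable) group.
* **Small-sample survival machinery** — Kaplan–Meier, log-rank, Cox
  proportional hazards (Efron ties), and Firth-penalized Cox/logistic
  regression maximizing `l*(β) = l(β) + ½ log det I(β)`, which stays
  finite under the monotone-likelihood/separation problems typical of
  ~50-patient mutation subsets.
* **Model evaluation** — Harrell's C, IPCW cumulative/dynamic AUC(t),
  IDI and continuous NRI with seeded bootstrap CIs, decision-curve net
  benefit `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)`, confusion accuracy,
  and the Schoenfeld events formula
  `d = (z_{1−α/2}+z_{1−β})² / (p(1−p)(log HR)²)`.
* **Gene signature** — log2(TPM+1) transform, empirical-Bayes moderated
  t (variances shrunk toward s₀² with prior df d₀), strict
  |log2FC| > 1 & adjusted p < 0.05 filtering, LASSO-Cox with 10-fold
  cross-validated λ_min, and a median-split linear risk score; plus the
  comparative 2^(−ΔΔCt) qPCR quantity.
* **Drug sensitivity** — per-compound Z-score normalization (higher Z =
  reduced sensitivity) and Wilcoxon rank-sum contrasts with BH
  adjustment.
* **Synthetic cohorts** — a seeded generator reproducing the assumed
  data structure (marker downshift in R/R, exponential survival with a
  configurable High-vs-Low hazard ratio, shifted drug responses,
  prognostic genes), so the full pipeline runs without external data.

## Worked example

```python
import immuscore as im

cohort = im.generate_cohort(im.SimulationConfig(seed=7, n_patients=200))
matrix = im.build_matrix(cohort.marker_calls)
groups = im.stratify(im.compute_immuscore(matrix))["group"]

df = cohort.survival.join(groups)
df["high_score"] = (df["group"] == "High").astype(float)
lr = im.logrank_test(df["time_months"], df["event"], df["group"])
fit = im.cox_fit(df, ["high_score"])
print(f"log-rank p = {lr.p_value:.2e}")
print(f"HR High vs Low = {fit.hr[0]:.2f} "
      f"(95% CI {fit.ci_low[0]:.2f}-{fit.ci_high[0]:.2f})")
```

prints

```
log-rank p = 5.06e-09
HR High vs Low = 0.35 (95% CI 0.24-0.51)
```

i.e. on this simulated 200-patient cohort (generated with a true
High-vs-Low hazard ratio of 0.38) High-score patients have roughly a
third of the death hazard of Low-score patients, and the Kaplan–Meier
curves separate far beyond chance. The `examples/` directory contains
one short script per capability (simulation, scoring, survival
screening, model evaluation, gene signature, drug contrasts, full
pipeline); each prints its numbers with a line on what they mean.

A thin CLI wraps the same functions:

```bash
immuscore simulate --seed 7 --n 200 --out demo/
immuscore score --markers demo/markers.tsv --rule median
immuscore run --config pipeline.yaml
```

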