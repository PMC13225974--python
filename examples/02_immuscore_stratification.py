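"""Encode marker intensities, compute the ImmuScore and stratify.

Each of CD11b, CD123 and HLA-DR is encoded 0 / 0.2 / 0.5 / 1.0
(negative / dim or partdim / part / bright); the ImmuScore is their sum,
and patients at or above the cohort median (or a fixed 1.2 cutoff) form
the High-score group, which carries the favourable phenotype.
"""

from immuscore import (
    SimulationConfig,
    StratificationRule,
    build_matrix,
    compare_markers,
    compute_immuscore,
    generate_cohort,
    stratify,
)

cohort = generate_cohort(SimulationConfig(seed=7, n_patients=200))
matrix = build_matrix(cohort.marker_calls)
scores = compute_immuscore(matrix)

median_rule = stratify(scores)  # cohort-median rule (inclusive >=)
fixed_rule = stratify(scores, StratificationRule("fixed_cutoff", cutoff=1.2))

print("cohort median threshold:", median_rule["threshold"].iloc[0])
print("median rule groups:", median_rule["group"].value_counts().to_dict())
print("fixed 1.2 cutoff groups:", fixed_rule["group"].value_counts().to_dict())

tests = compare_markers(matrix, cohort.survival["response"])
print("\nper-marker CR vs R/R Wilcoxon (BH-adjusted):")
print(tests[["median_CR", "median_RR", "W", "p_adj"]].round(4).to_string())
print("\nlower R/R medians with small adjusted p reproduce the marker")
print("downshift that motivates the score.")
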