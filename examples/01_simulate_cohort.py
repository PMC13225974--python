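"""Generate a synthetic AML cohort and inspect its structure.

The generator emulates the data layers of a flow-annotated AML cohort:
categorical marker intensities (lower categories enriched in R/R
patients), right-censored survival driven by the realized ImmuScore
group, per-compound drug-response Z-scores, and a TPM expression matrix
with response-associated prognostic genes.
"""

from immuscore import SimulationConfig, generate_cohort, write_cohort

config = SimulationConfig(seed=7, n_patients=200)
cohort = generate_cohort(config)

print("marker calls:", cohort.marker_calls.shape[0], "rows")
print(cohort.marker_calls.head(3).to_string(index=False))
print("\nsurvival (first rows):")
print(cohort.survival.head(3).to_string())
print("\nevent rate:", cohort.survival["event"].mean().round(3),
      "- fraction of patients with an observed death")
print("R/R fraction:", (cohort.survival['response'] == 'RR').mean().round(3))
print("true High-vs-Low hazard ratio:", config.hr_high_vs_low)
print("prognostic genes:", cohort.truth["prognostic_genes"])

paths = write_cohort(cohort, "scratch/example_cohort")
print("\nwrote:", ", ".join(sorted(p.name for p in paths.values())))
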