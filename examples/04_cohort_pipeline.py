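"""End-to-end cohort analysis: simulate -> QC -> fit -> metrics -> statistics.

Simulates a control + MCD-diet cohort (5 replicates per condition, the
study's measurement count), runs the full pipeline, and prints the fitted
group means and the omnibus p-value for each metric.
"""

import logging

from afspect import CohortScenario, RunConfig, make_cohort, run_pipeline

logging.basicConfig(level=logging.ERROR)

scenario = CohortScenario(replicate_count=5, seed=11)
spectra, truth = make_cohort(scenario)
bundle = run_pipeline(spectra, RunConfig(n_starts=3, seed=0))

print(f"fitted {len(bundle.fits)} spectra "
      f"({len(bundle.discarded)} discarded by hemoglobin QC), "
      f"mean r2 = {bundle.fits['r2'].mean():.4f}\n")

cols = ["contribution_lipopigments", "contribution_flavins",
        "contribution_proteins", "contribution_vitamin_a"]
means = bundle.fits.groupby("condition")[cols].mean()
means.columns = [c.replace("contribution_", "") for c in cols]
print("fitted mean contribution (%) per condition:")
print(means.round(2).to_string())

print("\nomnibus p per metric (routed ANOVA / Kruskal-Wallis):")
print(bundle.comparisons.groupby("metric")["omnibus_p"].first().round(4)
      .to_string())

print("\nThe lipopigment and vitamin A trends survive the per-spectrum fit")
print("noise; the heavily overlapping NAD(P)H bands do not separate")
print("reliably in single noisy spectra, so their group effects wash out")
print("(their per-sample shares carry the unmixing noise floor).")
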