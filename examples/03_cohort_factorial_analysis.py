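"""Pathology x severity cohort analysis.

Draws a simulated cohort (two pathologies, three severity levels, ten
subjects per cell) from the default effect model, prints the per-cell
mean +- SE table for all four parameters and the two-way ANOVA for SM
and PSM.
"""

import warnings

from discsig import (
    EffectModel,
    cohort_report,
    report_markdown,
    sample_metric_cohort,
    two_way_anova,
)

model = EffectModel(n_per_cell=10, rng_seed=1)
cohort = sample_metric_cohort(model)
print(f"cohort: {len(cohort)} discs, "
      f"{cohort['pathology'].nunique()} pathologies x "
      f"{cohort['severity'].nunique()} severity levels\n")

print(report_markdown(cohort_report(cohort)))
print()

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for response in ("SM", "PSM_mm"):
        res = two_way_anova(cohort, response)
        print(f"two-way ANOVA on {response}:")
        print(res.table.round(4).to_string(), "\n")

print("Scoliotic nuclei are longer and brighter in this model, so the")
print("pathology effect dominates SM, while PSM responds to both the")
print("pathology and its severity (the nucleus shortens as degeneration")
print("advances) — DX carries no injected effect and stays quiet.")
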