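"""Calibrate OR-rule threshold panels and tabulate pooled performance.

Thresholds for IGFBP2 (up-regulated), LCAT and SHBG (down-regulated) are
placed at the empirical 5% false-positive control quantiles; CA125 keeps
its fixed 35 U/ml referral cutoff.  Panels call a sample positive when ANY
rule fires, and each panel is compared against CA125 alone with McNemar's
test on the paired detection calls.
"""

from ocpanel import CohortDesign, performance_table, simulate_cohort
from ocpanel.config import PipelineConfig
from ocpanel.pipeline import build_panels

cohort = simulate_cohort(CohortDesign(seed=1))
panels = build_panels(cohort, PipelineConfig(simulate=True, alpha=0.05))

print("calibrated thresholds:")
for rule in next(p for p in panels if p.name == "IGFBP2:LCAT:CA125").rules:
    print(f"  {rule.marker} {'>' if rule.direction == 'above' else '<'} "
          f"{rule.threshold:.3g}  ({rule.provenance})")

rows = performance_table(cohort, panels, reference_panel="CA125")
print("\npanel                     sens   spec   McNemar p vs CA125  (pan, pooled)")
for r in rows:
    if r.stratum == "pan":
        p = r.mcnemar_vs_ref.p_value if r.mcnemar_vs_ref else float("nan")
        print(f"{r.panel:<25} {r.sensitivity:.3f}  {r.specificity:.3f}  {p:.2g}")
# Sensitivity is per serum sample pooled over all time points ("triage",
# no temporal information); specificity is pooled over control samples.
# OR-combination trades a small specificity loss for higher sensitivity.
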