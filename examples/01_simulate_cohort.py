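"""Simulate a synthetic nested case-control serial-sample cohort.

Builds the default study design (49 ovarian-cancer cases: 30 Type II and
19 Type I of which 10 borderline; 31 matched controls; serial serum samples
up to 84 months before diagnosis), writes it as a cohort CSV and prints the
realized composition.
"""

from ocpanel import CohortDesign, simulate_cohort, write_cohort

design = CohortDesign(seed=1)
cohort = simulate_cohort(design)
write_cohort(cohort, "cohort.csv")

cases = cohort.cases()
print(f"subjects: {len(cohort.subjects)} "
      f"({len(cases)} cases / {len(cohort.controls())} controls)")
print(f"subtypes: {sum(s.subtype.value == 'type2' for s in cases)} Type II, "
      f"{sum(s.subtype.value == 'type1' for s in cases)} Type I "
      f"({sum(s.raw_subtype == 'borderline' for s in cases)} borderline)")
print(f"serial samples: {len(cohort.samples)}")
tdx = [s.tdx_days for s in cohort.samples]
print(f"tDx range: {min(tdx):.0f} to {max(tdx):.0f} days before diagnosis")
# The counts mirror the emulated screening-trial collection; marker levels
# are log-normal with case trajectories drifting from marker-specific
# change-points toward diagnosis.
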