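"""Generate a small synthetic mother-calf herd and inspect its design.

The generator reproduces the study design (weekly weighing from birth to
weaning at day 143, births centred in late May) at a reduced size, and
draws calf weights from the growth model's own mixed structure.
"""

import deerheat as dh

design = dh.HerdDesign(n_pairs=50, n_cohorts=5, n_mothers=30)
weather, records, manifest = dh.simulate_study(design, seed=42)

per_calf = records.groupby("calf_id").size()
print(f"{len(records)} weighings of {records['calf_id'].nunique()} calves")
print(f"weighings per calf: mean {per_calf.mean():.1f}, range {per_calf.min()}-{per_calf.max()}")
print(f"birth weights (t=0): mean {records.loc[records.calf_age_d == 0, 'calf_wt_kg'].mean():.1f} kg")
print(f"weights near weaning (t>130): mean "
      f"{records.loc[records.calf_age_d > 130, 'calf_wt_kg'].mean():.1f} kg")
print("\ntrue variance components used:", manifest["true_params"]["sigma_groups"])
# Calves start near 9 kg and approach their asymptote by weaning; the
# spread between calves reflects the cohort/mother/calf intercept sds.
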