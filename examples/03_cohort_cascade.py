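"""Subject exclusion cascade and pubertal grouping.

Generates a screening roster with the default subject-flow structure
(1330 screened), applies the ordered exclusion cascade, and groups the
survivors by Tanner stage.
"""

import adrenadc as ad

roster = ad.generate_cohort_roster(ad.RosterSpec(rng_seed=7))
eligible, audit = ad.apply_exclusion_cascade(roster)

print(f"screened:                    {audit.n_input}")
print(f"abnormal radiology removed:  {audit.n_abnormal_imaging}")
print(f"  -> remaining:              {audit.n_input - audit.n_abnormal_imaging}")
print(f"clinical exclusions removed: {audit.n_clinical}  {audit.clinical_breakdown}")
print(f"missing radiologic data:     {audit.n_missing_radiologic}")
print(f"eligible study sample:       {audit.n_eligible}")

groups = [ad.assign_group(r) for r in eligible]
print(f"prepubertal (Tanner 1):      {groups.count('PreP')}")
print(f"postpubertal (Tanner 2-5 / adult): {groups.count('PostP')}")
# Each subject is counted once, at the first cascade stage that removes
# it, so the stage counts always sum back to the roster size.
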