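"""Generate a synthetic severe-trauma cohort and summarise it.

The generator's defaults are calibrated so that large cohorts reproduce
the marginals of a single-centre severe-trauma registry population:
mortality ~26.8%, pneumonia ~19.0%, sepsis ~14.9%, all complications
~24.7%, death from hemorrhagic shock ~4.1%, death from MOF ~1.9%, mean
ISS ~28.2 and mean age ~45.8 years.
"""

from traumastrat import default_params, generate_cohort, summarize_cohort, write_cohort

cohort = generate_cohort(default_params(n_patients=20_000, seed=1))
s = summarize_cohort(cohort)

print(f"patients: {s.n}")
print(f"age {s.mean_age:.1f} +/- {s.sd_age:.1f} y   ISS {s.mean_iss:.1f} +/- {s.sd_iss:.1f}   NISS {s.mean_niss:.1f}")
print(f"mortality          {100 * s.mortality:5.1f} %   (death <=72 h {100 * s.death_within_72h:.1f} %)")
print(f"pneumonia          {100 * s.pneumonia:5.1f} %")
print(f"sepsis             {100 * s.sepsis:5.1f} %")
print(f"all complications  {100 * s.all_complications:5.1f} %")
print(f"death, hem. shock  {100 * s.death_causes['exsanguination']:5.1f} %")
print(f"death, MOF         {100 * s.death_causes['MOF']:5.1f} %")

write_cohort(cohort[:100], "example_cohort.csv")
print("wrote the first 100 patients to example_cohort.csv")
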