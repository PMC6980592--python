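"""Stratify a cohort by all four shipped grading systems.

Each score reads a different slice of the admission data, so coverage
(the share of patients with complete data for that score) differs: the
acid-base-only EAC covers the most patients, the multi-parameter grading
systems around 60%.  Patients missing a required value are reported as
not stratifiable and excluded from all downstream statistics.
"""

from collections import Counter

from traumastrat import (
    default_params,
    generate_cohort,
    load_default_definition,
    stratify,
    stratify_cohort,
)

cohort = generate_cohort(default_params(n_patients=10_000, seed=3))

for name in ("cgs", "mcgs", "ptgs", "eac"):
    definition = load_default_definition(name)
    results, coverage = stratify_cohort(cohort, definition)
    dist = Counter(r.stratum for r in results if r.stratified)
    shares = "  ".join(f"{s}: {100 * dist[s] / sum(dist.values()):.1f}%" for s in definition.strata)
    print(f"{definition.name:5s} coverage {100 * coverage:5.1f}%   {shares}")

# a single patient's stratification, with the criteria that drove it
definition = load_default_definition("eac")
patient = next(p for p in cohort if p.physiology.lactate and p.physiology.lactate >= 4.0)
result = stratify(patient, definition)
print(f"\npatient {result.patient_id}: {result.score_name} -> {result.stratum}")
print("triggered by:", ", ".join(f"{param} = {value}" for param, value in result.triggered))
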