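import numpy as np
import pytest

from traumastrat import (
    InjuryScores,
    OutcomeRecord,
    PatientRecord,
    PhysiologySnapshot,
    default_params,
    generate_cohort,
    load_default_definition,
)

#: Published mCGS (rows) x CGS (columns) cross-tabulation of 2155 jointly
#: stratified patients used as a fixed reference input for the agreement
#: analyses (strata ordered stable, borderline, unstable, in_extremis).
REFERENCE_CROSSTAB = np.array(
    [
        [757, 193, 9, 1],
        [0, 726, 107, 1],
        [0, 0, 331, 12],
        [0, 0, 0, 18],
    ]
)
CGS_STRATA = ["stable", "borderline", "unstable", "in_extremis"]


def make_patient(patient_id="p1", outcome=None, injury=None, **physiology):
    """A patient with unremarkable physiology, overridable per field."""
    base = dict(
        systolic_bp=120.0,
        lactate=1.0,
        ph=7.40,
        base_excess=0.0,
        platelet_count=250.0,
        fibrinogen=3.0,
        prothrombin_ratio=100.0,
        inr=1.0,
        prbc_2h=0,
        prbc_24h=0,
        temperature_core=36.8,
        chest_ais=0,
        abdomen_moore_grade=0,
        extremity_soft_tissue_ais=0,
        gcs=15,
    )
    base.update(physiology)
    record = PatientRecord(
        patient_id=patient_id,
        physiology=PhysiologySnapshot(**base),
        injury=injury or InjuryScores(iss=20, niss=25, age_years=40.0),
        outcome=outcome or OutcomeRecord(),
    )
    record.validate()
    return record


@pytest.fixture(scope="session")
def definitions():
    return {name: load_default_definition(name) for name in ("cgs", "mcgs", "ptgs", "eac")}


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-size default cohort shared across tests (fixed seed)."""
    return generate_cohort(default_params(n_patients=3000, seed=5))


@pytest.fixture
def reference_crosstab():
    return REFERENCE_CROSSTAB.copy()
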