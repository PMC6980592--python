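"""Synthetic severe-trauma cohort generator.

The generator emulates the statistical structure a registry-validation
pipeline needs, calibrated so that large default cohorts reproduce the
published marginals of a severe-trauma population (mean ISS 28.2 +/- 15.1
truncated to [16, 75], mean age 45.8, mortality 26.8%, pneumonia 19.0%,
sepsis 14.9%, all complications 24.7%, death from hemorrhagic shock 4.1%,
death from MOF 1.9%).

Generative chain per patient::

    latent anatomical severity  S ~ Gamma(shape, scale)
        -> ISS (16 + S, truncated at 75), NISS = ISS + extra (NISS >= ISS)
        -> soft-tissue / coagulation / hemorrhage derangements
           D_i = loading_i * S_std + noise            (unit variance)
    acid-base derangement D_ab = rho * (hemorrhage noise) + noise

so the acid-base axis is correlated with hemorrhage (acute shock) but, by
construction, independent of anatomical severity and of the soft-tissue
and coagulation axes: acid-base derangement models a transient shock
response that carries no information about the slow, tissue-driven
inflammatory pathways.  Measured physiology is monotone in its system's
derangement (lactate up / base excess down with D_ab, platelets and
fibrinogen down with D_coag, blood pressure down and transfusion counts up
with D_hem, AIS grades up with D_soft).  Early death (within 72 h) is
logistic in (hemorrhage, acid-base); pneumonia, sepsis and MOF death are
logistic in (soft-tissue, coagulation, severity).  Death causes follow the
dominant derangement.  Missingness is applied last, independently per
field (missing completely at random).  A fixed seed gives a bit-identical
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import PatientRecord

__all__ = [
    "SimulationParams",
    "CohortSummary",
    "default_params",
    "generate_cohort",
    "generate_frame",
    "summarize_cohort",
    "summarize_frame",
]


@dataclass
class SimulationParams:
    """Complete generator configuration; ``default_params()`` is calibrated."""

    n_patients: int = 1000
    seed: int = 0

    # latent severity -> injury scores
    severity_shape: float = 0.5
    severity_scale: float = 25.9251  # calibrated: truncated mean ISS 28.2, sd 15.2
    niss_extra_shape: float = 1.25
    niss_extra_scale: float = 7.2
    age_mean: float = 32.7214  # calibrated: truncated (>=16) mean 45.8, sd 20.2
    age_sd: float = 28.2451

    # per-system link strength from latent severity (unit-variance result)
    system_loadings: dict = field(
        default_factory=lambda: {
            "soft_tissue": 0.75,
            "coagulation": 0.65,
            "hemorrhage": 0.45,
            "acid_base": 0.0,  # acid-base carries no anatomical-severity signal
            "tbi": 0.50,
        }
    )
    #: correlation of the acid-base axis with the hemorrhage noise component
    shock_coupling: float = 0.55

    # measurement noise (standard deviations on the scale of each map)
    noise_sd: dict = field(
        default_factory=lambda: {
            "lactate": 0.22,
            "ph": 0.020,
            "base_excess": 1.3,
            "systolic_bp": 12.0,
            "platelet_count": 0.18,
            "fibrinogen": 0.20,
            "prothrombin_ratio": 8.0,
            "inr": 0.08,
            "temperature_core": 0.45,
            "chest_ais": 0.8,
            "abdomen_moore_grade": 0.8,
            "extremity_soft_tissue_ais": 0.8,
            "gcs": 2.2,
        }
    )

    # logistic links from derangements to outcomes (slopes)
    outcome_links: dict = field(
        default_factory=lambda: {
            "early_death": {"acid_base": 0.85, "hemorrhage": 1.30},
            "exsanguination": {"hemorrhage": 1.3, "tbi": -0.8},
            "early_tbi": {"tbi": 1.2},
            "mof_death": {"soft_tissue": 0.9, "coagulation": 0.8, "severity": 0.3, "sepsis": 1.2},
            "late_death": {"tbi": 0.9, "severity": 0.3},
            "late_tbi": {"tbi": 1.0},
            "pneumonia": {"soft_tissue": 0.75, "coagulation": 0.45, "severity": 0.25},
            "sepsis": {"soft_tissue": 0.70, "coagulation": 0.50, "severity": 0.25},
            "bacteraemia": {"soft_tissue": 0.4, "sepsis": 1.7},
            "infection": {"soft_tissue": 0.5},
            "ards": {"soft_tissue": 0.6, "severity": 0.3},
            "mof_morbidity": {"soft_tissue": 0.8, "coagulation": 0.6},
        }
    )

    # per-outcome baseline log-odds (calibrated against the target marginals)
    calibration_intercepts: dict = field(
        default_factory=lambda: {
            "early_death": -2.3173,
            "exsanguination": -2.6845,
            "early_tbi": 0.60,
            "mof_death": -5.8451,
            "late_death": -2.6186,
            "late_tbi": 0.50,
            "pneumonia": -1.7416,
            "sepsis": -2.6972,
            "sepsis_pneumonia_coupling": 1.6419,
            "bacteraemia": -3.0988,
            "infection": -0.8837,
            "ards": -2.4768,
            "mof_morbidity": -3.60,
            "septic_shock_given_sepsis": 0.215,  # plain conditional probability
        }
    )

    # per-field probability of being missing (missing completely at random)
    missingness: dict = field(
        default_factory=lambda: {
            "lactate": 0.0622,
            "ph": 0.0622,
            "base_excess": 0.0622,
            "systolic_bp": 0.02,
            "prbc_2h": 0.01,
            "prbc_24h": 0.115,
            "platelet_count": 0.02,
            "fibrinogen": 0.035,
            "prothrombin_ratio": 0.035,
            "inr": 0.31,
            "temperature_core": 0.08,
            "chest_ais": 0.03,
            "abdomen_moore_grade": 0.03,
            "extremity_soft_tissue_ais": 0.03,
            "gcs": 0.01,
        }
    )

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in ("severity_shape", "severity_scale", "age_sd", "niss_extra_shape", "niss_extra_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for fld, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness[{fld!r}] must be in [0, 1], got {p}")
        if not -1.0 < self.shock_coupling < 1.0:
            raise ValueError("shock_coupling must be in (-1, 1)")
        for sys_name, lam in self.system_loadings.items():
            if not -1.0 <= lam <= 1.0:
                raise ValueError(f"system_loadings[{sys_name!r}] must be in [-1, 1]")


def default_params(n_patients: int = 1000, seed: int = 0) -> SimulationParams:
    """The shipped calibration (see module docstring for the targets)."""
    return SimulationParams(n_patients=n_patients, seed=seed)


# ---------------------------------------------------------------------------
# generation


def _lin(n, link: dict, latents: dict, intercept: float) -> np.ndarray:
    eta = np.full(n, intercept)
    for name, slope in link.items():
        eta = eta + slope * latents[name]
    return eta


def generate_frame(params: SimulationParams, return_latents: bool = False):
    """Vectorised generation; returns the cohort as a DataFrame.

    With ``return_latents=True`` additionally returns a DataFrame of the
    per-patient latent variables (severity and system derangements), which
    exist only inside the generator and are never written to cohort files.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    lam = params.system_loadings

    # --- latent severity and injury scores
    severity = rng.gamma(params.severity_shape, params.severity_scale, size=n)
    s_mean = params.severity_shape * params.severity_scale
    s_sd = params.severity_scale * np.sqrt(params.severity_shape)
    s_std = (severity - s_mean) / s_sd

    iss = np.minimum(np.round(16 + severity), 75).astype(int)
    niss_extra = np.round(rng.gamma(params.niss_extra_shape, params.niss_extra_scale, size=n))
    niss = np.minimum(iss + niss_extra, 75).astype(int)

    age = params.age_mean + params.age_sd * rng.standard_normal(n)
    while True:  # resample below the adult cut instead of clipping
        bad = age < 16
        if not bad.any():
            break
        age[bad] = params.age_mean + params.age_sd * rng.standard_normal(int(bad.sum()))
    age = np.round(age, 1)

    def mix(loading, noise):
        return loading * s_std + np.sqrt(1.0 - loading**2) * noise

    d_soft = mix(lam["soft_tissue"], rng.standard_normal(n))
    d_coag = mix(lam["coagulation"], rng.standard_normal(n))
    hem_noise = rng.standard_normal(n)
    d_hem = mix(lam["hemorrhage"], hem_noise)
    rho = params.shock_coupling
    d_ab = lam["acid_base"] * s_std + np.sqrt(1.0 - lam["acid_base"] ** 2) * (
        rho * hem_noise + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    )
    d_tbi = mix(lam["tbi"], rng.standard_normal(n))
    latents = {
        "severity": s_std,
        "soft_tissue": d_soft,
        "coagulation": d_coag,
        "hemorrhage": d_hem,
        "acid_base": d_ab,
        "tbi": d_tbi,
    }

    # --- measured physiology, monotone in its system's derangement
    sd = params.noise_sd

    def noise(name):
        return sd[name] * rng.standard_normal(n)

    lactate = np.round(np.clip(np.exp(0.50 + 0.48 * d_ab + noise("lactate")), 0.1, 30.0), 1)
    ph = np.round(np.clip(7.40 - 0.055 * d_ab + noise("ph"), 6.8, 7.8), 2)
    base_excess = np.round(np.clip(0.5 - 3.6 * d_ab + noise("base_excess"), -30.0, 15.0), 1)
    systolic_bp = np.clip(np.round(125 - 20 * d_hem + noise("systolic_bp")), 40, 220).astype(int)
    prbc_2h = rng.poisson(np.clip(np.exp(-0.8 + 1.1 * d_hem), 0, 40))
    extra_units = rng.poisson(np.clip(np.exp(-0.5 + 0.9 * d_hem), 0, 40))
    # transfusion keeps pace with the 2-h count: late-only massive
    # transfusion is outside the emulation (see the mCGS dominance note)
    prbc_24h = prbc_2h + np.minimum(extra_units, 2 * prbc_2h + 5)
    platelet_count = np.clip(
        np.round(225 * np.exp(-0.30 * d_coag + noise("platelet_count"))), 5, 600
    ).astype(int)
    fibrinogen = np.round(np.clip(2.7 * np.exp(-0.32 * d_coag + noise("fibrinogen")), 0.1, 10.0), 2)
    prothrombin_ratio = np.clip(np.round(98 - 15 * d_coag + noise("prothrombin_ratio")), 5, 130).astype(int)
    inr = np.round(np.clip(np.exp(0.06 + 0.20 * d_coag + noise("inr")), 0.8, 10.0), 2)
    temperature_core = np.round(np.clip(36.4 - 0.55 * d_hem + noise("temperature_core"), 28.0, 41.0), 1)
    chest_ais = np.clip(np.round(1.5 + 1.15 * d_soft + noise("chest_ais")), 0, 6).astype(int)
    abdomen = np.clip(np.round(0.9 + 1.0 * d_soft + noise("abdomen_moore_grade")), 0, 5).astype(int)
    extremity = np.clip(np.round(1.3 + 1.1 * d_soft + noise("extremity_soft_tissue_ais")), 0, 6).astype(int)
    gcs = np.clip(np.round(9.8 - 2.6 * d_tbi + noise("gcs")), 3, 15).astype(int)

    # --- outcomes
    links = params.outcome_links
    icpt = params.calibration_intercepts

    pneumonia = rng.random(n) < expit(_lin(n, links["pneumonia"], latents, icpt["pneumonia"]))
    sepsis_eta = _lin(n, links["sepsis"], latents, icpt["sepsis"])
    sepsis_eta = sepsis_eta + icpt["sepsis_pneumonia_coupling"] * pneumonia
    sepsis = rng.random(n) < expit(sepsis_eta)
    septic_shock = sepsis & (rng.random(n) < icpt["septic_shock_given_sepsis"])
    bacteraemia_eta = _lin(n, {"soft_tissue": links["bacteraemia"]["soft_tissue"]}, latents,
                           icpt["bacteraemia"]) + links["bacteraemia"]["sepsis"] * sepsis
    bacteraemia = rng.random(n) < expit(bacteraemia_eta)
    infection = rng.random(n) < expit(_lin(n, links["infection"], latents, icpt["infection"]))
    ards = rng.random(n) < expit(_lin(n, links["ards"], latents, icpt["ards"]))

    early_death = rng.random(n) < expit(_lin(n, links["early_death"], latents, icpt["early_death"]))
    exsang = early_death & (
        rng.random(n) < expit(_lin(n, links["exsanguination"], latents, icpt["exsanguination"]))
    )
    early_tbi = early_death & ~exsang & (
        rng.random(n) < expit(_lin(n, links["early_tbi"], latents, icpt["early_tbi"]))
    )

    alive = ~early_death
    mof_eta = _lin(n, {k: v for k, v in links["mof_death"].items() if k != "sepsis"},
                   latents, icpt["mof_death"]) + links["mof_death"]["sepsis"] * sepsis
    mof_death = alive & (rng.random(n) < expit(mof_eta))
    late_death = alive & ~mof_death & (
        rng.random(n) < expit(_lin(n, links["late_death"], latents, icpt["late_death"]))
    )
    late_tbi = late_death & (
        rng.random(n) < expit(_lin(n, links["late_tbi"], latents, icpt["late_tbi"]))
    )

    died = early_death | mof_death | late_death
    death_cause = np.full(n, "", dtype=object)
    death_cause[early_death] = "other"
    death_cause[early_tbi] = "TBI"
    death_cause[exsang] = "exsanguination"
    death_cause[mof_death] = "MOF"
    death_cause[late_death & late_tbi] = "TBI"
    death_cause[late_death & ~late_tbi] = "other"

    death_hour = np.full(n, np.nan)
    death_hour[early_death] = np.round(rng.uniform(0.5, 72.0, size=int(early_death.sum())), 1)
    n_late = int((mof_death | late_death).sum())
    death_hour[mof_death | late_death] = np.round(
        72.1 + np.exp(4.3 + 0.8 * rng.standard_normal(n_late)), 1
    )

    mof_flag = mof_death | (
        rng.random(n) < expit(_lin(n, links["mof_morbidity"], latents, icpt["mof_morbidity"]))
    )

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "age_years": age,
            "iss": iss,
            "niss": niss,
            "gcs": gcs.astype(float),
            "systolic_bp": systolic_bp.astype(float),
            "lactate": lactate,
            "ph": ph,
            "base_excess": base_excess,
            "platelet_count": platelet_count.astype(float),
            "fibrinogen": fibrinogen,
            "prothrombin_ratio": prothrombin_ratio.astype(float),
            "inr": inr,
            "prbc_2h": prbc_2h.astype(float),
            "prbc_24h": prbc_24h.astype(float),
            "temperature_core": temperature_core,
            "chest_ais": chest_ais.astype(float),
            "abdomen_moore_grade": abdomen.astype(float),
            "extremity_soft_tissue_ais": extremity.astype(float),
            "died": died.astype(int),
            "death_hour": death_hour,
            "death_cause": [c if c else None for c in death_cause],
            "pneumonia": pneumonia.astype(int),
            "sepsis": sepsis.astype(int),
            "bacteraemia": bacteraemia.astype(int),
            "septic_shock": septic_shock.astype(int),
            "infection": infection.astype(int),
            "ards": ards.astype(int),
            "mof": mof_flag.astype(int),
        }
    )

    # --- missingness last, independently per field
    for fld, p in params.missingness.items():
        if p > 0:
            df.loc[rng.random(n) < p, fld] = np.nan

    if return_latents:
        return df, pd.DataFrame(latents)
    return df


def _records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    from .cohort import record_from_row

    return [record_from_row(row) for row in df.to_dict("records")]


def generate_cohort(params: SimulationParams) -> list[PatientRecord]:
    """Generate a validated synthetic cohort (deterministic under the seed)."""
    if params.n_patients == 0:
        params.validate()
        return []
    return _records_from_frame(generate_frame(params))


# ---------------------------------------------------------------------------
# summaries


@dataclass
class CohortSummary:
    n: int
    mean_age: float
    sd_age: float
    mean_iss: float
    sd_iss: float
    mean_niss: float
    sd_niss: float
    mean_gcs: float
    mortality: float
    death_within_72h: float
    death_causes: dict
    pneumonia: float
    sepsis: float
    bacteraemia: float
    septic_shock: float
    all_complications: float


def summarize_frame(df: pd.DataFrame) -> CohortSummary:
    """Exact sample statistics of a cohort frame (rates over all rows,
    means over present values)."""
    if len(df) == 0:
        raise ValueError("cannot summarise an empty cohort")
    n = len(df)
    died = df["died"].astype(bool)
    early = died & (df["death_hour"] <= 72.0)
    causes = {
        cause: float((df["death_cause"] == cause).sum() / n)
        for cause in ("TBI", "exsanguination", "MOF", "other")
    }
    mof_death = df["death_cause"] == "MOF"
    all_comp = df["pneumonia"].astype(bool) | df["sepsis"].astype(bool) | mof_death
    return CohortSummary(
        n=n,
        mean_age=float(df["age_years"].mean()),
        sd_age=float(df["age_years"].std()),
        mean_iss=float(df["iss"].mean()),
        sd_iss=float(df["iss"].std()),
        mean_niss=float(df["niss"].mean()),
        sd_niss=float(df["niss"].std()),
        mean_gcs=float(df["gcs"].mean()),
        mortality=float(died.mean()),
        death_within_72h=float(early.sum() / n),
        death_causes=causes,
        pneumonia=float(df["pneumonia"].mean()),
        sepsis=float(df["sepsis"].mean()),
        bacteraemia=float(df["bacteraemia"].mean()),
        septic_shock=float(df["septic_shock"].mean()),
        all_complications=float(all_comp.mean()),
    )


def summarize_cohort(cohort: Sequence[PatientRecord]) -> CohortSummary:
    """Summarise a cohort of records (see :func:`summarize_frame`)."""
    from .cohort import cohort_to_frame

    if not cohort:
        raise ValueError("cannot summarise an empty cohort")
    return summarize_frame(cohort_to_frame(cohort))
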