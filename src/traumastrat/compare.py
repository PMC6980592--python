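"""Comparison pipeline: the four validation analyses as composable stages.

Each stage consumes a cohort plus stratification results and produces a
machine-readable report:

* :func:`endpoint_or_table` - per-stratum odds ratios for each endpoint
  against the score's lowest (reference) stratum;
* :func:`agreement_analysis` - cross-tabulation of two scores on the
  jointly stratifiable subset, Krippendorff's alpha, and directional shift
  counts;
* :func:`eac_early_late_profile` - early vs late complication rates per
  EAC stratum with Yates-corrected chi-square tests;
* :func:`cross_stratification` - conditional distribution of one score's
  strata within a stratum of another;
* :func:`nested_system_auc` - logistic prediction models over cumulative
  physiological-system predictor sets with in-sample ROC AUC.

Every stage is complete-case: patients not stratifiable for the score(s)
under analysis (or missing a model predictor) are excluded and the subset
size is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import (
    EARLY_LABELS,
    LATE_LABELS,
    PatientRecord,
    classify_complication_timing,
)
from .scores import ScoreDefinition, StratificationResult, stratify_cohort
from .stats import (
    AlphaEstimate,
    AUCEstimate,
    ChiSquareResult,
    ContingencyTable,
    LogisticModel,
    StatsUsageError,
    chi_square,
    fit_logistic,
    krippendorff_alpha,
    odds_ratio,
    roc_auc,
)

__all__ = [
    "AnalysisError",
    "EndpointORTable",
    "AgreementReport",
    "EarlyLateProfile",
    "NestedAUCReport",
    "ENDPOINTS",
    "NESTED_PREDICTOR_SETS",
    "endpoint_value",
    "endpoint_or_table",
    "agreement_analysis",
    "agreement_from_pairs",
    "pairs_from_crosstab",
    "eac_early_late_profile",
    "cross_stratification",
    "nested_system_auc",
]


class AnalysisError(ValueError):
    """A pipeline stage cannot run on the given inputs."""


#: Endpoints derivable from an OutcomeRecord (timing labels + plain flags).
ENDPOINTS = (
    "death_72h",
    "death_tbi",
    "death_exsanguination",
    "death_mof",
    "pneumonia",
    "sepsis",
    "bacteraemia",
    "septic_shock",
    "infection",
    "ards",
    "mortality",
)

#: Cumulative predictor sets for the nested prediction models, in the
#: order acid-base -> +coagulation -> +hemorrhage -> +soft-tissue.
NESTED_PREDICTOR_SETS = (
    ("acid_base", ("lactate", "ph", "base_excess")),
    ("coagulation", ("platelet_count", "fibrinogen", "prothrombin_ratio")),
    ("hemorrhage", ("systolic_bp", "prbc_2h")),
    ("soft_tissue", ("chest_ais", "abdomen_moore_grade", "extremity_soft_tissue_ais")),
)


def endpoint_value(record: PatientRecord, endpoint: str) -> bool:
    """Evaluate a boolean endpoint on one patient's outcome."""
    if endpoint == "mortality":
        return record.outcome.died
    if endpoint.startswith("death_"):
        return endpoint in classify_complication_timing(record.outcome)
    return bool(getattr(record.outcome, endpoint))


def _stratified_pairs(
    cohort: Sequence[PatientRecord], results: Sequence[StratificationResult]
) -> list[tuple[PatientRecord, StratificationResult]]:
    if len(cohort) != len(results):
        raise AnalysisError("stratification does not cover the cohort")
    return [(p, r) for p, r in zip(cohort, results) if r.stratified]


# ---------------------------------------------------------------------------
# odds-ratio table (per stratum vs reference)


@dataclass
class EndpointORTable:
    score_name: str
    reference: str  # lowest stratum label
    n_per_stratum: dict
    estimates: dict  # (stratum, endpoint) -> OREstimate
    absent_strata: list[str] = field(default_factory=list)


def endpoint_or_table(
    cohort: Sequence[PatientRecord],
    results: Sequence[StratificationResult],
    definition: ScoreDefinition,
    endpoints: Sequence[str] = ("pneumonia", "sepsis", "death_mof", "death_72h"),
) -> EndpointORTable:
    """Odds of each endpoint in every non-reference stratum vs the lowest.

    Strata with no patients are reported as absent rather than as an OR of
    zero; an empty reference stratum is an error because every contrast
    would be undefined.
    """
    pairs = _stratified_pairs(cohort, results)
    reference = definition.strata[0]
    by_stratum: dict[str, list[PatientRecord]] = {s: [] for s in definition.strata}
    for patient, res in pairs:
        by_stratum[res.stratum].append(patient)
    if not by_stratum[reference]:
        raise AnalysisError(f"reference stratum {reference!r} is empty")

    estimates: dict = {}
    absent = [s for s in definition.strata[1:] if not by_stratum[s]]
    for stratum in definition.strata[1:]:
        group = by_stratum[stratum]
        if not group:
            continue
        for endpoint in endpoints:
            exposed = sum(endpoint_value(p, endpoint) for p in group)
            ref_pos = sum(endpoint_value(p, endpoint) for p in by_stratum[reference])
            table = ContingencyTable(
                row_labels=[stratum, reference],
                col_labels=[endpoint, f"no_{endpoint}"],
                counts=np.array(
                    [
                        [exposed, len(group) - exposed],
                        [ref_pos, len(by_stratum[reference]) - ref_pos],
                    ]
                ),
            )
            try:
                estimates[(stratum, endpoint)] = odds_ratio(table)
            except StatsUsageError:
                estimates[(stratum, endpoint)] = None  # degenerate margin
    return EndpointORTable(
        score_name=definition.name,
        reference=reference,
        n_per_stratum={s: len(v) for s, v in by_stratum.items()},
        estimates=estimates,
        absent_strata=absent,
    )


# ---------------------------------------------------------------------------
# agreement between two scores


@dataclass
class AgreementReport:
    cross_tab: ContingencyTable  # score A strata (rows) x score B strata (cols)
    alpha: AlphaEstimate
    n_joint: int
    n_shifted_toward_stable: int  # A strictly less severe than B
    n_shifted_toward_severe: int  # A strictly more severe than B


def agreement_from_pairs(
    pairs: Sequence[tuple[str, str]],
    strata: Sequence[str],
    metric: str = "nominal",
    row_name: str = "A",
    col_name: str = "B",
) -> AgreementReport:
    """Agreement report from raw (stratum_A, stratum_B) label pairs.

    Both labels must come from the same ordered stratum scale.  The
    agreement estimate is Krippendorff's alpha over the coincidence
    matrix with the chosen metric (nominal by default).
    """
    if len(pairs) < 2:
        raise AnalysisError("agreement requires >= 2 jointly stratified patients")
    index = {s: i for i, s in enumerate(strata)}
    counts = np.zeros((len(strata), len(strata)), dtype=int)
    stable = severe = 0
    for a, b in pairs:
        counts[index[a], index[b]] += 1
        if index[a] < index[b]:
            stable += 1
        elif index[a] > index[b]:
            severe += 1
    alpha = krippendorff_alpha(pairs, metric=metric, categories=list(strata))
    return AgreementReport(
        cross_tab=ContingencyTable(
            row_labels=[f"{row_name}:{s}" for s in strata],
            col_labels=[f"{col_name}:{s}" for s in strata],
            counts=counts,
        ),
        alpha=alpha,
        n_joint=len(pairs),
        n_shifted_toward_stable=stable,
        n_shifted_toward_severe=severe,
    )


def pairs_from_crosstab(counts, strata: Sequence[str]) -> list[tuple[str, str]]:
    """Expand an r x r cross-tabulation back into per-unit label pairs.

    Re-tabulating the returned pairs reproduces the input table exactly
    (the reconstruction identity used to feed printed tables into
    :func:`agreement_from_pairs`).
    """
    counts = np.asarray(counts, dtype=int)
    pairs = []
    for i, a in enumerate(strata):
        for j, b in enumerate(strata):
            pairs.extend([(a, b)] * counts[i, j])
    return pairs


def agreement_analysis(
    cohort: Sequence[PatientRecord],
    definition_a: ScoreDefinition,
    definition_b: ScoreDefinition,
    metric: str = "nominal",
) -> AgreementReport:
    """Stratify the cohort by both scores and compare on the joint subset."""
    if definition_a.strata != definition_b.strata:
        raise AnalysisError("agreement requires a shared stratum scale")
    results_a, _ = stratify_cohort(cohort, definition_a)
    results_b, _ = stratify_cohort(cohort, definition_b)
    pairs = [
        (ra.stratum, rb.stratum)
        for ra, rb in zip(results_a, results_b)
        if ra.stratified and rb.stratified
    ]
    if len(pairs) < 2:
        raise AnalysisError("fewer than 2 patients jointly stratifiable")
    return agreement_from_pairs(
        pairs, definition_a.strata, metric=metric,
        row_name=definition_a.name, col_name=definition_b.name,
    )


# ---------------------------------------------------------------------------
# EAC early vs late profile


@dataclass
class EndpointProfile:
    endpoint: str
    timing: str  # "early" | "late"
    rate_per_stratum: dict  # stratum -> rate among stratum patients
    n_per_stratum: dict
    test: Optional[ChiSquareResult]  # None when degenerate (no events)


@dataclass
class EarlyLateProfile:
    score_name: str
    profiles: list[EndpointProfile]


def eac_early_late_profile(
    cohort: Sequence[PatientRecord],
    results: Sequence[StratificationResult],
    definition: ScoreDefinition,
) -> EarlyLateProfile:
    """Early vs late complication rates per stratum with Yates chi-square.

    Endpoints follow the early/late partition of the outcome definitions:
    early = death within 72 h, death from TBI, death from exsanguination;
    late = pneumonia, sepsis, death from MOF.
    """
    pairs = _stratified_pairs(cohort, results)
    strata = definition.strata
    groups = {s: [p for p, r in pairs if r.stratum == s] for s in strata}
    for s in strata:
        if not groups[s]:
            raise AnalysisError(f"stratum {s!r} is empty")

    profiles = []
    for timing, labels in (("early", sorted(EARLY_LABELS)), ("late", sorted(LATE_LABELS))):
        for endpoint in labels:
            counts = {s: sum(endpoint_value(p, endpoint) for p in groups[s]) for s in strata}
            rates = {s: counts[s] / len(groups[s]) for s in strata}
            table = ContingencyTable(
                row_labels=list(strata),
                col_labels=[endpoint, f"no_{endpoint}"],
                counts=np.array([[counts[s], len(groups[s]) - counts[s]] for s in strata]),
            )
            try:
                test = chi_square(table, yates=len(strata) == 2)
            except StatsUsageError:
                test = None  # no events at all -> degenerate
            profiles.append(
                EndpointProfile(
                    endpoint=endpoint,
                    timing=timing,
                    rate_per_stratum=rates,
                    n_per_stratum={s: len(groups[s]) for s in strata},
                    test=test,
                )
            )
    return EarlyLateProfile(score_name=definition.name, profiles=profiles)


# ---------------------------------------------------------------------------
# cross-stratification


def cross_stratification(
    cohort: Sequence[PatientRecord],
    filter_results: Sequence[StratificationResult],
    filter_stratum: str,
    target_results: Sequence[StratificationResult],
    target_strata: Sequence[str],
) -> dict:
    """Distribution of target-score strata within one filter-score stratum."""
    if not (len(cohort) == len(filter_results) == len(target_results)):
        raise AnalysisError("stratifications do not cover the cohort")
    subset = [
        rt.stratum
        for rf, rt in zip(filter_results, target_results)
        if rf.stratified and rf.stratum == filter_stratum and rt.stratified
    ]
    if not subset:
        raise AnalysisError(f"no jointly stratified patients in filter stratum {filter_stratum!r}")
    counts = {s: subset.count(s) for s in target_strata}
    n = len(subset)
    return {
        "filter_stratum": filter_stratum,
        "n": n,
        "counts": counts,
        "fractions": {s: c / n for s, c in counts.items()},
    }


# ---------------------------------------------------------------------------
# nested prediction models


@dataclass
class NestedModel:
    label: str  # cumulative set label, e.g. "acid_base+coagulation"
    predictors: list[str]
    model: LogisticModel
    auc: AUCEstimate


@dataclass
class NestedAUCReport:
    endpoint: str
    n: int
    n_events: int
    models: list[NestedModel]

    @property
    def auc_gain(self) -> float:
        """AUC of the full model minus the first (acid-base only) model."""
        return self.models[-1].auc.auc - self.models[0].auc.auc


def nested_system_auc(
    cohort: Sequence[PatientRecord],
    endpoint_labels: frozenset[str] = EARLY_LABELS,
) -> NestedAUCReport:
    """Fit logistic models over cumulative physiological-system sets.

    Complete-case on the union of all predictors; the response is "any of
    the given complication labels".  AUCs are in-sample, mirroring a
    development-cohort analysis (no cross-validation).
    """
    all_predictors = [p for _, cols in NESTED_PREDICTOR_SETS for p in cols]
    rows, y = [], []
    for rec in cohort:
        values = [rec.get(p) for p in all_predictors]
        if any(v is None for v in values):
            continue
        rows.append(values)
        y.append(bool(classify_complication_timing(rec.outcome) & endpoint_labels))
    X = np.asarray(rows, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) == 0 or y.min() == y.max():
        raise AnalysisError("endpoint must have both classes on the complete-case subset")

    models = []
    running: list[str] = []
    label_parts: list[str] = []
    for system, cols in NESTED_PREDICTOR_SETS:
        running.extend(cols)
        label_parts.append(system)
        idx = [all_predictors.index(p) for p in running]
        fit = fit_logistic(X[:, idx], y, predictor_names=list(running))
        scores = fit.predict_proba(X[:, idx])
        models.append(
            NestedModel(
                label="+".join(label_parts),
                predictors=list(running),
                model=fit,
                auc=roc_auc(scores, y.astype(bool)),
            )
        )
    return NestedAUCReport(
        endpoint="|".join(sorted(endpoint_labels)),
        n=len(y),
        n_events=int(y.sum()),
        models=models,
    )
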