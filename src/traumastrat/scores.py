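"""Declarative rule engine for clinical grading systems.

A :class:`ScoreDefinition` is loaded from a YAML file and lists, per
physiological pathway, the criteria (parameter, direction, ordered cut
values) that assign a patient to one of the score's ordered risk strata.
Four definitions ship with the package under ``definitions/``:

* ``cgs``   - Clinical Grading System: stable < borderline < unstable <
  in_extremis, worst-criterion aggregation over acid-base, hemorrhage,
  coagulation and soft-tissue criteria (pRBC units within 2 h).
* ``mcgs``  - modified CGS: same strata, pared-down criterion set with
  non-overlapping bands and pRBC units within 24 h.
* ``ptgs``  - Polytrauma Grading Score: stable < borderline < unstable,
  a points system over shock, coagulation and injury-severity markers.
* ``eac``   - Early Appropriate Care protocol: low_risk < high_risk from
  acid-base values only (lactate, pH, base excess).

Stratification is a pure function of (patient, definition): a patient
missing any *required* criterion parameter is ``not_stratifiable`` and is
excluded from all downstream statistics; otherwise every evaluable
criterion is scored and aggregated either by worst criterion (the most
severe band reached by any single criterion wins) or by summing criterion
points and cutting the total against the definition's point table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import yaml

from .cohort import PatientRecord

__all__ = [
    "NOT_STRATIFIABLE",
    "Cut",
    "Criterion",
    "ScoreDefinition",
    "StratificationResult",
    "ScoreDefinitionError",
    "load_score_definition",
    "load_default_definition",
    "DEFAULT_SCORES",
    "completeness",
    "evaluate_criterion",
    "stratify",
    "stratify_cohort",
    "coverage_percent",
]

NOT_STRATIFIABLE = "not_stratifiable"
DEFAULT_SCORES = ("cgs", "mcgs", "ptgs", "eac")
_PATHWAYS = ("acid_base", "coagulation", "hemorrhage", "soft_tissue", "injury_severity")
_AGGREGATIONS = ("worst_criterion", "point_sum", "majority_vote")


class ScoreDefinitionError(ValueError):
    """A score definition file is malformed or internally inconsistent."""


@dataclass(frozen=True)
class Cut:
    """A band boundary: the value at which the band is reached.

    ``inclusive`` mirrors the comparison operator printed in the source
    table: a cut printed as "<x" (or ">x") is exclusive, "x or less/more"
    inclusive.
    """

    value: float
    inclusive: bool = True


@dataclass
class Criterion:
    parameter: str
    pathway: str
    direction: str  # "high_is_worse" | "low_is_worse"
    required: bool
    cuts: dict[str, Cut]  # stratum label -> boundary at which it is reached
    points: Optional[dict[str, int]] = None  # per-band points (point_sum scores)

    def met(self, value: float, stratum: str) -> bool:
        cut = self.cuts[stratum]
        if self.direction == "high_is_worse":
            return value >= cut.value if cut.inclusive else value > cut.value
        return value <= cut.value if cut.inclusive else value < cut.value


@dataclass
class ScoreDefinition:
    name: str
    strata: list[str]  # ordered, least to most severe
    criteria: list[Criterion]
    aggregation: str = "worst_criterion"
    point_table: Optional[dict[str, int]] = None  # stratum -> minimum total points

    def severity(self, stratum: str) -> int:
        return self.strata.index(stratum)

    def validate(self) -> None:
        if len(self.strata) < 2:
            raise ScoreDefinitionError(f"{self.name}: needs >= 2 strata")
        if not self.criteria:
            raise ScoreDefinitionError(f"{self.name}: needs >= 1 criterion")
        if self.aggregation not in _AGGREGATIONS:
            raise ScoreDefinitionError(f"{self.name}: unknown aggregation {self.aggregation!r}")
        if (self.aggregation == "point_sum") != (self.point_table is not None):
            raise ScoreDefinitionError(f"{self.name}: point_table present iff aggregation is point_sum")
        if self.point_table is not None:
            mins = [self.point_table[s] for s in self.strata]
            if mins[0] != 0 or any(b <= a for a, b in zip(mins, mins[1:])):
                raise ScoreDefinitionError(
                    f"{self.name}: point_table minimums must start at 0 and strictly increase"
                )
        from .cohort import PhysiologySnapshot, InjuryScores
        known = {f for cls in (PhysiologySnapshot, InjuryScores) for f in cls.__dataclass_fields__}
        for crit in self.criteria:
            if crit.parameter not in known:
                raise ScoreDefinitionError(f"{self.name}: unknown parameter {crit.parameter!r}")
            if crit.pathway not in _PATHWAYS:
                raise ScoreDefinitionError(f"{self.name}: unknown pathway {crit.pathway!r}")
            if crit.direction not in ("high_is_worse", "low_is_worse"):
                raise ScoreDefinitionError(f"{self.name}: bad direction {crit.direction!r}")
            unknown = set(crit.cuts) - set(self.strata[1:])
            if unknown:
                raise ScoreDefinitionError(
                    f"{self.name}/{crit.parameter}: cuts for unknown strata {sorted(unknown)}"
                )
            # cuts must walk monotonically in the worse direction as severity rises
            ordered = [crit.cuts[s].value for s in self.strata[1:] if s in crit.cuts]
            sign = 1.0 if crit.direction == "high_is_worse" else -1.0
            if any(sign * b <= sign * a for a, b in zip(ordered, ordered[1:])):
                raise ScoreDefinitionError(
                    f"{self.name}/{crit.parameter}: cut values not strictly monotone "
                    f"in stratum severity for direction {crit.direction}"
                )
            if self.aggregation == "point_sum":
                if crit.points is None:
                    raise ScoreDefinitionError(f"{self.name}/{crit.parameter}: points required for point_sum")
                pts = [crit.points.get(s, 0) for s in self.strata[1:] if s in crit.cuts]
                if any(b < a for a, b in zip(pts, pts[1:])) or any(p < 0 for p in pts):
                    raise ScoreDefinitionError(
                        f"{self.name}/{crit.parameter}: points must be non-negative and non-decreasing"
                    )


@dataclass
class StratificationResult:
    patient_id: str
    score_name: str
    stratum: str  # a stratum label or NOT_STRATIFIABLE
    triggered: list[tuple[str, float]] = field(default_factory=list)

    @property
    def stratified(self) -> bool:
        return self.stratum != NOT_STRATIFIABLE


def _parse_definition(doc: dict, source: str) -> ScoreDefinition:
    try:
        criteria = []
        for c in doc["criteria"]:
            cuts = {
                stratum: Cut(float(spec["value"]), bool(spec.get("inclusive", True)))
                for stratum, spec in c["cuts"].items()
            }
            criteria.append(
                Criterion(
                    parameter=c["parameter"],
                    pathway=c["pathway"],
                    direction=c["direction"],
                    required=bool(c.get("required", True)),
                    cuts=cuts,
                    points={k: int(v) for k, v in c["points"].items()} if "points" in c else None,
                )
            )
        definition = ScoreDefinition(
            name=doc["name"],
            strata=list(doc["strata"]),
            criteria=criteria,
            aggregation=doc.get("aggregation", "worst_criterion"),
            point_table={k: int(v) for k, v in doc["point_table"].items()}
            if "point_table" in doc
            else None,
        )
    except (KeyError, TypeError) as exc:
        raise ScoreDefinitionError(f"{source}: malformed definition ({exc})") from exc
    definition.validate()
    return definition


def load_score_definition(path) -> ScoreDefinition:
    """Load and validate a score definition from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_definition(doc, str(path))


def load_default_definition(name: str) -> ScoreDefinition:
    """Load one of the shipped definitions: 'cgs', 'mcgs', 'ptgs' or 'eac'."""
    key = name.lower()
    if key not in DEFAULT_SCORES:
        raise ScoreDefinitionError(f"no shipped definition named {name!r}; choose from {DEFAULT_SCORES}")
    text = resources.files("traumastrat").joinpath(f"definitions/{key}.yaml").read_text()
    return _parse_definition(yaml.safe_load(text), f"definitions/{key}.yaml")


def completeness(patient: PatientRecord, definition: ScoreDefinition) -> bool:
    """True iff every required criterion's parameter is present on the patient."""
    return all(
        patient.get(crit.parameter) is not None for crit in definition.criteria if crit.required
    )


def evaluate_criterion(value: float, criterion: Criterion, strata: Sequence[str]) -> str:
    """Most severe stratum whose cut the value meets, else the lowest stratum."""
    if value is None:
        raise ValueError(f"criterion {criterion.parameter!r}: value is absent")
    for stratum in reversed(strata):
        if stratum in criterion.cuts and criterion.met(value, stratum):
            return stratum
    return strata[0]


def stratify(patient: PatientRecord, definition: ScoreDefinition) -> StratificationResult:
    """Assign the patient a stratum (or not_stratifiable) under the definition."""
    if not completeness(patient, definition):
        return StratificationResult(patient.patient_id, definition.name, NOT_STRATIFIABLE)

    evaluated: list[tuple[Criterion, float, str]] = []
    for crit in definition.criteria:
        value = patient.get(crit.parameter)
        if value is None:  # optional criterion not measured
            continue
        evaluated.append((crit, value, evaluate_criterion(value, crit, definition.strata)))

    if definition.aggregation == "point_sum":
        total = sum(
            crit.points.get(band, 0) if band != definition.strata[0] else 0
            for crit, _, band in evaluated
        )
        stratum = definition.strata[0]
        for s in definition.strata:
            if total >= definition.point_table[s]:
                stratum = s
        triggered = [
            (crit.parameter, value)
            for crit, value, band in evaluated
            if band != definition.strata[0] and crit.points.get(band, 0) > 0
        ]
    elif definition.aggregation == "majority_vote":
        counts: dict[str, int] = {s: 0 for s in definition.strata}
        for _, _, band in evaluated:
            counts[band] += 1
        best = max(counts.values()) if evaluated else 0
        stratum = definition.strata[0]
        for s in definition.strata:  # tie goes to the more severe band
            if counts[s] == best:
                stratum = s
        triggered = [(crit.parameter, value) for crit, value, band in evaluated if band == stratum]
        if stratum == definition.strata[0]:
            triggered = []
    else:  # worst_criterion
        stratum = definition.strata[0]
        for _, _, band in evaluated:
            if definition.severity(band) > definition.severity(stratum):
                stratum = band
        triggered = (
            []
            if stratum == definition.strata[0]
            else [(crit.parameter, value) for crit, value, band in evaluated if band == stratum]
        )
    return StratificationResult(patient.patient_id, definition.name, stratum, triggered)


def stratify_cohort(
    cohort: Sequence[PatientRecord], definition: ScoreDefinition
) -> tuple[list[StratificationResult], Optional[float]]:
    """Stratify every patient; coverage = stratified / total (None if empty)."""
    results = [stratify(p, definition) for p in cohort]
    if not results:
        return results, None
    coverage = sum(r.stratified for r in results) / len(results)
    return results, coverage


def coverage_percent(n_stratified: int, n_total: int) -> float:
    """Coverage as a percentage rounded to one decimal (e.g. 3026/3668 -> 82.5)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_stratified / n_total, 1)
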