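"""Selection and parameterization of cognitive training tasks (CTTs).

Each training task carries a model: which cognitive domains/subdomains it
trains (with training weights summing to 1), the Cognitive Status range it
covers per domain, the daily-living contexts it is themed in, and bounds
for its difficulty parameters.  Ranking matches a patient's Cognitive
Status against these models with a per-domain coverage distance (a
variation on Hamming distance on a 0-10 axis: 0 inside the covered range,
the gap to the nearest endpoint otherwise, and the maximal value 10 when a
required domain is not covered at all), combined by the objective's
priority weights.  Lower total distance means a better match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DataValidationError, NoCandidateError
from .npa_aggregation import CognitiveStatus
from .profile_core import Profile

#: Maximal per-domain distance; also the score for uncovered domains.
MAX_DOMAIN_DISTANCE = 10.0

#: Hard parameter limits per task kind (target counts, sections, steps,
#: containers ...); task models may only narrow these.
KIND_LIMITS: dict[str, dict[str, tuple[float, float]]] = {
    "search": {
        "targets": (1, 12),
        "elements_per_section": (1, 20),
        "sections": (1, 8),
    },
    "organize": {"steps": (2, 12)},
    "categorize": {"items": (2, 60), "containers": (1, 4)},
    "pay": {},
    "drive": {},
}

#: Nominal task duration in minutes used for session budgeting.
DEFAULT_NOMINAL_MINUTES = 11.0


@dataclass(frozen=True)
class CTTModel:
    """A training task's cognitive coverage, weights, contexts and bounds."""

    id: str
    kind: str  # search | organize | categorize | pay | drive
    contexts: tuple[str, ...]
    coverage: Mapping[str, tuple[float, float]]  # domain -> CS range [lo, hi]
    training_weights: Mapping[str, float]  # domain -> fraction, sums to 1
    parameters: Mapping[str, tuple[float, float]]  # name -> (min, max)
    nominal_minutes: float = DEFAULT_NOMINAL_MINUTES

    def __post_init__(self) -> None:
        if self.kind not in KIND_LIMITS:
            raise DataValidationError(f"{self.id}: unknown task kind {self.kind!r}")
        for dom, (lo, hi) in self.coverage.items():
            if not (0 <= lo <= hi <= 100):
                raise DataValidationError(
                    f"{self.id}: coverage range for {dom!r} must satisfy "
                    f"0 <= lo <= hi <= 100, got [{lo}, {hi}]"
                )
        if self.training_weights:
            total = sum(self.training_weights.values())
            if abs(total - 1.0) > 1e-6:
                raise DataValidationError(
                    f"{self.id}: training weights sum to {total}, expected 1"
                )
            if any(w < 0 for w in self.training_weights.values()):
                raise DataValidationError(f"{self.id}: negative training weight")
        limits = KIND_LIMITS[self.kind]
        for name, (lo, hi) in self.parameters.items():
            if lo > hi:
                raise DataValidationError(
                    f"{self.id}: parameter {name!r} has min {lo} > max {hi}"
                )
            if name in limits:
                klo, khi = limits[name]
                if lo < klo or hi > khi:
                    raise DataValidationError(
                        f"{self.id}: parameter {name!r} bounds [{lo}, {hi}] exceed "
                        f"the {self.kind} limits [{klo}, {khi}]"
                    )

    @property
    def trained_domains(self) -> tuple[str, ...]:
        return tuple(d for d, w in self.training_weights.items() if w > 0)


@dataclass(frozen=True)
class TrainingObjective:
    """Clinician-set training goal: prioritized domains, preferred
    daily-living contexts, and the session budget."""

    priorities: Mapping[str, float]  # domain -> priority weight >= 0
    contexts: tuple[str, ...] = ()
    sessions: int = 12
    minutes_per_session: float = 30.0
    thresholds: tuple[float, float] = (50.0, 71.0)  # (low, high) challenge %

    def __post_init__(self) -> None:
        if not self.priorities or all(w <= 0 for w in self.priorities.values()):
            raise DataValidationError("objective needs at least one positive priority")
        if any(w < 0 for w in self.priorities.values()):
            raise DataValidationError("priorities must be non-negative")
        low, high = self.thresholds
        if not (0 <= low < high <= 100):
            raise DataValidationError(
                f"challenge thresholds must satisfy 0 <= low < high <= 100, "
                f"got ({low}, {high})"
            )


def domain_distance(
    cs_value: float,
    coverage_range: tuple[float, float] | None,
) -> float:
    """Coverage distance for one domain, on the 0-10 axis.

    0 when the CS value (0-100) falls inside the task's covered range;
    the gap to the nearest endpoint, rescaled by /10 and capped at 10,
    when it falls outside; exactly 10 when the domain is uncovered.
    """
    if not (0 <= cs_value <= 100):
        raise DataValidationError(f"CS value {cs_value} outside [0, 100]")
    if coverage_range is None:
        return MAX_DOMAIN_DISTANCE
    lo, hi = coverage_range
    if not (0 <= lo <= hi <= 100):
        raise DataValidationError(f"malformed coverage range [{lo}, {hi}]")
    if lo <= cs_value <= hi:
        return 0.0
    gap = (lo - cs_value if cs_value < lo else cs_value - hi) / 10.0
    return min(gap, MAX_DOMAIN_DISTANCE)


def rank_ctts(
    cs: CognitiveStatus,
    objective: TrainingObjective,
    repo: Sequence[CTTModel],
) -> list[tuple[CTTModel, float]]:
    """Rank tasks by priority-weighted coverage distance, best first.

    Deterministic: ties in total score break by lexicographic task id, so
    the result is invariant under permutation of ``repo``.
    """
    if not repo:
        raise NoCandidateError("task repository is empty")
    scored = []
    for ctt in repo:
        score = 0.0
        for dom, priority in objective.priorities.items():
            if priority <= 0:
                continue
            score += priority * domain_distance(cs[dom], ctt.coverage.get(dom))
        scored.append((ctt, score))
    scored.sort(key=lambda pair: (pair[1], pair[0].id))
    return scored


def filter_by_context(
    ranked: Sequence[tuple[CTTModel, float]],
    objective: TrainingObjective,
    budget_minutes: float | None = None,
) -> list[tuple[CTTModel, float]]:
    """Keep tasks matching the preferred contexts, within the time budget.

    An empty preference set disables the context filter.  Tasks are kept
    in ranked order while their cumulative nominal duration fits within
    the program budget ``sessions * minutes_per_session``
    (``budget_minutes`` overrides it).  Raises
    :class:`NoCandidateError` rather than returning an empty plan.
    """
    budget = (
        budget_minutes if budget_minutes is not None
        else objective.sessions * objective.minutes_per_session
    )
    kept: list[tuple[CTTModel, float]] = []
    used = 0.0
    for ctt, score in ranked:
        if objective.contexts and not set(ctt.contexts) & set(objective.contexts):
            continue
        if used + ctt.nominal_minutes > budget + 1e-9:
            continue
        kept.append((ctt, score))
        used += ctt.nominal_minutes
    if not kept:
        raise NoCandidateError(
            "no training task survives the context/time filter "
            f"(contexts={list(objective.contexts)}, budget={budget} min)"
        )
    return kept


def task_difficulty(ctt: CTTModel, profile: Profile) -> float:
    """Initial task difficulty: training-weight-weighted mean of the
    profile values over the trained domains, snapped to the profile grid."""
    if not ctt.trained_domains:
        raise DataValidationError(f"{ctt.id}: task trains no domain")
    d = sum(ctt.training_weights[dom] * profile[dom] for dom in ctt.trained_domains)
    return profile.schema.snap(ctt.trained_domains[0], d)


def initial_parameters(ctt: CTTModel, profile: Profile) -> dict[str, float]:
    """Parameter assignment for a task at a patient's 1-10 profile.

    The difficulty ``d`` is the training-weight-weighted mean of the
    profile values over trained domains, snapped to the grid; each
    parameter interpolates linearly between its bounds at
    ``(d - grid_min) / (grid_max - grid_min)`` so the scale minimum maps
    to every parameter's minimum and the maximum to its maximum.
    Integer-bounded parameters are rounded; results always validate.
    """
    d = task_difficulty(ctt, profile)
    lo_g, hi_g, _ = profile.schema.grid_for(ctt.trained_domains[0])
    frac = (d - lo_g) / (hi_g - lo_g) if hi_g > lo_g else 1.0
    params: dict[str, float] = {}
    for name, (pmin, pmax) in ctt.parameters.items():
        value = pmin + (pmax - pmin) * frac
        if float(pmin).is_integer() and float(pmax).is_integer():
            value = float(round(value))
        params[name] = min(max(value, pmin), pmax)
    return params


@dataclass(frozen=True)
class ParameterViolation:
    parameter: str
    value: float
    bound: tuple[float, float]
    source: str  # "task" or "kind"

    def __str__(self) -> str:
        lo, hi = self.bound
        return (
            f"{self.parameter}={self.value} violates {self.source} "
            f"bounds [{lo}, {hi}]"
        )


def validate_task_parameters(
    ctt: CTTModel, params: Mapping[str, float]
) -> list[ParameterViolation]:
    """Check a parameter assignment against the task's bounds and the hard
    per-kind limits.  Violations are returned as data, never raised."""
    violations: list[ParameterViolation] = []
    limits = KIND_LIMITS[ctt.kind]
    for name, value in params.items():
        if name in ctt.parameters:
            lo, hi = ctt.parameters[name]
            if not (lo <= value <= hi):
                violations.append(ParameterViolation(name, value, (lo, hi), "task"))
        if name in limits:
            klo, khi = limits[name]
            if not (klo <= value <= khi):
                violations.append(
                    ParameterViolation(name, value, (klo, khi), "kind")
                )
    return violations
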