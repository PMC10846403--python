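"""In-session difficulty adaptation, rewards and session records.

The controller keeps each task's success rate inside a flow band: after a
play, performance below the low threshold lowers that task's difficulty by
one step, performance above the high threshold raises it by one step, and
anything in between holds it.  Defaults (low 50%, high 71%, step 0.5 on a
1-10 half-step difficulty grid) follow the adaptation rule used in the
tablet-based training the engine grew out of; a clinician can widen or
narrow the band per patient.  Adaptation is per task, not session-global.

Screening-based initialization maps the four MoCA cognitive-domain raw
scores (attention, memory, executive, language, maxima 6/11/7/6) and the
0-30 total onto the same 1-10 half-step scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .ctt_selection import CTTModel
from .errors import CogRehabError, DataValidationError

#: MoCA cognitive-domain maximal raw scores, and the total.
MOCA_DOMAIN_MAX: dict[str, float] = {
    "attention": 6.0,
    "memory": 11.0,
    "executive": 7.0,
    "language": 6.0,
}
MOCA_TOTAL_MAX = 30.0

#: Stable session-log CSV column order (consumed by profile revision).
SESSION_LOG_COLUMNS = [
    "session_id",
    "play_index",
    "task_id",
    "difficulty",
    "performance",
    "medal",
    "points",
    "hint",
]


@dataclass(frozen=True)
class AdaptationConfig:
    """Flow-band controller settings.

    low/high are performance percentages (strict: < low lowers, > high
    raises); step is in difficulty points on the (min, max, step) grid.
    """

    low: float = 50.0
    high: float = 71.0
    step: float = 0.5
    grid: tuple[float, float, float] = (1.0, 10.0, 0.5)

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high <= 100):
            raise DataValidationError(
                f"thresholds must satisfy 0 <= low < high <= 100, "
                f"got ({self.low}, {self.high})"
            )
        lo, hi, gstep = self.grid
        if gstep <= 0 or lo >= hi:
            raise DataValidationError(f"malformed difficulty grid {self.grid}")
        k = self.step / gstep
        if self.step <= 0 or abs(k - round(k)) > 1e-9:
            raise DataValidationError(
                f"step {self.step} must be a positive multiple of the "
                f"grid step {gstep}"
            )


def round_half_step(x: float, step: float = 0.5) -> float:
    """Round to the nearest multiple of ``step``, half away from zero up."""
    return math.floor(x / step + 0.5) * step


def init_difficulty_from_moca(
    raw: Mapping[str, float],
    grid: tuple[float, float, float] = (1.0, 10.0, 0.5),
) -> tuple[dict[str, float], float]:
    """Map MoCA domain raw scores and total onto the 1-10 training scale.

    ``raw`` must carry attention, memory, executive and language scores;
    each maps as ``clamp(round_half_step(10 * raw / max), 1, 10)`` and the
    initial difficulty applies the same mapping to the 0-30 total
    (the total is the sum of the four domain scores).
    """
    lo, hi, step = grid
    values: dict[str, float] = {}
    total = 0.0
    for domain, dmax in MOCA_DOMAIN_MAX.items():
        if domain not in raw:
            raise DataValidationError(f"missing MoCA domain score {domain!r}")
        r = float(raw[domain])
        if not (0 <= r <= dmax):
            raise DataValidationError(
                f"MoCA {domain} score {r} outside [0, {dmax}]"
            )
        total += r
        values[domain] = min(max(round_half_step(10.0 * r / dmax, step), lo), hi)
    difficulty = min(max(round_half_step(10.0 * total / MOCA_TOTAL_MAX, step), lo), hi)
    return values, difficulty


def adapt_difficulty(
    current: float, performance: float, config: AdaptationConfig = AdaptationConfig()
) -> float:
    """One controller step: lower / hold / raise by the configured step,
    clamped at the difficulty grid bounds."""
    lo, hi, _ = config.grid
    if performance < config.low:
        nxt = current - config.step
    elif performance > config.high:
        nxt = current + config.step
    else:
        nxt = current
    return min(max(nxt, lo), hi)


#: Reward bands over performance %: [0,50) none, [50,70] copper,
#: (70,90] silver, (90,100] gold -- a partition of [0,100].
def award_medal(performance: float) -> str | None:
    if not (0 <= performance <= 100):
        raise DataValidationError(f"performance {performance} outside [0, 100]")
    if performance < 50:
        return None
    if performance <= 70:
        return "copper"
    if performance <= 90:
        return "silver"
    return "gold"


def score_task(base_points: float, hint_used: bool) -> float:
    """Points for a completed task: halved when a hint was displayed;
    never negative (errors are never penalized)."""
    if base_points < 0:
        raise DataValidationError("base points must be non-negative")
    return base_points / 2.0 if hint_used else base_points


@dataclass(frozen=True)
class TaskResult:
    task_id: str
    performance: float  # %
    difficulty: float  # difficulty at which the task was played
    hint_used: bool = False
    points: float = 0.0
    medal: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.performance <= 100):
            raise DataValidationError(
                f"performance {self.performance} outside [0, 100]"
            )
        if self.points < 0:
            raise DataValidationError("points must be non-negative")


@dataclass(frozen=True)
class SessionRecord:
    """Ordered play results plus each task's difficulty trajectory."""

    session_id: str
    results: tuple[TaskResult, ...]
    trajectories: Mapping[str, tuple[float, ...]]  # task -> difficulty per play
    timestamp: str | None = None

    @property
    def medals(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.results:
            if r.medal:
                counts[r.medal] = counts.get(r.medal, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "session_id": self.session_id,
                "play_index": i,
                "task_id": r.task_id,
                "difficulty": r.difficulty,
                "performance": r.performance,
                "medal": r.medal or "",
                "points": r.points,
                "hint": int(r.hint_used),
            }
            for i, r in enumerate(self.results)
        ]
        return pd.DataFrame(rows, columns=SESSION_LOG_COLUMNS)


class SessionAbortedError(CogRehabError):
    """The performance source failed mid-session; the partial record is
    preserved on the exception."""

    def __init__(self, cause: Exception, partial: SessionRecord):
        super().__init__(f"session aborted after {len(partial.results)} plays: {cause}")
        self.partial = partial
        self.__cause__ = cause


@dataclass(frozen=True)
class PlayOutcome:
    """What a performance source reports for one play."""

    performance: float  # %
    hint_used: bool = False
    base_points: float | None = None  # defaults to the performance %


PerformanceSource = Callable[[CTTModel, float], "PlayOutcome | float"]


def run_session(
    plan: Sequence[tuple[CTTModel, float]],
    performance_source: PerformanceSource,
    config: AdaptationConfig = AdaptationConfig(),
    session_id: str = "session",
    plays_per_task: int = 1,
) -> SessionRecord:
    """Execute a session's adaptation loop over a validated task plan.

    ``plan`` holds (task, starting difficulty) pairs; each task is played
    ``plays_per_task`` times in round-robin order, and the controller
    adapts each task's difficulty independently after each of its plays.
    The performance source is called as ``source(task, difficulty)`` and
    may return a bare percentage or a :class:`PlayOutcome`; a failure
    aborts the session with the partial record attached.
    """
    if not plan:
        raise DataValidationError("empty session plan")
    current = {ctt.id: diff for ctt, diff in plan}
    trajectories: dict[str, list[float]] = {ctt.id: [] for ctt, _ in plan}
    results: list[TaskResult] = []
    for round_i in range(plays_per_task):
        for ctt, _ in plan:
            difficulty = current[ctt.id]
            try:
                outcome = performance_source(ctt, difficulty)
            except Exception as exc:  # preserve the partial session
                partial = SessionRecord(
                    session_id,
                    tuple(results),
                    {t: tuple(v) for t, v in trajectories.items()},
                )
                raise SessionAbortedError(exc, partial) from exc
            if not isinstance(outcome, PlayOutcome):
                outcome = PlayOutcome(float(outcome))
            base = (
                outcome.base_points
                if outcome.base_points is not None
                else outcome.performance
            )
            results.append(
                TaskResult(
                    task_id=ctt.id,
                    performance=outcome.performance,
                    difficulty=difficulty,
                    hint_used=outcome.hint_used,
                    points=score_task(base, outcome.hint_used),
                    medal=award_medal(outcome.performance),
                )
            )
            trajectories[ctt.id].append(difficulty)
            current[ctt.id] = adapt_difficulty(difficulty, outcome.performance, config)
    return SessionRecord(
        session_id,
        tuple(results),
        {t: tuple(v) for t, v in trajectories.items()},
    )


def write_session_csv(record: SessionRecord, path) -> None:
    record.to_frame().to_csv(path, index=False)


def read_session_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in SESSION_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise DataValidationError(f"session log missing columns: {missing}")
    return frame[SESSION_LOG_COLUMNS]
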