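"""Synthetic patients and the closed training loop.

The simulator is a test harness, not a model of stroke recovery: each
patient carries latent per-domain abilities on a 0-100 scale, task
performance follows a logistic curve in (ability - difficulty) on the 1-10
training axis with additive Gaussian noise, and training can slowly drift
abilities upward.  The logistic model is the simplest mechanism producing
the monotone difficulty-performance relationship the flow-band controller
assumes, and makes the 50-70% success target reachable: performance sits
at exactly 50% when difficulty matches ability.

All randomness flows through one explicitly passed
``numpy.random.Generator``; nothing touches global state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .ctt_selection import CTTModel, task_difficulty
from .errors import DataValidationError
from .profile_core import Profile
from .profile_dynamics import (
    PredictedProfile,
    revise_profile,
    summarize_to_sentence,
)
from .session_engine import (
    AdaptationConfig,
    PlayOutcome,
    SessionRecord,
    run_session,
)

#: Ability ranges per severity preset (latent 0-100 scale).
SEVERITY_PRESETS: dict[str, tuple[float, float]] = {
    "mild": (60.0, 85.0),
    "moderate": (30.0, 70.0),
    "severe": (10.0, 40.0),
}

DEFAULT_NOISE_SD = 5.0
DEFAULT_SLOPE = 1.0


@dataclass(frozen=True)
class SyntheticPatient:
    """Latent abilities plus the parameters of the performance model."""

    abilities: Mapping[str, float]  # domain -> latent ability in [0, 100]
    noise_sd: float = DEFAULT_NOISE_SD
    learning_rate: float = 0.0  # ability points per training play
    slope: float = DEFAULT_SLOPE  # of the logistic difficulty-performance curve

    def __post_init__(self) -> None:
        for dom, a in self.abilities.items():
            if not (0 <= a <= 100):
                raise DataValidationError(
                    f"ability for {dom!r} must lie in [0, 100], got {a}"
                )
        if self.noise_sd < 0:
            raise DataValidationError("noise sd must be non-negative")
        if self.learning_rate < 0:
            raise DataValidationError("learning rate must be non-negative")

    def to_dict(self) -> dict:
        return {
            "abilities": dict(self.abilities),
            "noise_sd": self.noise_sd,
            "learning_rate": self.learning_rate,
            "slope": self.slope,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SyntheticPatient":
        return cls(
            abilities=dict(doc["abilities"]),
            noise_sd=float(doc.get("noise_sd", DEFAULT_NOISE_SD)),
            learning_rate=float(doc.get("learning_rate", 0.0)),
            slope=float(doc.get("slope", DEFAULT_SLOPE)),
        )


def generate_patient(
    seed: int | np.random.Generator,
    domains: Sequence[str],
    severity: str | None = "moderate",
    abilities: Mapping[str, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    learning_rate: float = 0.0,
    slope: float = DEFAULT_SLOPE,
) -> SyntheticPatient:
    """Draw a synthetic patient; reproducible under a fixed seed.

    Explicit ``abilities`` pass through unchanged; otherwise each domain's
    ability is drawn uniformly from the severity preset's range.
    """
    if abilities is not None:
        drawn = {dom: float(abilities[dom]) for dom in domains}
    else:
        if severity not in SEVERITY_PRESETS:
            raise DataValidationError(
                f"unknown severity preset {severity!r}; "
                f"known: {sorted(SEVERITY_PRESETS)}"
            )
        rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
        lo, hi = SEVERITY_PRESETS[severity]
        drawn = {dom: float(rng.uniform(lo, hi)) for dom in domains}
    return SyntheticPatient(drawn, noise_sd, learning_rate, slope)


def effective_ability(patient: SyntheticPatient, ctt: CTTModel) -> float:
    """Training-weight-weighted latent ability for a task, on the 1-10 axis."""
    if not ctt.trained_domains:
        raise DataValidationError(f"{ctt.id}: task trains no domain")
    mean = sum(
        ctt.training_weights[dom] * patient.abilities[dom]
        for dom in ctt.trained_domains
    )
    return mean / 10.0


def simulate_task_performance(
    patient: SyntheticPatient,
    ctt: CTTModel,
    difficulty: float,
    rng: np.random.Generator,
) -> float:
    """Simulated performance % for one play at a given difficulty.

    Expected performance is ``100 * logistic(slope * (ability - difficulty))``
    on the 1-10 axis (50% when difficulty matches ability); Gaussian noise
    is added and the result clipped to [0, 100].
    """
    eff = effective_ability(patient, ctt)
    expected = 100.0 * float(expit(patient.slope * (eff - difficulty)))
    noisy = expected + float(rng.normal(0.0, patient.noise_sd)) if patient.noise_sd else expected
    return float(np.clip(noisy, 0.0, 100.0))


def apply_training_effect(
    patient: SyntheticPatient, record: SessionRecord, models: Mapping[str, CTTModel]
) -> SyntheticPatient:
    """Ability drift after a session: each trained domain rises by
    ``learning_rate`` per play that trained it, capped at 100."""
    if not record.results:
        raise DataValidationError("empty session record")
    if patient.learning_rate == 0:
        return patient
    plays: dict[str, int] = {}
    for result in record.results:
        ctt = models[result.task_id]
        for dom in ctt.trained_domains:
            plays[dom] = plays.get(dom, 0) + 1
    abilities = {
        dom: min(a + patient.learning_rate * plays.get(dom, 0), 100.0)
        for dom, a in patient.abilities.items()
    }
    return replace(patient, abilities=abilities)


# ---------------------------------------------------------------------------
# Closed loop: profile -> plan -> session -> sentence -> revised profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProgramResult:
    """Trace of a simulated training program."""

    final_profile: Profile
    profiles: tuple[Profile, ...]  # profile before each session, then final
    records: tuple[SessionRecord, ...]
    revisions: tuple[PredictedProfile, ...]
    final_patient: SyntheticPatient


def run_program(
    patient: SyntheticPatient,
    repo: Sequence[CTTModel],
    initial_profile: Profile,
    rng: np.random.Generator,
    sessions: int = 12,
    plays_per_session: int = 4,
    config: AdaptationConfig = AdaptationConfig(),
) -> ProgramResult:
    """Simulate a full training program against a synthetic patient.

    Each session plays ``plays_per_session`` tasks, cycling through the
    repository continuously across sessions so every task (hence every
    domain) is trained over the program even when a single session cannot
    hold them all.  Task difficulty at session start comes from the
    current profile; the in-session controller adapts per task; the
    session summary sentence revises the profile (minimal change) into the
    Predicted Cognitive Profile used for the next session.
    """
    models = {ctt.id: ctt for ctt in repo}
    profile = initial_profile
    profiles = [profile]
    records: list[SessionRecord] = []
    revisions: list[PredictedProfile] = []
    cursor = 0
    for s in range(sessions):
        session_tasks = [repo[(cursor + i) % len(repo)] for i in range(plays_per_session)]
        cursor = (cursor + plays_per_session) % len(repo)
        # deduplicate while keeping order: repeated tasks become extra plays
        plan_tasks: list[CTTModel] = []
        plays: dict[str, int] = {}
        for ctt in session_tasks:
            if ctt.id not in plays:
                plan_tasks.append(ctt)
            plays[ctt.id] = plays.get(ctt.id, 0) + 1
        # each task starts at the difficulty implied by the current profile
        plan = [(ctt, task_difficulty(ctt, profile)) for ctt in plan_tasks]
        max_plays = max(plays.values())

        def source(ctt: CTTModel, difficulty: float) -> PlayOutcome:
            return PlayOutcome(
                simulate_task_performance(patient, ctt, difficulty, rng)
            )

        record = run_session(
            plan,
            source,
            config=config,
            session_id=f"s{s:02d}",
            plays_per_task=max_plays,
        )
        records.append(record)
        sentence = summarize_to_sentence(record, models, profile, config)
        tiebreak = _aggregate_training_weights(record, models)
        predicted = revise_profile(
            profile, sentence, tiebreak_weights=tiebreak,
            source_sessions=(record.session_id,),
        )
        revisions.append(predicted)
        profile = predicted.profile
        profiles.append(profile)
        patient = apply_training_effect(patient, record, models)
    return ProgramResult(
        profile, tuple(profiles), tuple(records), tuple(revisions), patient
    )


def _aggregate_training_weights(
    record: SessionRecord, models: Mapping[str, CTTModel]
) -> dict[str, float]:
    weights: dict[str, float] = {}
    for result in record.results:
        for dom, w in models[result.task_id].training_weights.items():
            weights[dom] = weights.get(dom, 0.0) + w
    return weights
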