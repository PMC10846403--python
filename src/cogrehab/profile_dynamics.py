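"""Between-session profile revision by minimal change.

After a session, each trained domain's training-weight-weighted mean
performance is compared against the flow-band thresholds and summarized as
an atom of the profile language: above the band the domain must rise
(``domain > current``), below it must fall (``domain < current``), inside
it must hold (``domain = current``).  The conjunction of these atoms is
the revision input.  The revision operator picks, among the grid profiles
satisfying the sentence, the one at minimal L1 distance from the current
profile (minimal change); distance ties prefer concentrating the change on
domains with higher task training weight, and any remaining ties resolve
to the lexicographically smallest value vector.  With the default sentence
builder every domain moves at most one grid step per session, yielding the
Predicted Cognitive Profile that parameterizes the next session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .ctt_selection import CTTModel
from .errors import (
    DataValidationError,
    InconsistencyError,
    StateSpaceError,
)
from .profile_core import (
    And,
    Atom,
    Label,
    Profile,
    Wff,
    enumerate_models,
    profile_distance,
    satisfies,
    wff_to_string,
)
from .session_engine import AdaptationConfig, SessionRecord

DEFAULT_REVISION_CAP = 200_000


# ---------------------------------------------------------------------------
# Performance summary and sentence construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerformanceSummary:
    """Training-weight-weighted mean performance per trained domain."""

    means: Mapping[str, float]  # domain -> weighted mean %
    play_counts: Mapping[str, int]  # domain -> plays that trained it


def summarize_performance(
    record: SessionRecord,
    models: Mapping[str, CTTModel],
) -> PerformanceSummary:
    """Aggregate a session's plays into per-domain weighted means.

    Each play contributes its performance to every domain its task trains,
    weighted by that task's training weight for the domain.  Only domains
    actually trained in the session appear.
    """
    if not record.results:
        raise DataValidationError("cannot summarize an empty session")
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    counts: dict[str, int] = {}
    for result in record.results:
        if result.task_id not in models:
            raise DataValidationError(f"no task model for {result.task_id!r}")
        ctt = models[result.task_id]
        for dom, w in ctt.training_weights.items():
            if w <= 0:
                continue
            num[dom] = num.get(dom, 0.0) + w * result.performance
            den[dom] = den.get(dom, 0.0) + w
            counts[dom] = counts.get(dom, 0) + 1
    means = {dom: num[dom] / den[dom] for dom in num}
    return PerformanceSummary(means, counts)


def summarize_to_sentence(
    record: SessionRecord,
    models: Mapping[str, CTTModel],
    current: Profile,
    config: AdaptationConfig = AdaptationConfig(),
) -> Wff:
    """Session outcome as a sentence of the profile language.

    Conjunction over trained domains: weighted mean above the high
    threshold demands an increase (strict ``>`` atom), below the low
    threshold a decrease, otherwise equality.  A strict atom that would be
    unsatisfiable because the current value already sits at the grid
    boundary degrades to equality.  Untrained domains are omitted.
    """
    summary = summarize_performance(record, models)
    atoms: list[Atom] = []
    for dom in current.schema.labels:  # deterministic schema order
        if dom not in summary.means:
            continue
        mean = summary.means[dom]
        cur = current[dom]
        lo, hi, _ = current.schema.grid_for(dom)
        if mean > config.high and cur < hi:
            atoms.append(Atom(Label(dom), ">", cur))
        elif mean < config.low and cur > lo:
            atoms.append(Atom(Label(dom), "<", cur))
        else:
            atoms.append(Atom(Label(dom), "=", cur))
    if not atoms:
        raise DataValidationError("session trained no schema domain")
    sentence: Wff = atoms[0]
    for atom in atoms[1:]:
        sentence = And(sentence, atom)
    return sentence


# ---------------------------------------------------------------------------
# Minimal-change revision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictedProfile:
    """Revision output plus provenance."""

    profile: Profile
    sentence: str
    distance: float
    source_sessions: tuple[str, ...] = ()


def _tiebreak_key(
    candidate: Profile,
    current: Profile,
    weight_order: Sequence[str],
):
    """Sort key implementing the revision preferences after distance:
    concentrate change on high-weight domains, then smallest values."""
    changes = tuple(
        -abs(candidate[dom] - current[dom]) for dom in weight_order
    )
    return (changes, candidate.values)


def _conjunction_atoms(sentence: Wff) -> list[Atom] | None:
    """Flatten a conjunction of single-label atoms; None if out of fragment."""
    atoms: list[Atom] = []
    stack: list[Wff] = [sentence]
    while stack:
        node = stack.pop()
        if isinstance(node, And):
            stack.extend((node.left, node.right))
        elif isinstance(node, Atom) and isinstance(node.term, Label):
            atoms.append(node)
        else:
            return None
    return atoms


def _atom_holds(value: float, op: str, const: float) -> bool:
    eps = 1e-9
    if op == "=":
        return abs(value - const) <= eps
    if op == "<":
        return value < const - eps
    if op == ">":
        return value > const + eps
    if op == "<=":
        return value <= const + eps
    return value >= const - eps


def _coordinatewise_revision(
    current: Profile,
    atoms: Sequence[Atom],
) -> Profile:
    """Minimal change for conjunctions of single-label atoms.

    The sentence is separable, so each label's new value is the admissible
    grid value nearest the current one (smaller value on equidistant
    ties, matching the lexicographic preference of the exhaustive search).
    """
    schema = current.schema
    constraints: dict[str, list[Atom]] = {}
    for atom in atoms:
        constraints.setdefault(atom.term.name, []).append(atom)  # type: ignore[union-attr]
    values = list(current.values)
    for dom, dom_atoms in constraints.items():
        idx = schema.index(dom)
        admissible = [
            v
            for v in schema.values_for(dom)
            if all(_atom_holds(v, a.op, a.const) for a in dom_atoms)
        ]
        if not admissible:
            raise InconsistencyError(
                f"no grid value for {dom!r} satisfies the revision sentence"
            )
        cur = values[idx]
        values[idx] = min(admissible, key=lambda v: (abs(v - cur), v))
    return Profile(schema, tuple(values))


def revise_profile(
    current: Profile,
    sentence: Wff,
    tiebreak_weights: Mapping[str, float] | None = None,
    cap: int = DEFAULT_REVISION_CAP,
    source_sessions: Iterable[str] = (),
) -> PredictedProfile:
    """Minimal-change revision of a profile by a sentence.

    Searches the schema grid exhaustively (up to ``cap`` points) for the
    model of ``sentence`` minimizing unit-weighted L1 distance from
    ``current``; distance ties prefer models whose change concentrates on
    domains with higher ``tiebreak_weights`` (task training weights), and
    remaining ties take the lexicographically smallest value vector.
    Above the cap, conjunction-of-atoms sentences use an equivalent
    coordinate-wise construction; anything else re-raises the state-space
    error.  An unsatisfiable sentence raises
    :class:`InconsistencyError` -- never a silent clamp.
    """
    schema = current.schema
    weights = dict(tiebreak_weights or {})
    # domains ordered by descending tiebreak weight, schema order on ties
    weight_order = sorted(
        schema.labels,
        key=lambda dom: (-weights.get(dom, 0.0), schema.index(dom)),
    )
    try:
        models = enumerate_models(sentence, schema, cap=cap)
    except StateSpaceError:
        atoms = _conjunction_atoms(sentence)
        if atoms is None:
            raise
        best = _coordinatewise_revision(current, atoms)
        return PredictedProfile(
            best,
            wff_to_string(sentence),
            profile_distance(current, best),
            tuple(source_sessions),
        )
    if not models:
        raise InconsistencyError(
            f"revision sentence {wff_to_string(sentence)!r} has no model "
            "on the schema grid"
        )
    best = min(
        models,
        key=lambda m: (
            profile_distance(current, m),
            _tiebreak_key(m, current, weight_order),
        ),
    )
    return PredictedProfile(
        best,
        wff_to_string(sentence),
        profile_distance(current, best),
        tuple(source_sessions),
    )


# ---------------------------------------------------------------------------
# Predicted-vs-assessed comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceReport:
    """Signed per-domain differences predicted - assessed, the aggregate
    weighted distance, and the domains flagged above threshold."""

    differences: Mapping[str, float]
    aggregate: float
    flagged: tuple[str, ...]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "differences": dict(self.differences),
            "aggregate": self.aggregate,
            "flagged": list(self.flagged),
            "threshold": self.threshold,
        }


def compare_profiles(
    predicted: Profile,
    assessed: Profile,
    weights: Mapping[str, float] | None = None,
    flag_threshold: float = 0.5,
) -> DivergenceReport:
    """Compare the Predicted Cognitive Profile with a new assessment.

    The aggregate equals :func:`profile_distance` under the same weights;
    domains whose absolute divergence meets ``flag_threshold`` are flagged,
    largest first.
    """
    if predicted.schema != assessed.schema:
        raise DataValidationError("profiles live on different schemas")
    diffs = {
        dom: predicted[dom] - assessed[dom] for dom in predicted.schema.labels
    }
    flagged = sorted(
        (dom for dom, d in diffs.items() if abs(d) >= flag_threshold),
        key=lambda dom: (-abs(diffs[dom]), dom),
    )
    return DivergenceReport(
        diffs,
        profile_distance(predicted, assessed, weights),
        tuple(flagged),
        flag_threshold,
    )


# ---------------------------------------------------------------------------
# Audit log
# ---------------------------------------------------------------------------

def append_revision_audit(
    path,
    predicted: PredictedProfile,
    before: Profile,
    session_id: str | None = None,
) -> None:
    """Append one revision event to a JSON-lines audit log."""
    event = {
        "session_id": session_id,
        "sentence": predicted.sentence,
        "before": list(before.values),
        "after": list(predicted.profile.values),
        "labels": list(before.schema.labels),
        "distance": predicted.distance,
    }
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(event) + "\n")
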