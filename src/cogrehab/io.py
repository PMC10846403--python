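"""File formats and packaged defaults.

JSON documents for structured inputs (instrument registry, weight table,
normative table, raw scores, task repository, objectives, profiles,
synthetic patients), CSV for session logs, JSON-lines for the revision
audit trail.  Every reader validates structure and raises
:class:`~cogrehab.errors.DataValidationError` with context; writers
round-trip (``read(write(x)) == x``).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

from .ctt_selection import CTTModel, TrainingObjective
from .errors import DataValidationError
from .npa_aggregation import (
    InstrumentNorms,
    InstrumentRegistry,
    NormativeStratum,
    NormativeTable,
    NPAInstrument,
    NPAScoreSet,
    SimpleEntry,
    SimpleScheme,
    Subscore,
    WeightEntry,
    WeightTable,
)
from .patient_simulator import SyntheticPatient
from .profile_core import Profile, ProfileSchema


def _load_json(path) -> Any:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    except FileNotFoundError:
        raise DataValidationError(f"{path}: file not found") from None
    except json.JSONDecodeError as exc:
        raise DataValidationError(
            f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}"
        ) from None


def _dump_json(doc: Any, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")


def _require(doc: Mapping, key: str, context: str) -> Any:
    if key not in doc:
        raise DataValidationError(f"{context}: missing required key {key!r}")
    return doc[key]


def config_hash(doc: Any) -> str:
    """Stable short hash of a JSON-serializable configuration document."""
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Instruments
# ---------------------------------------------------------------------------

def parse_instruments(doc: Mapping) -> InstrumentRegistry:
    registry: dict[str, NPAInstrument] = {}
    for item in _require(doc, "instruments", "instrument registry"):
        subs = tuple(
            Subscore(
                id=_require(s, "id", "subscore"),
                min=float(_require(s, "min", "subscore")),
                max=float(_require(s, "max", "subscore")),
                higher_is_better=bool(s.get("higher_is_better", True)),
            )
            for s in _require(item, "subscores", "instrument")
        )
        instr = NPAInstrument(_require(item, "id", "instrument"), subs)
        if instr.id in registry:
            raise DataValidationError(f"duplicate instrument {instr.id!r}")
        registry[instr.id] = instr
    return registry


def load_instruments(path) -> InstrumentRegistry:
    return parse_instruments(_load_json(path))


def write_instruments(registry: InstrumentRegistry, path) -> None:
    _dump_json(
        {
            "instruments": [
                {
                    "id": instr.id,
                    "subscores": [
                        {
                            "id": s.id,
                            "min": s.min,
                            "max": s.max,
                            "higher_is_better": s.higher_is_better,
                        }
                        for s in instr.subscores
                    ],
                }
                for instr in registry.values()
            ]
        },
        path,
    )


# ---------------------------------------------------------------------------
# Weight table
# ---------------------------------------------------------------------------

def parse_weight_table(doc: Mapping) -> WeightTable:
    entries = [
        WeightEntry(
            domain=_require(e, "domain", "weight entry"),
            instrument=_require(e, "instrument", "weight entry"),
            subscore=_require(e, "subscore", "weight entry"),
            raw_pct=float(_require(e, "weight_pct", "weight entry")),
        )
        for e in _require(doc, "entries", "weight table")
    ]
    return WeightTable(entries)


def load_weight_table(path) -> WeightTable:
    return parse_weight_table(_load_json(path))


def write_weight_table(table: WeightTable, path) -> None:
    _dump_json(
        {
            "entries": [
                {
                    "domain": e.domain,
                    "instrument": e.instrument,
                    "subscore": e.subscore,
                    "weight_pct": e.raw_pct,
                }
                for e in table.entries
            ]
        },
        path,
    )


# ---------------------------------------------------------------------------
# Normative table
# ---------------------------------------------------------------------------

def parse_normative(doc: Mapping) -> NormativeTable:
    instruments: dict[str, InstrumentNorms] = {}
    for instr_id, body in _require(doc, "instruments", "normative table").items():
        strata = tuple(
            NormativeStratum(
                criteria=dict(_require(s, "criteria", f"{instr_id} stratum")),
                mean=float(_require(s, "mean", f"{instr_id} stratum")),
                sd=float(s["sd"]) if s.get("sd") is not None else None,
            )
            for s in _require(body, "strata", instr_id)
        )
        instruments[instr_id] = InstrumentNorms(
            min=float(_require(body, "min", instr_id)),
            max=float(_require(body, "max", instr_id)),
            strata=strata,
        )
    return NormativeTable(instruments)


def load_normative(path) -> NormativeTable:
    return parse_normative(_load_json(path))


def write_normative(table: NormativeTable, path) -> None:
    _dump_json(
        {
            "instruments": {
                instr_id: {
                    "min": nrm.min,
                    "max": nrm.max,
                    "strata": [
                        {
                            "criteria": dict(s.criteria),
                            "mean": s.mean,
                            "sd": s.sd,
                        }
                        for s in nrm.strata
                    ],
                }
                for instr_id, nrm in table.instruments.items()
            }
        },
        path,
    )


# ---------------------------------------------------------------------------
# Raw scores
# ---------------------------------------------------------------------------

def parse_scores(doc: Mapping) -> NPAScoreSet:
    raw = _require(doc, "scores", "score set")
    scores = {
        (instr, sub): float(v)
        for instr, subs in raw.items()
        for sub, v in subs.items()
    }
    return NPAScoreSet(
        patient_id=str(_require(doc, "patient_id", "score set")),
        scores=scores,
        sdi=dict(doc.get("sdi", {})),
    )


def load_scores(path) -> NPAScoreSet:
    return parse_scores(_load_json(path))


def write_scores(scores: NPAScoreSet, path) -> None:
    nested: dict[str, dict[str, float]] = {}
    for (instr, sub), v in scores.scores.items():
        nested.setdefault(instr, {})[sub] = v
    _dump_json(
        {"patient_id": scores.patient_id, "sdi": dict(scores.sdi), "scores": nested},
        path,
    )


# ---------------------------------------------------------------------------
# Task repository and objectives
# ---------------------------------------------------------------------------

def parse_ctts(doc: Mapping) -> list[CTTModel]:
    tasks = []
    for t in _require(doc, "tasks", "task repository"):
        tasks.append(
            CTTModel(
                id=_require(t, "id", "task"),
                kind=_require(t, "kind", "task"),
                contexts=tuple(t.get("contexts", ())),
                coverage={
                    d: (float(lo), float(hi))
                    for d, (lo, hi) in t.get("coverage", {}).items()
                },
                training_weights={
                    d: float(w) for d, w in t.get("training_weights", {}).items()
                },
                parameters={
                    p: (float(lo), float(hi))
                    for p, (lo, hi) in t.get("parameters", {}).items()
                },
                nominal_minutes=float(t.get("nominal_minutes", 11.0)),
            )
        )
    ids = [t.id for t in tasks]
    if len(set(ids)) != len(ids):
        raise DataValidationError("duplicate task ids in repository")
    return tasks


def load_ctts(path) -> list[CTTModel]:
    return parse_ctts(_load_json(path))


def write_ctts(tasks, path) -> None:
    _dump_json(
        {
            "tasks": [
                {
                    "id": t.id,
                    "kind": t.kind,
                    "contexts": list(t.contexts),
                    "coverage": {d: list(r) for d, r in t.coverage.items()},
                    "training_weights": dict(t.training_weights),
                    "parameters": {p: list(b) for p, b in t.parameters.items()},
                    "nominal_minutes": t.nominal_minutes,
                }
                for t in tasks
            ]
        },
        path,
    )


def parse_objective(doc: Mapping) -> TrainingObjective:
    thresholds = doc.get("thresholds", [50.0, 71.0])
    return TrainingObjective(
        priorities={d: float(w) for d, w in _require(doc, "priorities", "objective").items()},
        contexts=tuple(doc.get("contexts", ())),
        sessions=int(doc.get("sessions", 12)),
        minutes_per_session=float(doc.get("minutes_per_session", 30.0)),
        thresholds=(float(thresholds[0]), float(thresholds[1])),
    )


def load_objective(path) -> TrainingObjective:
    return parse_objective(_load_json(path))


def write_objective(obj: TrainingObjective, path) -> None:
    _dump_json(
        {
            "priorities": dict(obj.priorities),
            "contexts": list(obj.contexts),
            "sessions": obj.sessions,
            "minutes_per_session": obj.minutes_per_session,
            "thresholds": list(obj.thresholds),
        },
        path,
    )


# ---------------------------------------------------------------------------
# Profiles and patients
# ---------------------------------------------------------------------------

def load_profile(path) -> Profile:
    return Profile.from_dict(_load_json(path))


def write_profile(profile: Profile, path, meta: Mapping | None = None) -> None:
    doc = profile.to_dict()
    if meta:
        doc["meta"] = dict(meta)
    _dump_json(doc, path)


def load_schema(path) -> ProfileSchema:
    return ProfileSchema.from_dict(_load_json(path))


def load_patient(path) -> SyntheticPatient:
    return SyntheticPatient.from_dict(_load_json(path))


def write_patient(patient: SyntheticPatient, path) -> None:
    _dump_json(patient.to_dict(), path)


# ---------------------------------------------------------------------------
# Simplified profiling scheme
# ---------------------------------------------------------------------------

def parse_simple_scheme(doc: Mapping) -> SimpleScheme:
    domains: dict[str, dict[str, tuple[SimpleEntry, ...]]] = {}
    for macro, subdomains in _require(doc, "domains", "simple scheme").items():
        domains[macro] = {
            sub: tuple(
                SimpleEntry(
                    instrument=_require(e, "instrument", f"{macro}/{sub}"),
                    subscore=_require(e, "subscore", f"{macro}/{sub}"),
                    min=float(_require(e, "min", f"{macro}/{sub}")),
                    max=float(_require(e, "max", f"{macro}/{sub}")),
                )
                for e in entries
            )
            for sub, entries in subdomains.items()
        }
    return SimpleScheme(domains)


def load_simple_scheme(path) -> SimpleScheme:
    return parse_simple_scheme(_load_json(path))


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------

def _default_doc(name: str) -> Any:
    ref = resources.files("cogrehab").joinpath("data", name)
    return json.loads(ref.read_text(encoding="utf-8"))


def default_instruments() -> InstrumentRegistry:
    """Registry of the standard assessment battery."""
    return parse_instruments(_default_doc("instruments_default.json"))


def default_weight_table() -> WeightTable:
    """Expert-elicited instrument-to-domain weight table (raw percentages)."""
    return parse_weight_table(_default_doc("weights_default.json"))


def default_simple_scheme() -> SimpleScheme:
    """Simplified five-macro-domain screening scheme (0-10 scale)."""
    return parse_simple_scheme(_default_doc("simple_scheme_default.json"))


def default_ctts() -> list[CTTModel]:
    """Illustrative task repository covering the five task families."""
    return parse_ctts(_default_doc("ctts_default.json"))


def synthetic_normative() -> NormativeTable:
    """Synthetic demonstration norms -- NOT published population data."""
    return parse_normative(_default_doc("normative_synthetic.json"))
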