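"""Building the Assessed Cognitive Profile and Cognitive Status.

The profiling stage turns a heterogeneous battery of neuropsychological
assessment (NPA) sub-scores into a per-domain Assessed Cognitive Profile
(ACP) on a 0-100 scale, and then contextualizes the ACP against normative
data stratified by socio-demographic group to obtain the Cognitive Status
(CS), where 50 anchors group-average performance.

Per domain/subdomain ``k`` the ACP is a weighted sum of min-max normalized
sub-scores::

    ACP_k = sum_ij Norm(score_ij) * W_kij,      sum_ij W_kij = 1

The weight table ships with the package as raw expert-elicited percentages;
renormalization to fractions summing to 1 happens at load, and again over
the *available* entries when some sub-scores are missing (a domain with no
available entry is reported absent, never imputed or zeroed).

The CS for domain ``k`` divides the ACP by twice the expected (normative)
score for the patient's socio-demographic group, so a patient exactly at
the group average lands on 50; values are clipped to [0, 100].
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import norm as _normal

from .errors import DataValidationError
from .profile_core import Profile, ProfileSchema


# ---------------------------------------------------------------------------
# Instruments and raw scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subscore:
    """A bounded sub-score of an NPA instrument.

    ``higher_is_better=False`` marks reverse-scored instruments (e.g.
    depression scales) whose normalization is flipped so that 100 always
    means the better outcome.
    """

    id: str
    min: float
    max: float
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if self.min >= self.max:
            raise DataValidationError(
                f"subscore {self.id!r}: min {self.min} must be below max {self.max}"
            )


@dataclass(frozen=True)
class NPAInstrument:
    id: str
    subscores: tuple[Subscore, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subscores]
        if len(set(ids)) != len(ids):
            raise DataValidationError(f"instrument {self.id!r}: duplicate subscores")

    def subscore(self, subscore_id: str) -> Subscore:
        for s in self.subscores:
            if s.id == subscore_id:
                return s
        raise DataValidationError(
            f"instrument {self.id!r} has no subscore {subscore_id!r}"
        )


InstrumentRegistry = Mapping[str, NPAInstrument]


@dataclass(frozen=True)
class NPAScoreSet:
    """Raw scores for one patient plus socio-demographic information."""

    patient_id: str
    scores: Mapping[tuple[str, str], float]  # (instrument, subscore) -> raw
    sdi: Mapping[str, object] = field(default_factory=dict)

    def validate(self, registry: InstrumentRegistry) -> None:
        for (instr, sub), raw in self.scores.items():
            if instr not in registry:
                raise DataValidationError(f"unknown instrument {instr!r}")
            spec = registry[instr].subscore(sub)
            if not (spec.min <= raw <= spec.max):
                raise DataValidationError(
                    f"{instr}/{sub}: raw score {raw} outside [{spec.min}, {spec.max}]"
                )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_score(
    raw: float, min: float, max: float, higher_is_better: bool = True
) -> float:
    """Linear min-max normalization of a raw score onto [0, 100].

    Reverse-scored inputs (``higher_is_better=False``) are flipped:
    ``100 * (max - raw) / (max - min)``.
    """
    if min >= max:
        raise DataValidationError(f"degenerate score range [{min}, {max}]")
    if not (min <= raw <= max):
        raise DataValidationError(f"raw score {raw} outside [{min}, {max}]")
    frac = (raw - min) / (max - min)
    if not higher_is_better:
        frac = 1.0 - frac
    return 100.0 * frac


def renormalize_weights(raw_weights: Sequence[float]) -> list[float]:
    """Rescale positive raw percentages to fractions summing to 1.

    Order is preserved; used both at weight-table load (so the table can
    ship verbatim raw percentages) and again over the available entries
    when sub-scores are missing.
    """
    if len(raw_weights) == 0:
        raise DataValidationError("cannot renormalize an empty weight list")
    if any(w <= 0 for w in raw_weights):
        raise DataValidationError("raw weights must be strictly positive")
    total = sum(raw_weights)
    return [w / total for w in raw_weights]


# ---------------------------------------------------------------------------
# Weight table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightEntry:
    domain: str            # "domain" or "domain.subdomain" key
    instrument: str
    subscore: str
    raw_pct: float

    def __post_init__(self) -> None:
        if self.raw_pct <= 0:
            raise DataValidationError(
                f"{self.domain}/{self.instrument}/{self.subscore}: "
                "raw weight must be positive"
            )


class WeightTable:
    """Maps (domain, instrument, subscore) to expert-elicited raw weights.

    ``renormalized(domain)`` yields the per-entry fractions used in the ACP
    weighted sum; restricting to a subset of available entries renormalizes
    over the surviving raw percentages.
    """

    def __init__(self, entries: Sequence[WeightEntry]):
        self.entries = tuple(entries)
        seen = set()
        for e in self.entries:
            key = (e.domain, e.instrument, e.subscore)
            if key in seen:
                raise DataValidationError(f"duplicate weight entry {key}")
            seen.add(key)

    @property
    def domains(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.domain not in out:
                out.append(e.domain)
        return out

    def entries_for(self, domain: str) -> list[WeightEntry]:
        return [e for e in self.entries if e.domain == domain]

    def renormalized(
        self,
        domain: str,
        available: set[tuple[str, str]] | None = None,
    ) -> dict[tuple[str, str], float]:
        """Fractions per (instrument, subscore) for one domain.

        ``available`` restricts to present sub-scores before renormalizing;
        an empty restriction yields an empty mapping (the caller decides
        whether that makes the domain absent).
        """
        entries = self.entries_for(domain)
        if available is not None:
            entries = [e for e in entries if (e.instrument, e.subscore) in available]
        if not entries:
            return {}
        fracs = renormalize_weights([e.raw_pct for e in entries])
        return {(e.instrument, e.subscore): f for e, f in zip(entries, fracs)}

    def instrument_weights(
        self,
        domain: str,
        available: set[tuple[str, str]] | None = None,
    ) -> dict[str, float]:
        """Per-instrument fractions for a domain (subscore weights summed).

        These serve as the default normative-aggregation weights ``w_i``;
        ``available`` restricts to the sub-scores actually present.
        """
        fracs = self.renormalized(domain, available=available)
        out: dict[str, float] = {}
        for (instr, _), f in fracs.items():
            out[instr] = out.get(instr, 0.0) + f
        return out


# ---------------------------------------------------------------------------
# ACP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ACPResult:
    """Assessed Cognitive Profile: 0-100 value per scorable domain.

    Domains whose every weighted sub-score is missing appear in ``absent``
    and carry no value.
    """

    values: Mapping[str, float]
    absent: frozenset[str] = frozenset()

    def __getitem__(self, domain: str) -> float:
        return self.values[domain]

    def to_profile(self, schema: ProfileSchema) -> Profile:
        """Snap the ACP onto a schema grid (labels must be scorable)."""
        vals = []
        for label in schema.labels:
            if label not in self.values:
                raise DataValidationError(f"domain {label!r} has no ACP value")
            vals.append(schema.snap(label, self.values[label]))
        return Profile(schema, tuple(vals))


def compute_acp(
    scores: NPAScoreSet,
    weights: WeightTable,
    instruments: InstrumentRegistry,
) -> ACPResult:
    """Aggregate normalized sub-scores into the per-domain ACP.

    For each domain the weights are renormalized over the sub-scores
    actually present in ``scores``; each ACP value is a convex combination
    of normalized scores and therefore lies in [0, 100].
    """
    scores.validate(instruments)
    available = set(scores.scores.keys())
    values: dict[str, float] = {}
    absent: set[str] = set()
    for domain in weights.domains:
        fracs = weights.renormalized(domain, available=available)
        if not fracs:
            absent.add(domain)
            continue
        total = 0.0
        for (instr, sub), f in fracs.items():
            spec = instruments[instr].subscore(sub)
            normed = normalize_score(
                scores.scores[(instr, sub)], spec.min, spec.max, spec.higher_is_better
            )
            total += normed * f
        values[domain] = total
    return ACPResult(values, frozenset(absent))


# ---------------------------------------------------------------------------
# Normative data and Cognitive Status
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormativeStratum:
    """Reference statistics for one socio-demographic group.

    ``criteria`` maps an SDI key to an inclusive ``[lo, hi]`` range (for
    numeric keys) or an explicit list of admissible values.
    """

    criteria: Mapping[str, object]
    mean: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd <= 0:
            raise DataValidationError("stratum sd must be positive")

    def matches(self, sdi: Mapping[str, object]) -> bool:
        for key, rule in self.criteria.items():
            if key not in sdi:
                return False
            val = sdi[key]
            if (
                isinstance(rule, (list, tuple))
                and len(rule) == 2
                and all(isinstance(x, (int, float)) for x in rule)
                and isinstance(val, (int, float))
            ):
                lo, hi = rule
                if not (lo <= val <= hi):
                    return False
            elif isinstance(rule, (list, tuple)):
                if val not in rule:
                    return False
            elif val != rule:
                return False
        return True


@dataclass(frozen=True)
class InstrumentNorms:
    """Normative strata for one instrument's total score."""

    min: float
    max: float
    strata: tuple[NormativeStratum, ...]

    def stratum_for(self, sdi: Mapping[str, object]) -> NormativeStratum:
        for s in self.strata:
            if s.matches(sdi):
                return s
        raise DataValidationError(
            f"no normative stratum covers SDI {dict(sdi)!r}"
        )


class NormativeTable:
    def __init__(self, instruments: Mapping[str, InstrumentNorms]):
        self.instruments = dict(instruments)

    def expected_normalized(self, instrument: str, sdi: Mapping[str, object]) -> float:
        """Group-average score for ``instrument``, min-max normalized to 0-100."""
        if instrument not in self.instruments:
            raise DataValidationError(f"no normative data for {instrument!r}")
        nrm = self.instruments[instrument]
        stratum = nrm.stratum_for(sdi)
        return normalize_score(stratum.mean, nrm.min, nrm.max)

    def stratum(self, instrument: str, sdi: Mapping[str, object]) -> NormativeStratum:
        if instrument not in self.instruments:
            raise DataValidationError(f"no normative data for {instrument!r}")
        return self.instruments[instrument].stratum_for(sdi)


@dataclass(frozen=True)
class CognitiveStatus:
    """Per-domain standing relative to the patient's socio-demographic group.

    Values live in [0, 100]; 50 marks group-average performance.
    """

    values: Mapping[str, float]
    absent: frozenset[str] = frozenset()

    def __getitem__(self, domain: str) -> float:
        return self.values[domain]


def compute_cs(
    acp: ACPResult,
    normative: NormativeTable,
    sdi: Mapping[str, object],
    nd_weights: Mapping[str, Mapping[str, float]],
    method: str = "anchor",
) -> CognitiveStatus:
    """Contextualize an ACP against normative data.

    ``nd_weights`` maps each domain to per-instrument fractions summing to
    1 (``WeightTable.instrument_weights`` provides the default).  Two
    backends are exposed:

    - ``"anchor"`` (default): the expected normalized score per domain is
      the weighted mean of each contributing instrument's group-average;
      ``CS_k = 100 * ACP_k / (2 * expected_k)``, clipped to [0, 100], so a
      patient exactly at the group average lands on 50.
    - ``"percentile"``: the patient's ACP is placed on a normal curve with
      the aggregated group mean and sd; ``CS_k`` is the resulting
      percentile (this requires every stratum to carry an sd).
    """
    if method not in ("anchor", "percentile"):
        raise DataValidationError(f"unknown CS method {method!r}")
    values: dict[str, float] = {}
    for domain, acp_k in acp.values.items():
        iw = nd_weights.get(domain)
        if not iw:
            raise DataValidationError(f"no normative weights for domain {domain!r}")
        if method == "anchor":
            expected = sum(
                normative.expected_normalized(instr, sdi) * w
                for instr, w in iw.items()
            )
            if expected <= 0:
                raise DataValidationError(
                    f"domain {domain!r}: expected normative score is zero"
                )
            cs = 100.0 * acp_k / (2.0 * expected)
        else:
            mean = 0.0
            var = 0.0
            for instr, w in iw.items():
                nrm = normative.instruments[instr]
                stratum = normative.stratum(instr, sdi)
                if stratum.sd is None:
                    raise DataValidationError(
                        f"{instr}: percentile backend requires stratum sd"
                    )
                scale = 100.0 / (nrm.max - nrm.min)
                mean += normalize_score(stratum.mean, nrm.min, nrm.max) * w
                var += (stratum.sd * scale * w) ** 2
            cs = 100.0 * float(_normal.cdf(acp_k, loc=mean, scale=var ** 0.5))
        values[domain] = min(max(cs, 0.0), 100.0)
    return CognitiveStatus(values, acp.absent)


# ---------------------------------------------------------------------------
# Simplified screening-battery profile (0-10 macro-domains)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimpleEntry:
    instrument: str
    subscore: str
    min: float
    max: float


@dataclass(frozen=True)
class SimpleScheme:
    """Simplified profiling scheme: macro-domains split into subdomains,
    each backed by one or two bounded instrument scores."""

    # macro-domain -> subdomain -> entries
    domains: Mapping[str, Mapping[str, tuple[SimpleEntry, ...]]]


def compute_simple_profile(
    scores: NPAScoreSet,
    scheme: SimpleScheme,
) -> tuple[dict[str, float], set[str]]:
    """Macro-domain profile on a 0-10 scale from the simplified scheme.

    Each entry is min-max normalized to 0-10; a subdomain is the mean of
    its available entries, and a macro-domain the mean of its scorable
    subdomains.  Returns (values, absent-macro-domains).
    """
    values: dict[str, float] = {}
    absent: set[str] = set()
    for macro, subdomains in scheme.domains.items():
        sub_means: list[float] = []
        for entries in subdomains.values():
            normed = [
                10.0 * (scores.scores[(e.instrument, e.subscore)] - e.min)
                / (e.max - e.min)
                for e in entries
                if (e.instrument, e.subscore) in scores.scores
            ]
            if normed:
                sub_means.append(statistics.mean(normed))
        if sub_means:
            values[macro] = statistics.mean(sub_means)
        else:
            absent.add(macro)
    return values, absent
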