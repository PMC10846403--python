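# cogrehab

An adaptive cognitive-neurorehabilitation engine. `cogrehab` takes the
heterogeneous sub-scores of a neuropsychological assessment (NPA) battery
and turns them into a per-domain cognitive profile, selects and
parameterizes cognitive training tasks (CTTs) to match that profile,
keeps each task's in-session success rate inside a flow band by adjusting
difficulty, and revises the profile between sessions with a
minimal-change (belief-revision) operator. A synthetic-patient simulator
closes the loop so the whole pipeline can be exercised and tested without
clinical data.

It is written for researchers and engineers building computerized
cognitive-training systems: the library is the interface, and a thin
`cogrehab` CLI covers the common profile → plan → run → compare workflow.

## The model

**Profiles and the profile language.** A profile is a tuple
⟪v₁, …, vₙ⟫ of finite-valued components, one per cognitive
domain/subdomain, each on an explicit (min, max, step) grid — integers by
default, the half-step 1–10 training scale for session work. Sentences
about profiles come from a small propositional language: atoms compare
terms (labels, sums, negations) against constants
(`memory > 7`, `weight >= 90 & height <= 180`), with `¬`/`∧` primitive and
`≤, ≥, ∨, →, ↔` derived.

**Assessed Cognitive Profile (ACP).** Per domain *k*,

    ACP_k = Σ_ij Norm(score_ij) · W_kij,   Σ_ij W_kij = 1,

where `Norm` is linear min–max normalization onto [0, 100] and the
weights `W_kij` are expert-elicited raw percentages, renormalized per
domain (and re-renormalized over whatever sub-scores are actually
available; a domain with none is absent, never imputed). The **Cognitive
Status (CS)** contextualizes the ACP against normative data for the
patient's socio-demographic group: `CS_k = 100·ACP_k / (2·expected_k)`,
clipped to [0, 100], so group-average performance anchors at the 50th
percentile.

**Task selection.** Each CTT model declares which domains it trains
(weights summing to 1), the CS range it covers per domain, its
daily-living contexts and parameter bounds. Tasks are ranked by a
priority-weighted coverage distance (0 inside the covered range, the gap
to the nearest endpoint on a 0–10 axis otherwise, 10 when uncovered),
filtered by context and session budget, and parameterized by linear
interpolation at the profile-implied difficulty.

**In-session adaptation.** After each play, performance below 50% lowers
that task's difficulty by 0.5 points on the 1–10 half-step grid,
performance above 71% raises it, anything between holds it
(both thresholds configurable). Rewards: <50% no medal, 50–70% copper,
70–90% silver, >90% gold; hints halve the points, errors never go
negative.

**Profile dynamics.** A session is summarized as a sentence of the
profile language — per trained domain, the training-weight-weighted mean
performance demands an increase (`dom > current`), a decrease
(`dom < current`) or a hold (`dom = current`). The revision operator
returns the grid model of that sentence at minimal L1 distance from the
current profile, breaking ties toward domains with higher training
weight; this Predicted Cognitive Profile parameterizes the next session
and is later compared against the next real assessment.

## Worked example

Build a profile from a scores file (the packaged instrument registry and
weight table are used by default):

```
$ cogrehab profile scores.json --out .
domain (ACP)                         value
general_cognition                     80.00
orientation                           83.33
memory.immediate_verbal               60.00
executive.working_memory              51.79
attention.sustained                   51.67
...
functionality.basic_adl              absent
```

Values are 0–100 weighted aggregates of the normalized sub-scores —
this patient's general cognition (MoCA 24/30 → 80) is well preserved
while processing speed (35.15) is not; domains whose instruments were not
administered are reported absent rather than guessed.

Run the full closed loop against a synthetic patient:

```
$ cogrehab simulate --seed 1 --sessions 12 --out sim
domain        ability  final-profile
attention        50.5    5.0
executive        68.0    6.0
language         35.8    3.5
memory           67.9    6.0
```

After twelve simulated sessions the revised profile tracks the latent
abilities (ability/10, slightly below, since the controller holds
difficulty where success stays above 50%): the engine has *discovered*
the patient's per-domain levels purely from task performance. Session
logs (`sim/s00.csv`, …) record each play's difficulty, performance,
medal and points.

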