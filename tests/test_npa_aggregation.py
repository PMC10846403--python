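"""ACP/CS aggregation: normalization, weight renormalization, worked sums."""

import pytest

from cogrehab import (
    ACPResult,
    DataValidationError,
    NormativeTable,
    NPAScoreSet,
    compute_acp,
    compute_cs,
    compute_simple_profile,
    normalize_score,
    renormalize_weights,
)
from cogrehab.npa_aggregation import InstrumentNorms, NormativeStratum
from cogrehab.io import default_simple_scheme

# Expected renormalized percentages per domain row of the shipped weight
# table, in entry order.  Two cells carry sum-to-100 rounding in their
# published form (working-memory 17.13 is exactly 17.135, inhibition 79.88
# is exactly 79.8706), so those rows get a slightly wider tolerance.
TABLE_ROWS = [
    ("general_cognition", [50.0, 50.0], 0.006),
    ("orientation", [72.73, 27.27], 0.006),
    ("memory.immediate_verbal", [68.57, 22.86, 8.57], 0.006),
    ("memory.immediate_visual", [50.0, 50.0], 0.006),
    ("memory.delayed_verbal", [75.0, 25.0], 0.006),
    ("memory.delayed_visual", [50.0, 50.0], 0.006),
    ("executive.working_memory", [68.54, 17.13, 8.57, 5.76], 0.006),
    ("executive.processing_speed", [36.36, 36.36, 24.23, 3.05], 0.006),
    ("executive.verbal_fluency", [88.81, 11.19], 0.006),
    ("executive.inhibition", [79.88, 10.06, 10.06], 0.015),
    ("executive.visuoconstructive", [50.0, 50.0], 0.006),
    ("language.comprehension", [100.0], 0.006),
    ("language.expression", [100.0], 0.006),
    ("attention.divided", [100.0], 0.006),
    ("attention.sustained", [81.33, 3.42, 5.08, 10.17], 0.006),
    ("premorbid_intelligence", [100.0], 0.006),
    ("functionality.basic_adl", [50.0, 50.0], 0.006),
    ("functionality.instrumental_familiar", [50.0, 50.0], 0.006),
    ("functionality.instrumental_advanced", [33.33, 33.33, 33.33], 0.006),
    ("functionality.perceived_impact", [100.0], 0.006),
    ("depressive_symptomatology", [100.0], 0.006),
]

class TestNormalize:
    @pytest.mark.parametrize(
        "raw,lo,hi,expected",
        [(30, 0, 30, 100.0), (0, 0, 30, 0.0), (15, 0, 30, 50.0), (12, 0, 16, 75.0)],
    )
    def test_linear_min_max(self, raw, lo, hi, expected):
        assert normalize_score(raw, lo, hi) == pytest.approx(expected)

    def test_reverse_scored_flips(self):
        assert normalize_score(0, 0, 30, higher_is_better=False) == 100.0
        assert normalize_score(30, 0, 30, higher_is_better=False) == 0.0

    def test_out_of_range_raises(self):
        with pytest.raises(DataValidationError):
            normalize_score(31, 0, 30)

    def test_degenerate_range_raises(self):
        with pytest.raises(DataValidationError):
            normalize_score(5, 5, 5)


class TestRenormalizeWeights:
    def test_working_memory_row(self):
        fracs = renormalize_weights([50, 12.5, 6.25, 4.2])
        assert fracs == pytest.approx([0.6854, 0.1713, 0.0857, 0.0576], abs=5.1e-5)

    def test_single_entry_becomes_one(self):
        assert renormalize_weights([50]) == [1.0]

    def test_orientation_row(self):
        assert renormalize_weights([33.33, 12.5]) == pytest.approx(
            [0.7273, 0.2727], abs=5e-5
        )

    def test_sum_is_one_and_order_preserved(self):
        fracs = renormalize_weights([1, 2, 3])
        assert sum(fracs) == pytest.approx(1.0)
        assert fracs == sorted(fracs)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(DataValidationError):
            renormalize_weights([])
        with pytest.raises(DataValidationError):
            renormalize_weights([50, 0])


class TestShippedWeightTable:
    @pytest.mark.parametrize("domain,printed,tol", TABLE_ROWS, ids=[r[0] for r in TABLE_ROWS])
    def test_renormalization_reproduces_published_percentages(
        self, weight_table, domain, printed, tol
    ):
        entries = weight_table.entries_for(domain)
        fracs = renormalize_weights([e.raw_pct for e in entries])
        assert len(fracs) == len(printed)
        for got, want in zip(fracs, printed):
            assert abs(got * 100 - want) <= tol

    def test_renormalized_fractions_sum_to_one(self, weight_table):
        for domain in weight_table.domains:
            total = sum(weight_table.renormalized(domain).values())
            assert total == pytest.approx(1.0, abs=1e-9)


def _wm_scores(**override) -> NPAScoreSet:
    """Raw scores whose normalized values are DSC 80, digit 60, calculus 40,
    target 100 (the working-memory worked example)."""
    scores = {
        ("WAISIII", "digit_symbol_coding"): 0.80 * 133,
        ("MoCA", "digit_reverse"): 0.60,
        ("MoCA", "calculus"): 0.40 * 3,
        ("MoCA", "target_detection"): 1.0,
    }
    scores.update(override)
    return NPAScoreSet("p1", scores, {"age": 65, "education": 8})


class TestComputeACP:
    def test_working_memory_weighted_sum(self, weight_table, instruments):
        acp = compute_acp(_wm_scores(), weight_table, instruments)
        # 0.6854*80 + 0.1713*60 + 0.0857*40 + 0.0576*100
        assert acp["executive.working_memory"] == pytest.approx(74.30, abs=0.05)

    def test_all_maxima_give_100_everywhere(self, weight_table, instruments):
        scores = {}
        for instr in instruments.values():
            for sub in instr.subscores:
                raw = sub.max if sub.higher_is_better else sub.min
                scores[(instr.id, sub.id)] = raw
        acp = compute_acp(
            NPAScoreSet("p", scores), weight_table, instruments
        )
        assert not acp.absent
        for domain, value in acp.values.items():
            assert value == pytest.approx(100.0), domain

    def test_missing_subscores_renormalize_over_available(
        self, weight_table, instruments
    ):
        """With every MoCA sub-score missing, working memory falls back to
        the digit-symbol-coding score alone at weight 1."""
        scores = NPAScoreSet("p", {("WAISIII", "digit_symbol_coding"): 0.80 * 133})
        acp = compute_acp(scores, weight_table, instruments)
        assert acp["executive.working_memory"] == pytest.approx(80.0)

    def test_domain_with_no_entries_is_absent_not_zero(
        self, weight_table, instruments
    ):
        acp = compute_acp(_wm_scores(), weight_table, instruments)
        assert "memory.delayed_visual" in acp.absent
        assert "memory.delayed_visual" not in acp.values

    def test_monotone_in_raw_subscores(self, weight_table, instruments, rng):
        """Raising any direct-scored raw sub-score never lowers any domain."""
        keys = [
            (i.id, s.id)
            for i in instruments.values()
            for s in i.subscores
            if s.higher_is_better
        ]
        base_scores = {
            (i.id, s.id): s.min + 0.5 * (s.max - s.min)
            for i in instruments.values()
            for s in i.subscores
        }
        before = compute_acp(
            NPAScoreSet("p", base_scores), weight_table, instruments
        )
        for key in [keys[i] for i in rng.choice(len(keys), 8, replace=False)]:
            instr, sub = key
            spec = instruments[instr].subscore(sub)
            bumped = dict(base_scores)
            bumped[key] = spec.min + 0.75 * (spec.max - spec.min)
            after = compute_acp(
                NPAScoreSet("p", bumped), weight_table, instruments
            )
            for domain in before.values:
                assert after[domain] >= before[domain] - 1e-9

    def test_convex_bounds_per_domain(self, weight_table, instruments, rng):
        """Each domain value lies between the min and max of its normalized
        available sub-scores."""
        scores = {}
        for instr in instruments.values():
            for sub in instr.subscores:
                scores[(instr.id, sub.id)] = float(
                    rng.uniform(sub.min, sub.max)
                )
        score_set = NPAScoreSet("p", scores)
        acp = compute_acp(score_set, weight_table, instruments)
        for domain in acp.values:
            normed = []
            for e in weight_table.entries_for(domain):
                spec = instruments[e.instrument].subscore(e.subscore)
                normed.append(
                    normalize_score(
                        scores[(e.instrument, e.subscore)],
                        spec.min,
                        spec.max,
                        spec.higher_is_better,
                    )
                )
            assert min(normed) - 1e-9 <= acp[domain] <= max(normed) + 1e-9


def _single_norms(mean: float, sd: float = 10.0) -> NormativeTable:
    return NormativeTable(
        {
            "T": InstrumentNorms(
                0.0,
                100.0,
                (NormativeStratum({"age": [0, 120]}, mean, sd),),
            )
        }
    )


class TestComputeCS:
    ND_W = {"dom": {"T": 1.0}}

    def test_group_average_anchors_to_50(self):
        cs = compute_cs(
            ACPResult({"dom": 60.0}), _single_norms(60.0), {"age": 70}, self.ND_W
        )
        assert cs["dom"] == pytest.approx(50.0)

    def test_zero_acp_floors_at_zero(self):
        cs = compute_cs(
            ACPResult({"dom": 0.0}), _single_norms(60.0), {"age": 70}, self.ND_W
        )
        assert cs["dom"] == 0.0

    def test_cross_multiplication_example(self):
        cs = compute_cs(
            ACPResult({"dom": 90.0}), _single_norms(60.0), {"age": 70}, self.ND_W
        )
        assert cs["dom"] == pytest.approx(75.0)

    def test_linear_below_the_clip(self):
        norms = _single_norms(70.0)
        lo = compute_cs(ACPResult({"dom": 30.0}), norms, {"age": 70}, self.ND_W)
        hi = compute_cs(ACPResult({"dom": 60.0}), norms, {"age": 70}, self.ND_W)
        assert hi["dom"] == pytest.approx(2 * lo["dom"])

    def test_clipped_at_100(self):
        cs = compute_cs(
            ACPResult({"dom": 100.0}), _single_norms(20.0), {"age": 70}, self.ND_W
        )
        assert cs["dom"] == 100.0

    def test_missing_stratum_raises(self):
        with pytest.raises(DataValidationError, match="stratum"):
            compute_cs(
                ACPResult({"dom": 50.0}), _single_norms(60.0), {"age": 150}, self.ND_W
            )

    def test_percentile_backend_centers_at_50(self):
        cs = compute_cs(
            ACPResult({"dom": 60.0}),
            _single_norms(60.0, sd=8.0),
            {"age": 70},
            self.ND_W,
            method="percentile",
        )
        assert cs["dom"] == pytest.approx(50.0)
        above = compute_cs(
            ACPResult({"dom": 70.0}),
            _single_norms(60.0, sd=8.0),
            {"age": 70},
            self.ND_W,
            method="percentile",
        )
        assert above["dom"] > 50.0


class TestSimpleProfile:
    def test_moca_ceiling_maps_to_10(self):
        scores = NPAScoreSet("p", {("MoCA", "total"): 30.0})
        values, absent = compute_simple_profile(scores, default_simple_scheme())
        assert values["general_cognition"] == pytest.approx(10.0)

    def test_all_minima_floor_at_zero(self):
        scheme = default_simple_scheme()
        scores = {}
        for subdomains in scheme.domains.values():
            for entries in subdomains.values():
                for e in entries:
                    scores[(e.instrument, e.subscore)] = e.min
        values, absent = compute_simple_profile(NPAScoreSet("p", scores), scheme)
        assert not absent
        assert all(v == pytest.approx(0.0) for v in values.values())

    def test_memory_mean_of_subdomains(self):
        scores = NPAScoreSet(
            "p",
            {
                ("FCSRT", "immediate_memory"): 24.0,  # /48 -> 5.0
                ("ROCFT", "recall_3min"): 18.0,  # /36 -> 5.0
                ("FCSRT", "delayed_recall"): 8.0,  # /16 -> 5.0
            },
        )
        values, _ = compute_simple_profile(scores, default_simple_scheme())
        assert values["memory"] == pytest.approx(5.0)

    def test_unscored_macro_domain_reported_absent(self):
        scores = NPAScoreSet("p", {("MoCA", "total"): 20.0})
        values, absent = compute_simple_profile(scores, default_simple_scheme())
        assert "memory" in absent and "general_cognition" in values
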