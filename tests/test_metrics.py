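"""Reclassification tables, NRI components, IDI, slope and bootstrap."""

import numpy as np
import pytest

from riskreclass import ValidationError
from riskreclass.metrics import (
    MetricResult,
    ReclassTable,
    RiskPair,
    RiskPairs,
    bootstrap_ci,
    build_reclass_table,
    category_free_nri,
    count_reclassified,
    discrimination_slope,
    idi,
    nri_events,
    nri_nonevents,
    nri_overall,
    stratify,
)
from riskreclass.tables import printed_table


def random_pairs(rng, n=200, shift=0.05):
    old = rng.uniform(0.02, 0.9, n)
    new = np.clip(old + rng.normal(0, shift, n), 0.01, 0.99)
    event = rng.random(n) < old
    if event.all() or not event.any():
        event[:2] = [True, False]
    return RiskPairs(old, new, event)


class TestStratify:
    @pytest.mark.parametrize("risk,threshold,expected", [
        (0.10, 0.10, "low"),    # boundary is inclusive on the low side
        (0.101, 0.10, "high"),
        (0.05, 0.20, "low"),
    ])
    def test_boundary_convention(self, risk, threshold, expected):
        assert stratify(risk, threshold) == expected

    def test_rejects_degenerate_probabilities(self):
        with pytest.raises(ValidationError):
            stratify(0.0, 0.1)


class TestReclassTable:
    def test_hand_enumeration(self):
        pairs = RiskPairs.from_pairs([
            RiskPair(0.05, 0.15, True),
            RiskPair(0.15, 0.05, False),
        ])
        table = build_reclass_table(pairs, 0.10)
        assert table.events[0, 1] == 1  # the event moved up
        assert table.nonevents[1, 0] == 1  # the nonevent moved down
        assert table.n_events == 1 and table.n_nonevents == 1

    def test_identity_risks_have_empty_off_diagonals(self, rng):
        old = rng.uniform(0.05, 0.5, 50)
        pairs = RiskPairs(old, old, rng.random(50) < 0.3)
        table = build_reclass_table(pairs, 0.2)
        assert table.events[0, 1] == table.events[1, 0] == 0
        assert table.nonevents[0, 1] == table.nonevents[1, 0] == 0

    def test_cell_totals_conserve_n(self, rng):
        pairs = random_pairs(rng)
        table = build_reclass_table(pairs, 0.15)
        assert table.n_events + table.n_nonevents == len(pairs)

    def test_json_round_trip(self):
        table = printed_table("high_sa_days", 0.10)
        assert ReclassTable.from_dict(table.to_dict()) == table

    def test_event_nonevent_relabelling_exchanges_tables(self, rng):
        pairs = random_pairs(rng)
        flipped = RiskPairs(pairs.old, pairs.new, ~pairs.event)
        a = build_reclass_table(pairs, 0.15)
        b = build_reclass_table(flipped, 0.15)
        assert np.array_equal(a.events, b.nonevents)
        assert np.array_equal(a.nonevents, b.events)


class TestNRIComponents:
    def test_published_days_table_at_10pct(self):
        table = printed_table("high_sa_days", 0.10)
        e, ne = nri_events(table), nri_nonevents(table)
        assert e.estimate_pct == pytest.approx(100 * 3 / 59)
        assert ne.estimate_pct == pytest.approx(100 * -25 / 520)
        assert e.movers_up == 7 and e.movers_down == 4

    def test_published_days_table_at_20pct(self):
        table = printed_table("high_sa_days", 0.20)
        assert nri_events(table).estimate_pct == pytest.approx(-1.69, abs=0.01)

    def test_no_movers_is_not_available_with_zero_retained(self):
        table = printed_table("high_sa_episodes", 0.10)
        e = nri_events(table)
        assert e.not_available
        assert e.estimate == 0.0
        assert e.se is None and e.ci is None and e.p_value is None

    def test_all_stayers_nonevents_zero(self):
        table = ReclassTable(0.1, [[5, 0], [0, 2]], [[7, 0], [0, 3]])
        assert nri_nonevents(table).not_available
        assert nri_nonevents(table).estimate == 0.0

    def test_overall_is_component_sum(self):
        table = printed_table("high_sa_days", 0.10)
        total = nri_overall(table)
        assert total.estimate == pytest.approx(
            nri_events(table).estimate + nri_nonevents(table).estimate
        )
        assert total.estimate_pct == pytest.approx(0.28, abs=0.01)
        assert total.se == pytest.approx(
            np.hypot(nri_events(table).se, nri_nonevents(table).se)
        )

    def test_overall_not_available_propagates(self):
        table = printed_table("high_sa_episodes", 0.20)
        assert nri_overall(table).not_available

    def test_symmetric_flows_cancel(self):
        table = ReclassTable(0.1, [[5, 3], [3, 5]], [[8, 2], [2, 8]])
        assert nri_events(table).estimate == 0.0
        assert nri_overall(table).estimate == 0.0

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            pairs = random_pairs(rng, n=30, shift=0.3)
            table = build_reclass_table(pairs, 0.3)
            for m in (nri_events(table), nri_nonevents(table)):
                assert -1.0 <= m.estimate <= 1.0


class TestCategoryFreeNRI:
    def test_hand_enumeration(self):
        pairs = RiskPairs.from_pairs([
            RiskPair(0.2, 0.3, True), RiskPair(0.6, 0.5, True),
            RiskPair(0.3, 0.2, False), RiskPair(0.4, 0.3, False),
        ])
        res = category_free_nri(pairs)
        assert res.events.estimate == pytest.approx(0.0)
        assert res.nonevents.estimate == pytest.approx(1.0)
        assert res.caveat

    def test_identical_risks_not_available(self, rng):
        old = rng.uniform(0.1, 0.5, 20)
        res = category_free_nri(RiskPairs(old, old, rng.random(20) < 0.5))
        assert res.events.not_available and res.nonevents.not_available
        assert res.overall.not_available

    def test_equals_categorical_when_no_threshold_crossings(self, rng):
        # risks all on one side of the threshold: categorical sees stayers only
        old = rng.uniform(0.02, 0.08, 40)
        new = np.clip(old + rng.normal(0, 0.005, 40), 0.01, 0.09)
        event = rng.random(40) < 0.3
        event[:2] = [True, False]
        pairs = RiskPairs(old, new, event)
        table = build_reclass_table(pairs, 0.10)
        assert nri_events(table).not_available
        assert nri_nonevents(table).not_available
        res = category_free_nri(pairs)
        assert not res.events.not_available  # continuous variant still moves


class TestSlopeAndIDI:
    def test_slope_hand_arithmetic(self):
        assert discrimination_slope([0.6, 0.2, 0.3], [True, False, False]) == \
            pytest.approx(0.35)

    def test_constant_risks_zero_slope(self):
        assert discrimination_slope([0.4] * 6, [True] * 3 + [False] * 3) == 0.0

    def test_near_perfect_separation(self):
        eps = 1e-3
        risks = [1 - eps] * 4 + [eps] * 4
        events = [True] * 4 + [False] * 4
        assert discrimination_slope(risks, events) == pytest.approx(1 - 2 * eps)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            discrimination_slope([0.5, 0.6], [True, True])

    def test_idi_hand_arithmetic(self):
        pairs = RiskPairs.from_pairs([
            RiskPair(0.6, 0.7, True),
            RiskPair(0.2, 0.2, False), RiskPair(0.3, 0.2, False),
        ])
        assert idi(pairs).estimate == pytest.approx(0.15)

    def test_idi_zero_when_models_agree(self, rng):
        old = rng.uniform(0.1, 0.6, 30)
        event = rng.random(30) < 0.4
        event[:2] = [True, False]
        assert idi(RiskPairs(old, old, event)).estimate == 0.0

    def test_idi_equals_slope_difference_and_stratum_sum(self, rng):
        pairs = random_pairs(rng)
        res = idi(pairs)
        slope_new = discrimination_slope(pairs.new, pairs.event)
        slope_old = discrimination_slope(pairs.old, pairs.event)
        assert res.estimate == pytest.approx(slope_new - slope_old, abs=1e-12)
        diff = pairs.new - pairs.old
        stratum_sum = diff[pairs.event].mean() + (-diff[~pairs.event]).mean()
        assert res.estimate == pytest.approx(stratum_sum, abs=1e-12)


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        pairs = random_pairs(rng)
        a = bootstrap_ci(pairs, "idi", replicates=200, seed=42)
        b = bootstrap_ci(pairs, "idi", replicates=200, seed=42)
        assert a.ci == b.ci

    def test_degenerate_identical_pairs_zero_width(self):
        pairs = RiskPairs([0.3] * 10, [0.3] * 10, [True] * 5 + [False] * 5)
        res = bootstrap_ci(pairs, "idi", replicates=200, seed=1)
        assert res.ci == (0.0, 0.0)

    def test_mostly_unavailable_metric_flagged(self, rng):
        old = rng.uniform(0.2, 0.4, 20)
        pairs = RiskPairs(old, old, rng.random(20) < 0.5)
        res = bootstrap_ci(pairs, "nri_events", threshold=0.3,
                           replicates=100, seed=1)
        assert res.not_available

    def test_agrees_with_asymptotic_ci_at_large_n(self, rng):
        pairs = random_pairs(rng, n=5000, shift=0.05)
        for metric, threshold in (("idi", None), ("nri_nonevents", 0.3)):
            boot = bootstrap_ci(pairs, metric, threshold=threshold,
                                replicates=400, seed=7)
            if metric == "idi":
                asym = idi(pairs)
            else:
                asym = nri_nonevents(build_reclass_table(pairs, threshold))
            w_boot = boot.ci[1] - boot.ci[0]
            w_asym = asym.ci[1] - asym.ci[0]
            assert w_boot == pytest.approx(w_asym, rel=0.2)

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValidationError):
            bootstrap_ci(random_pairs(rng), "idi", replicates=10)


class TestCountReclassified:
    def test_published_counts(self):
        assert count_reclassified(printed_table("high_sa_days", 0.10))[0] == 84
        assert count_reclassified(printed_table("high_sa_episodes", 0.10))[0] == 7

    def test_identity_table(self):
        table = ReclassTable(0.1, [[5, 0], [0, 2]], [[7, 0], [0, 3]])
        assert count_reclassified(table) == (0, 0.0)
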