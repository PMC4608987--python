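"""Episode merging, register aggregation, outcome labelling and cohort I/O."""

import datetime as dt
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riskreclass import (
    Cohort,
    CohortFormatError,
    Episode,
    EpisodeRegister,
    ValidationError,
    aggregate_register,
    complete_cases,
    label_high_sa_days,
    label_high_sa_episodes,
    merge_episodes,
    read_cohort,
    read_register,
    write_cohort,
    write_register,
)
from riskreclass.simulate import default_params, generate_cohort


def day(k: int) -> dt.date:
    return dt.date(2007, 1, 1) + dt.timedelta(days=k - 1)


def ep(a: int, b: int, worker="w1") -> Episode:
    return Episode(day(a), day(b), worker)


YEAR = (day(1), day(365))


class TestMergeEpisodes:
    def test_short_gap_merges(self):
        # 19 worked days between episodes: below the 28-day rule, one episode
        merged = merge_episodes([ep(1, 10), ep(30, 35)])
        assert merged == [ep(1, 35)]

    def test_boundary_gap_of_exactly_28_stays_separate(self):
        # the rule is strictly "fewer than 28": a 28-day gap does not merge
        merged = merge_episodes([ep(1, 10), ep(39, 40)])
        assert len(merged) == 2

    def test_gap_of_27_merges(self):
        assert len(merge_episodes([ep(1, 10), ep(38, 40)])) == 1

    def test_single_episode_unchanged(self):
        assert merge_episodes([ep(5, 9)]) == [ep(5, 9)]

    def test_merging_is_transitive(self):
        merged = merge_episodes([ep(1, 2), ep(10, 11), ep(20, 21)])
        assert merged == [ep(1, 21)]

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            merge_episodes([ep(1, 10), ep(10, 12)])

    def test_end_before_start_rejected(self):
        with pytest.raises(ValidationError):
            Episode(day(5), day(4))

    @given(
        st.lists(
            st.tuples(st.integers(1, 330), st.integers(0, 20)),
            min_size=1, max_size=8,
        ),
        st.integers(0, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_separated(self, raw, gap):
        """Merged output is a fixed point and pairwise >= gap apart."""
        episodes, last_end = [], 0
        for start, length in sorted(raw):
            start = max(start, last_end + 2)
            end = start + length
            if end > 365:
                continue
            episodes.append(ep(start, end))
            last_end = end
        if not episodes:
            return
        merged = merge_episodes(episodes, gap)
        assert merge_episodes(merged, gap) == merged
        for a, b in zip(merged, merged[1:]):
            assert (b.start - a.end).days - 1 >= gap


class TestAggregateRegister:
    def test_merged_pair_counts_constituent_days_only(self):
        reg = EpisodeRegister((ep(1, 10), ep(30, 35)), YEAR)
        assert aggregate_register(reg, 28) == {"w1": (16, 1)}

    def test_unmerged_pair(self):
        reg = EpisodeRegister((ep(1, 10), ep(39, 40)), YEAR)
        assert aggregate_register(reg, 28) == {"w1": (12, 2)}

    def test_empty_register_means_zero(self):
        reg = EpisodeRegister((), YEAR)
        assert aggregate_register(reg, 28) == {}

    def test_zero_gap_preserves_raw_episode_count(self):
        reg = EpisodeRegister((ep(1, 3), ep(5, 6), ep(40, 41)), YEAR)
        _, n_eps = aggregate_register(reg, 0)["w1"]
        assert n_eps == 3

    def test_day_total_invariant_under_merging(self):
        reg = EpisodeRegister((ep(1, 3), ep(5, 6), ep(40, 41)), YEAR)
        for gap in (0, 5, 28, 100):
            days, _ = aggregate_register(reg, gap)["w1"]
            assert days == 3 + 2 + 2

    def test_window_clipping(self):
        window = (day(10), day(20))
        reg = EpisodeRegister((ep(5, 12), ep(18, 30)), window)
        days, n_eps = aggregate_register(reg, 0)["w1"]
        assert days == 3 + 3  # days 10-12 and 18-20
        assert n_eps == 2

    def test_episode_outside_period_rejected(self):
        with pytest.raises(ValidationError, match="period"):
            EpisodeRegister((ep(100, 120),), (day(1), day(50)))


class TestOutcomeLabels:
    @pytest.mark.parametrize("days,expected", [(30, True), (29, False), (0, False), (366, True)])
    def test_high_sa_days_threshold(self, days, expected):
        assert label_high_sa_days(days) is expected

    @pytest.mark.parametrize("eps,expected", [(3, True), (2, False), (0, False), (10, True)])
    def test_high_sa_episodes_threshold(self, eps, expected):
        assert label_high_sa_episodes(eps) is expected

    def test_labels_monotone(self):
        days_labels = [label_high_sa_days(d) for d in range(0, 60)]
        assert days_labels == sorted(days_labels)
        ep_labels = [label_high_sa_episodes(e) for e in range(0, 10)]
        assert ep_labels == sorted(ep_labels)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            label_high_sa_days(-1)


class TestCohortIO:
    def test_read_small_csv(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "worker_id,age,gender,work_hours,srh,prior_sa_days,"
            "prior_sa_episodes,fatigue,fu_sa_days,fu_sa_episodes\n"
            "a,44.5,M,36,3,10,1,55,0,0\n"
            "b,39.0,F,32,2,0,0,80,31,1\n"
            "c,51.2,M,40,4,5,2,20,12,3\n"
        )
        cohort = read_cohort(p)
        assert len(cohort) == 3
        rec = cohort.records()[1]
        assert rec.fatigue == 80 and rec.fu_sa_days == 31 and rec.gender == "F"

    def test_out_of_range_srh_becomes_missing_with_warning(self, tmp_path, caplog):
        p = tmp_path / "c.csv"
        p.write_text(
            "worker_id,age,gender,work_hours,srh,prior_sa_days,"
            "prior_sa_episodes,fatigue,fu_sa_days,fu_sa_episodes\n"
            "a,44,M,36,5,10,1,55,0,0\n"
        )
        with caplog.at_level(logging.WARNING):
            cohort = read_cohort(p)
        assert len(cohort) == 1
        assert cohort.records()[0].srh is None
        assert any("out-of-range" in r.message for r in caplog.records)

    def test_unparseable_cell_becomes_missing_row_count_preserved(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "worker_id,age,gender,work_hours,srh,prior_sa_days,"
            "prior_sa_episodes,fatigue,fu_sa_days,fu_sa_episodes\n"
            "a,forty,M,36,3,10,1,55,0,0\n"
        )
        cohort = read_cohort(p)
        assert len(cohort) == 1 and cohort.records()[0].age is None

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("worker_id,age\na,44\n")
        with pytest.raises(CohortFormatError, match="fatigue"):
            read_cohort(p)

    def test_duplicate_worker_id_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        header = ",".join(
            ["worker_id", "age", "gender", "work_hours", "srh", "prior_sa_days",
             "prior_sa_episodes", "fatigue", "fu_sa_days", "fu_sa_episodes"])
        p.write_text(f"{header}\na,44,M,36,3,0,0,55,0,0\na,45,F,32,2,0,0,60,0,0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_cohort(p)

    def test_write_read_round_trip_on_synthetic_cohort(self, tmp_path):
        cohort = generate_cohort(default_params(n=40, seed=3, missing_rate=0.1))
        p = tmp_path / "c.csv"
        write_cohort(cohort, p)
        back = read_cohort(p)
        pd.testing.assert_frame_equal(
            back.frame, cohort.frame, check_exact=False, rtol=1e-12
        )

    def test_register_round_trip(self, tmp_path):
        reg = EpisodeRegister((ep(1, 10, "a"), ep(50, 60, "b")), YEAR)
        p = tmp_path / "r.csv"
        write_register(reg, p)
        back = read_register(p, period=YEAR)
        assert sorted(back.episodes) == sorted(reg.episodes)


class TestCompleteCases:
    def test_planted_missingness_is_removed(self):
        # emulates the study's participant flow: 633 questionnaires, 54 with
        # missing data, 579 analysed
        cohort = generate_cohort(
            default_params(n=633, seed=21, missing_rate=54 / 633)
        )
        filtered = complete_cases(cohort)
        assert len(cohort) == 633
        assert len(filtered) == 579

    def test_no_missing_is_identity(self):
        cohort = generate_cohort(default_params(n=25, seed=4))
        assert complete_cases(cohort).equals(cohort)

    def test_all_missing_yields_empty(self, caplog):
        frame = pd.DataFrame({
            "worker_id": ["a", "b"], "age": [np.nan, np.nan], "gender": ["M", "F"],
            "work_hours": [36.0, 32.0], "srh": [pd.NA, pd.NA],
            "prior_sa_days": [0, 0], "prior_sa_episodes": [0, 0],
            "fatigue": [55, 60], "fu_sa_days": [0, 0], "fu_sa_episodes": [0, 0],
        })
        cohort = Cohort(frame)
        with caplog.at_level(logging.WARNING):
            out = complete_cases(cohort, ["age"])
        assert len(out) == 0
        assert any("every record" in r.message for r in caplog.records)
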