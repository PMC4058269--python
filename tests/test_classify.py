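"""Phenotyping: inclusion filter, slope fit vs oracle, median split."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdtask.classify import (
    GAMBLER,
    NON_GAMBLER,
    SubjectProfile,
    classify_cohort,
    include_subject,
    median_split,
    preference_odds_slope,
    read_profiles,
    write_profiles,
)
from pdtask.cohort import demo_cohort, simulate_cohort
from pdtask.metrics import cohort_metrics


def ols_slope_oracle(x, y):
    """Independent normal-equations slope: (n Σxy − Σx Σy) / (n Σx² − (Σx)²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    return (n * np.sum(x * y) - np.sum(x) * np.sum(y)) / (
        n * np.sum(x * x) - np.sum(x) ** 2
    )


def metrics_row(subject="s1", species="rat", session=1, p_set=0.5, pref=80.0,
                odds=1.0, n_trials=50):
    return dict(
        subject_id=subject, species=species, session_index=session, p_set=p_set,
        n_trials=n_trials, pref_LLL=pref, trials_per_min=2.0, pellets_per_min=3.0,
        persistence=0.5, restlessness=0.5,
        experienced_p=None if odds is None else 100.0 / (odds + 1.0),
        experienced_odds=odds,
    )


def subject_frame(prefs_by_session, subject="s1", species="rat"):
    """Build a metrics frame from {session: (p_set, pref, odds)}."""
    return pd.DataFrame(
        [
            metrics_row(subject=subject, species=species, session=s, p_set=p,
                        pref=pref, odds=odds)
            for s, (p, pref, odds) in prefs_by_session.items()
        ]
    )


class TestInclusion:
    def make(self, pref_100, pref_50):
        return subject_frame({1: (1.0, pref_100, 0.0), 2: (0.5, pref_50, 1.0)})

    @pytest.mark.parametrize(
        "pref_100, pref_50, expected",
        [
            (85.0, 85.0, True),
            (60.0, 60.0, False),  # boundary: strictly more than 60% required
            (61.0, 61.0, True),
            (100.0, 20.0, False),  # mean 60 exactly
            (100.0, 22.0, True),  # mean 61
        ],
    )
    def test_threshold_is_strict_on_the_mean(self, rat_protocol, pref_100, pref_50,
                                             expected):
        included, reason = include_subject(self.make(pref_100, pref_50), rat_protocol)
        assert included is expected
        assert (reason == "") is expected

    def test_replicate_sessions_all_enter_the_mean(self, marmoset_protocol):
        # marmoset: three sessions per level; mean over all six inclusion sessions
        rows = {s: (1.0, v, 0.0) for s, v in zip((1, 2, 3), (90.0, 80.0, 70.0))}
        rows.update({s: (0.5, v, 1.0) for s, v in zip((4, 5, 6), (50.0, 40.0, 36.0))})
        df = subject_frame(rows, species="marmoset")
        included, reason = include_subject(df, marmoset_protocol)
        assert included  # mean = 61
        rows[6] = (0.5, 30.0, 1.0)
        included, _ = include_subject(subject_frame(rows, species="marmoset"),
                                      marmoset_protocol)
        assert not included  # mean = 60

    def test_missing_inclusion_level_errors(self, rat_protocol):
        df = subject_frame({1: (1.0, 90.0, 0.0)})
        with pytest.raises(ValueError, match="0.5"):
            include_subject(df, rat_protocol)


class TestPreferenceOddsSlope:
    def test_known_three_point_fit(self):
        # x = log10(odds+1) at odds 0, ~1, ~3; slope ~ -99.7 by normal equations
        df = subject_frame({
            1: (1.0, 100.0, 0.0),
            2: (0.5, 70.0, 10 ** 0.301 - 1.0),
            3: (0.25, 40.0, 10 ** 0.602 - 1.0),
        })
        slope, n = preference_odds_slope(df)
        assert n == 3
        assert slope == pytest.approx(-99.67, abs=0.05)
        assert slope == pytest.approx(
            ols_slope_oracle([0.0, 0.301, 0.602], [100.0, 70.0, 40.0]), abs=1e-9
        )

    def test_flat_preference_zero_slope(self):
        df = subject_frame({s: (p, 75.0, o) for s, (p, o) in
                            enumerate([(1.0, 0.0), (0.5, 1.0), (0.25, 3.0)], 1)})
        slope, _ = preference_odds_slope(df)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_two_points_exact_line(self):
        df = subject_frame({1: (1.0, 90.0, 0.0), 2: (0.5, 60.0, 1.0)})
        slope, n = preference_odds_slope(df)
        assert n == 2
        assert slope == pytest.approx((60.0 - 90.0) / math.log10(2.0), abs=1e-9)

    def test_missing_odds_rows_excluded(self):
        df = subject_frame({1: (1.0, 90.0, 0.0), 2: (0.5, 60.0, 1.0),
                            3: (0.25, 0.0, None)})
        df.loc[df["session_index"] == 3, "experienced_odds"] = np.nan
        slope, n = preference_odds_slope(df)
        assert n == 2

    def test_fewer_than_two_points_names_subject(self):
        df = subject_frame({1: (1.0, 90.0, 0.0)}, subject="lonely")
        with pytest.raises(ValueError, match="lonely"):
            preference_odds_slope(df)

    def test_training_sessions_ignored(self):
        df = subject_frame({0: (1.0, 10.0, 0.0), 1: (1.0, 90.0, 0.0),
                            2: (0.5, 60.0, 1.0)})
        slope_all, n_all = preference_odds_slope(df, min_session_index=0)
        slope, n = preference_odds_slope(df, min_session_index=1)
        assert n == 2 and n_all == 3
        assert slope != slope_all

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=1.0),
                st.floats(min_value=0.0, max_value=100.0),
            ),
            min_size=3,
            max_size=10,
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_normal_equations_oracle(self, points):
        xs = [x for x, _ in points]
        ys = [y for _, y in points]
        if np.ptp(xs) < 1e-3:
            return
        df = pd.DataFrame(
            [
                metrics_row(session=i + 1, p_set=0.5, pref=y, odds=10 ** x - 1.0)
                for i, (x, y) in enumerate(points)
            ]
        )
        slope, _ = preference_odds_slope(df)
        assert slope == pytest.approx(ols_slope_oracle(xs, ys), abs=1e-6, rel=1e-6)


def profile(subject, slope, species="rat", included=True):
    return SubjectProfile(
        subject_id=subject, species=species, included=included,
        slope=slope if included else None, n_fit_points=7 if included else 0,
        exclusion_reason="" if included else "failed filter",
    )


class TestMedianSplit:
    def test_even_n_clean_split(self):
        profiles = [profile(f"s{i}", s) for i, s in enumerate([-5, -10, -60, -80])]
        labeled = median_split(profiles)
        by_slope = {p.slope: p.strategy for p in labeled}
        assert by_slope == {-5: GAMBLER, -10: GAMBLER, -60: NON_GAMBLER,
                            -80: NON_GAMBLER}

    def test_median_subject_assigned_to_nearer_group_mean(self):
        # median -40: distance to gambler mean (-5) is 35, to non-gambler (-80) is 40
        labeled = median_split([profile("a", -5.0), profile("b", -40.0),
                                profile("c", -80.0)])
        assert {p.subject_id: p.strategy for p in labeled} == {
            "a": GAMBLER, "b": GAMBLER, "c": NON_GAMBLER
        }

    def test_tie_rules_can_disagree(self):
        # median subject -40: nearest group mean is the shallow side (22.5 vs 32)
        # but its nearest individual slope is on the steep side (4 vs 10)
        profiles = [profile(s_id, s) for s_id, s in
                    [("a", -5.0), ("b", -30.0), ("m", -40.0), ("c", -44.0),
                     ("d", -100.0)]]
        by_mean = {p.subject_id: p.strategy for p in median_split(profiles)}
        by_nn = {p.subject_id: p.strategy
                 for p in median_split(profiles, tie_rule="nearest-neighbor")}
        assert by_mean["m"] == GAMBLER
        assert by_nn["m"] == NON_GAMBLER
        del by_mean["m"], by_nn["m"]
        assert by_mean == by_nn  # only the median subject is rule-sensitive

    def test_equidistant_median_subject_is_non_gambler(self):
        labeled = median_split([profile("a", -10.0), profile("b", -40.0),
                                profile("c", -70.0)])
        assert next(p.strategy for p in labeled if p.subject_id == "b") == NON_GAMBLER

    def test_all_equal_slopes_error(self):
        with pytest.raises(ValueError, match="separable"):
            median_split([profile("a", -30.0), profile("b", -30.0)])

    def test_split_is_within_species(self):
        profiles = [
            profile("r1", -5.0), profile("r2", -80.0),
            profile("m1", -20.0, species="marmoset"),
            profile("m2", -60.0, species="marmoset"),
        ]
        labeled = {p.subject_id: p.strategy for p in median_split(profiles)}
        assert labeled == {"r1": GAMBLER, "r2": NON_GAMBLER,
                           "m1": GAMBLER, "m2": NON_GAMBLER}

    def test_pooled_split_differs(self):
        profiles = [
            profile("r1", -50.0), profile("r2", -80.0),
            profile("m1", -5.0, species="marmoset"),
            profile("m2", -20.0, species="marmoset"),
        ]
        pooled = {p.subject_id: p.strategy for p in median_split(profiles, pooled=True)}
        assert pooled == {"r1": NON_GAMBLER, "r2": NON_GAMBLER,
                          "m1": GAMBLER, "m2": GAMBLER}

    def test_excluded_subjects_pass_through_unlabeled(self):
        profiles = [profile("a", -5.0), profile("b", -80.0),
                    profile("x", None, included=False)]
        labeled = median_split(profiles)
        assert next(p for p in labeled if p.subject_id == "x").strategy is None

    def test_single_included_subject_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            median_split([profile("a", -5.0)])

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_log_base_invariance_of_labels(self, data):
        slopes = data.draw(
            st.lists(
                st.floats(min_value=-100.0, max_value=0.0),
                min_size=4, max_size=12, unique=True,
            )
        )
        scale = data.draw(st.floats(min_value=0.01, max_value=100.0))
        base = [profile(f"s{i}", s) for i, s in enumerate(slopes)]
        rescaled = [profile(f"s{i}", s * scale) for i, s in enumerate(slopes)]
        labels_a = [p.strategy for p in median_split(base)]
        labels_b = [p.strategy for p in median_split(rescaled)]
        assert labels_a == labels_b


class TestClassifyCohort:
    def test_recovers_two_temperaments(self, small_rat_log, rat_protocol):
        metrics = cohort_metrics(small_rat_log, rat_protocol)
        profiles = classify_cohort(metrics, rat_protocol)
        labels = {p.subject_id: p.strategy for p in profiles}
        assert labels == {"rat_g01": GAMBLER, "rat_g02": GAMBLER,
                          "rat_n01": NON_GAMBLER, "rat_n02": NON_GAMBLER}
        assert all(p.included and p.n_fit_points >= 2 for p in profiles)

    def test_failing_subject_excluded_and_unlabeled(self, rat_protocol):
        frames = [
            subject_frame(
                {s: (p, pref, o) for s, (p, pref, o) in enumerate(
                    [(1.0, 95.0, 0.0), (0.5, 85.0, 1.0), (0.33, 70.0, 2.0),
                     (0.25, base, 3.0)], 1)},
                subject=name,
            )
            for name, base in [("good1", 60.0), ("good2", 20.0)]
        ]
        frames.append(
            subject_frame(
                {1: (1.0, 50.0, 0.0), 2: (0.5, 50.0, 1.0), 3: (0.33, 50.0, 2.0)},
                subject="weak",
            )
        )
        metrics = pd.concat(frames, ignore_index=True)
        profiles = classify_cohort(metrics, rat_protocol)
        weak = next(p for p in profiles if p.subject_id == "weak")
        assert not weak.included and weak.strategy is None
        assert "not above" in weak.exclusion_reason

    def test_determinism(self, small_rat_log, rat_protocol):
        metrics = cohort_metrics(small_rat_log, rat_protocol)
        assert classify_cohort(metrics, rat_protocol) == classify_cohort(
            metrics, rat_protocol
        )

    def test_profiles_csv_round_trip(self, small_rat_log, rat_protocol, tmp_path):
        metrics = cohort_metrics(small_rat_log, rat_protocol)
        profiles = classify_cohort(metrics, rat_protocol)
        path = tmp_path / "profiles.csv"
        write_profiles(profiles, path)
        assert read_profiles(path) == profiles
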