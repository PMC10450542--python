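import math
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from appmarker.event_model import AppCatalog, ObservationWindow, UsageInterval
from appmarker.markers import (
    APP_SCOPES,
    FEATURE_NAMES,
    FeatureMatrix,
    HammingIndex,
    enumerate_features,
    extract_features,
    hamming_distance,
    hamming_ratio,
    sparsity_filter,
    standardize,
    usage_entropy,
)
from appmarker.sessions import segment

T0 = datetime(2020, 8, 3)  # Monday
WINDOW = ObservationWindow(start=T0)


class TestEnumeration:
    def test_grid_has_864_names(self):
        specs = enumerate_features()
        assert len(specs) == 864
        assert len({s.name for s in specs}) == 864

    def test_grid_arithmetic(self):
        # 28 scopes x 2 days x 5 measures x 3 characteristics + 2 x 4 x 3
        assert 28 * 2 * 5 * 3 + 2 * 4 * 3 == 864

    def test_paper_style_name_present(self):
        assert "Weekday_Communication_Ratio_of_Hamming_6_Hour_Mean" in FEATURE_NAMES
        assert "Weekend_Photo_and_Video_Number_of_Apps_6_Hour_SD" in FEATURE_NAMES
        assert "Weekday_Session_Microsession_Total" in FEATURE_NAMES

    def test_28_app_scopes(self):
        assert len(APP_SCOPES) == 28 and "Smartphone" in APP_SCOPES


class TestEntropy:
    def test_single_app_zero(self):
        assert usage_entropy([123.4]) == 0.0

    def test_empty_scope_zero(self):
        assert usage_entropy([]) == 0.0
        assert usage_entropy([0.0, 0.0]) == 0.0

    def test_two_equal_apps_ln2(self):
        assert usage_entropy([5.0, 5.0]) == pytest.approx(math.log(2))

    def test_211_oracle(self):
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert usage_entropy([2.0, 1.0, 1.0]) == pytest.approx(expected)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_configurable_base(self):
        assert usage_entropy([1, 1], base=2) == pytest.approx(1.0)

    @given(st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=1, max_size=12))
    @settings(max_examples=100)
    def test_uniform_maximizes_and_permutation_invariant(self, durations):
        e = usage_entropy(durations)
        assert e == pytest.approx(usage_entropy(list(reversed(durations))))
        assert e <= usage_entropy([1.0] * len(durations)) + 1e-9
        assert e >= 0.0


class TestHammingRatio:
    def test_closer_to_depressed(self):
        assert hamming_ratio(
            frozenset("ab"), [frozenset("ab")], [frozenset("a")]
        ) == 0.0

    def test_identical_in_both_groups(self):
        assert hamming_ratio(
            frozenset("ab"), [frozenset("ab")], [frozenset("ab")]
        ) == 1.0

    def test_smoothed_x_over_zero(self):
        # D=3, ND=0 -> D+1 = 4.0
        assert hamming_ratio(
            frozenset("a"), [frozenset("bc")], [frozenset("a")]
        ) == 4.0

    def test_empty_pool_undefined(self):
        assert hamming_ratio(frozenset("a"), [], [frozenset("a")]) is None

    def test_distance_is_symmetric_difference(self):
        assert hamming_distance(frozenset("abc"), frozenset("bcd")) == 2

    @given(st.data())
    @settings(max_examples=300, deadline=None)
    def test_index_matches_bruteforce(self, data):
        """HammingIndex (bitmask path) vs the scalar set-based oracle."""
        universe = ["a", "b", "c", "d", "e", "f"]
        n = data.draw(st.integers(min_value=2, max_value=8))
        pids = [f"p{i}" for i in range(n)]
        labels = {p: data.draw(st.integers(0, 1)) for p in pids}
        labels[pids[0]], labels[pids[-1]] = 1, 0  # one member in each group
        sets = {}
        for slot in ("night", "morning", "afternoon", "evening", "total"):
            sets[("Games", "weekday", slot)] = {
                p: frozenset(
                    data.draw(st.sets(st.sampled_from(universe), max_size=6))
                )
                for p in pids
            }
        index = HammingIndex(sets, pids)
        cols = index.ratio_columns(labels)
        for p in pids:
            dep = [sets[("Games", "weekday", "total")][q] for q in pids
                   if q != p and labels[q] == 1]
            nd = [sets[("Games", "weekday", "total")][q] for q in pids
                  if q != p and labels[q] == 0]
            expected = hamming_ratio(sets[("Games", "weekday", "total")][p], dep, nd)
            got = cols.loc[p, "Weekday_Games_Ratio_of_Hamming_Total"]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)
            period_ratios = []
            for slot in ("night", "morning", "afternoon", "evening"):
                dep_s = [sets[("Games", "weekday", slot)][q] for q in pids
                        if q != p and labels[q] == 1]
                nds = [sets[("Games", "weekday", slot)][q] for q in pids
                       if q != p and labels[q] == 0]
                period_ratios.append(
                    hamming_ratio(sets[("Games", "weekday", slot)][p], dep_s, nds)
                )
            if all(r is not None for r in period_ratios):
                assert cols.loc[p, "Weekday_Games_Ratio_of_Hamming_6_Hour_Mean"] == (
                    pytest.approx(float(np.mean(period_ratios)))
                )


def toy_cohort():
    """One participant, 3 Games intervals, hand-computable."""
    ivs = [
        UsageInterval("p1", "A", T0.replace(hour=10), T0.replace(hour=10, minute=30),
                      category="Games"),
        UsageInterval("p1", "B", T0.replace(hour=13), T0.replace(hour=13, minute=20),
                      category="Games"),
        UsageInterval("p1", "A",
                      T0 + timedelta(days=1, hours=11, minutes=50),
                      T0 + timedelta(days=1, hours=12, minutes=10),
                      category="Games"),
    ]
    # a second participant so hamming pools exist
    ivs2 = [
        UsageInterval("p2", "A", T0.replace(hour=9), T0.replace(hour=9, minute=10),
                      category="Games"),
    ]
    intervals = {"p1": ivs, "p2": ivs2}
    sessions = {pid: segment(v) for pid, v in intervals.items()}
    labels = {"p1": 1, "p2": 0}
    return intervals, sessions, labels


class TestExtract:
    def test_toy_cohort_hand_computed_cells(self):
        intervals, sessions, labels = toy_cohort()
        fm, _ = extract_features(intervals, sessions, labels, WINDOW)
        row = fm.df.loc["p1"]
        assert row["Weekday_Games_Duration_Total"] == 4200.0
        assert row["Weekday_Games_Duration_6_Hour_Mean"] == 1050.0
        assert row["Weekday_Games_Duration_6_Hour_SD"] == pytest.approx(
            math.sqrt(1147500.0)
        )
        assert row["Weekday_Games_Launch_Total"] == 3.0
        assert row["Weekday_Games_Launch_6_Hour_Mean"] == 0.75
        assert row["Weekday_Games_Number_of_Apps_Total"] == 2.0
        # per-period app counts [0, 1, 2, 0]
        assert row["Weekday_Games_Number_of_Apps_6_Hour_Mean"] == 0.75
        expected_e = -(3000 / 4200 * math.log(3000 / 4200)
                       + 1200 / 4200 * math.log(1200 / 4200))
        assert row["Weekday_Games_Entropy_Total"] == pytest.approx(expected_e)
        # smartphone scope mirrors Games here (only category used)
        assert row["Weekday_Smartphone_Duration_Total"] == 4200.0
        assert row["Weekend_Games_Duration_Total"] == 0.0
        # sessions: three engage sessions, starts in morning x2 + afternoon
        assert row["Weekday_Session_Number_of_Sessions_Total"] == 3.0
        assert row["Weekday_Session_Engage_Session_Total"] == 3.0
        assert row["Weekday_Session_Microsession_Total"] == 0.0
        assert row["Weekday_Session_Number_of_Sessions_6_Hour_Mean"] == 0.75

    def test_exactly_864_columns(self):
        intervals, sessions, labels = toy_cohort()
        fm, _ = extract_features(intervals, sessions, labels, WINDOW)
        assert fm.df.shape == (2, 864)

    def test_zero_event_participant_all_zero_counts(self):
        intervals, sessions, labels = toy_cohort()
        intervals["p3"] = []
        sessions["p3"] = []
        labels["p3"] = 0
        fm, _ = extract_features(intervals, sessions, labels, WINDOW)
        row = fm.df.loc["p3"]
        for name in FEATURE_NAMES:
            if any(m in name for m in ("Duration", "Launch", "Number_of_Apps",
                                       "Session", "Entropy")):
                assert row[name] == 0.0, name

    def test_duration_conservation_under_splitting(self, small_matrix):
        fm, _, _ = small_matrix
        # Total equals 4 x 6-hour mean (mean over exactly the 4 periods)
        for scope in ("Smartphone", "Communication"):
            for day in ("Weekday", "Weekend"):
                total = fm.df[f"{day}_{scope}_Duration_Total"]
                mean = fm.df[f"{day}_{scope}_Duration_6_Hour_Mean"]
                assert np.allclose(total, 4 * mean)

    def test_missing_category_raises(self):
        ivs = {"p1": [UsageInterval("p1", "A", T0, T0 + timedelta(minutes=1))],
               "p2": []}
        with pytest.raises(ValueError, match="category"):
            extract_features(ivs, {"p1": [], "p2": []}, {"p1": 1, "p2": 0}, WINDOW)


def _matrix_with_frac(frac_games: float) -> FeatureMatrix:
    cols = [
        "Weekday_Games_Duration_Total",
        "Weekday_Tools_Duration_Total",
        "Weekday_Smartphone_Duration_Total",
        "Weekday_Session_Microsession_Total",
    ]
    df = pd.DataFrame(np.ones((4, len(cols))), columns=cols,
                      index=[f"p{i}" for i in range(4)])
    frac = pd.Series({"Games": frac_games, "Tools": 1.0})
    return FeatureMatrix(df=df, user_frac=frac)


class TestSparsityFilter:
    def test_category_below_half_dropped(self):
        out = sparsity_filter(_matrix_with_frac(0.49))
        assert "Weekday_Games_Duration_Total" not in out.df.columns
        assert "Weekday_Tools_Duration_Total" in out.df.columns

    def test_exactly_half_retained(self):
        out = sparsity_filter(_matrix_with_frac(0.50))
        assert "Weekday_Games_Duration_Total" in out.df.columns

    def test_smartphone_and_session_always_kept(self):
        out = sparsity_filter(_matrix_with_frac(0.0))
        assert "Weekday_Smartphone_Duration_Total" in out.df.columns
        assert "Weekday_Session_Microsession_Total" in out.df.columns

    def test_all_used_unchanged(self):
        m = _matrix_with_frac(1.0)
        out = sparsity_filter(m)
        assert list(out.df.columns) == list(m.df.columns)


class TestStandardize:
    def test_train_scaled_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 3, size=(30, 4)), columns=list("abcd"))
        scaled, _ = standardize(df)
        assert np.allclose(scaled.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(scaled.std(axis=0, ddof=0), 1.0)

    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"a": [3.0, 3.0, 3.0], "b": [1.0, 2.0, 3.0]})
        scaled, _ = standardize(df)
        assert (scaled["a"] == 0.0).all()

    def test_heldout_row_uses_train_stats(self):
        train = pd.DataFrame({"a": [0.0, 2.0]})  # mean 1, sd 1
        test = pd.DataFrame({"a": [5.0]})
        _, scaled = standardize(train, test)
        assert scaled["a"].iloc[0] == pytest.approx(4.0)

    def test_nan_zero_imputed_after_scaling(self):
        train = pd.DataFrame({"a": [0.0, 2.0, np.nan]})
        scaled, _ = standardize(train)
        assert scaled["a"].iloc[2] == 0.0


def test_matrix_csv_round_trip(tmp_path, small_matrix):
    fm, _, _ = small_matrix
    path = tmp_path / "matrix.csv"
    fm.to_csv(path)
    back = FeatureMatrix.from_csv(path)
    assert list(back.df.columns) == list(fm.df.columns)
    assert np.allclose(back.df.to_numpy(), fm.df.to_numpy(), equal_nan=True)
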