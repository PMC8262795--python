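"""Trip-level and user-averaged summaries, frequency and extrapolation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import greentrack as gt

DAY = 86400.0


def record(device="u1", trip="0", duration_min=5.0, length=300.0, gs_len=250.0,
           speed=1.0, home=1000.0, n_flags=0, t_start=1.5e9, ids=("p1",),
           types=("local park",)):
    return {
        "device_id": device, "trip_id": trip, "t_start": t_start,
        "duration_s": duration_min * 60.0, "length_m": length,
        "length_in_greenspace_m": gs_len, "avg_speed_ms": speed,
        "home_dist_m": home, "n_flags": n_flags,
        "greenspace_ids_visited": ids, "greenspace_types_visited": types,
    }


def records_frame(rows):
    return pd.DataFrame(rows)


class TestSummariseTrips:
    def test_mean_and_median(self):
        recs = records_frame([record(duration_min=d, trip=str(i))
                              for i, d in enumerate([2.0, 4.0, 9.0])])
        tab = gt.summarise_trips(recs)
        dur = tab[tab["characteristic"] == "duration_min"].iloc[0]
        assert dur["mean"] == pytest.approx(5.0)
        assert dur["median"] == pytest.approx(4.0)
        assert dur["count"] == 3

    def test_max_flags_excludes_flagged_trips(self):
        recs = records_frame([record(duration_min=2.0), record(duration_min=100.0, n_flags=1)])
        tab0 = gt.summarise_trips(recs, max_flags=0)
        dur = tab0[tab0["characteristic"] == "duration_min"].iloc[0]
        assert dur["mean"] == pytest.approx(2.0)
        assert dur["count"] == 1

    def test_matches_two_pass_oracle_on_synthetic_records(self):
        rng = np.random.default_rng(10)
        rows = [record(device=f"u{i%7}", trip=str(i),
                       duration_min=float(rng.uniform(1, 60)),
                       length=float(rng.uniform(10, 2000)),
                       n_flags=int(rng.integers(0, 3)))
                for i in range(500)]
        recs = records_frame(rows)
        tab = gt.summarise_trips(recs, max_flags=1)
        sel = [r for r in rows if r["n_flags"] <= 1]
        durs = [r["duration_s"] / 60.0 for r in sel]
        row = tab[tab["characteristic"] == "duration_min"].iloc[0]
        assert row["mean"] == pytest.approx(sum(durs) / len(durs))
        assert row["sd"] == pytest.approx(np.std(durs, ddof=1))
        assert row["median"] == pytest.approx(float(np.median(durs)))
        assert row["count"] == len(sel)

    def test_empty_selection_count_zero(self):
        recs = records_frame([record(n_flags=3)])
        tab = gt.summarise_trips(recs, max_flags=0)
        assert (tab["count"] == 0).all()
        assert tab["mean"].isna().all()


class TestUserAverage:
    def test_users_weighted_equally(self):
        recs = records_frame([
            record("A", "0", duration_min=10.0), record("A", "1", duration_min=10.0),
            record("B", "0", duration_min=4.0),
        ])
        users = gt.user_average(recs)
        assert users["mean_duration_min"].mean() == pytest.approx(7.0)
        # trip-level mean differs: (10+10+4)/3 = 8
        assert gt.summarise_trips(recs).iloc[0]["mean"] == pytest.approx(8.0)

    def test_single_user_equals_trip_level(self):
        recs = records_frame([record("A", str(i), duration_min=float(d))
                              for i, d in enumerate([3, 5, 10])])
        users = gt.user_average(recs)
        assert users["mean_duration_min"].iloc[0] == pytest.approx(6.0)

    def test_matches_group_then_mean_oracle(self):
        rng = np.random.default_rng(3)
        rows = [record(device=f"u{rng.integers(0, 50)}", trip=str(i),
                       duration_min=float(rng.uniform(1, 30)))
                for i in range(400)]
        recs = records_frame(rows)
        users = gt.user_average(recs)
        oracle = (recs.assign(duration_min=recs["duration_s"] / 60)
                  .groupby("device_id")["duration_min"].mean())
        got = users.set_index("device_id")["mean_duration_min"]
        pd.testing.assert_series_equal(got, oracle, check_names=False)

    def test_equal_trip_counts_make_weightings_agree(self):
        rng = np.random.default_rng(8)
        rows = [record(device=f"u{i}", trip=str(j), duration_min=float(rng.uniform(1, 30)))
                for i in range(10) for j in range(4)]
        recs = records_frame(rows)
        user_mean = gt.user_average(recs)["mean_duration_min"].mean()
        trip_mean = gt.summarise_trips(recs).iloc[0]["mean"]
        assert user_mean == pytest.approx(trip_mean)


class TestVisitFrequency:
    def test_span_of_14_days(self):
        rows = [record("A", str(i), t_start=1.5e9 + i * DAY) for i in range(14)]
        # first and last trip dates 13 days apart -> period 14 days
        assert gt.visit_frequency(records_frame(rows), "A") == pytest.approx(1.0)

    def test_single_trip_is_one_per_day(self):
        rows = [record("A", "0")]
        assert gt.visit_frequency(records_frame(rows), "A") == pytest.approx(1.0)

    def test_matches_date_span_oracle(self):
        rng = np.random.default_rng(5)
        rows = [record("A", str(i), t_start=1.5e9 + float(rng.uniform(0, 30 * DAY)))
                for i in range(25)]
        recs = records_frame(rows)
        days = pd.to_datetime(recs["t_start"], unit="s", utc=True).dt.date
        span = (max(days) - min(days)).days + 1
        assert gt.visit_frequency(recs, "A") == pytest.approx(25 / span)

    def test_unknown_device_raises(self):
        with pytest.raises(KeyError):
            gt.visit_frequency(records_frame([record("A", "0")]), "nobody")


class TestExtrapolate:
    def test_weekly_is_seven_times_daily(self):
        rows = [record("A", str(i), t_start=1.5e9 + i * DAY) for i in range(10)]
        users = gt.extrapolate(gt.user_average(records_frame(rows)))
        assert users["weekly_duration_min"].iloc[0] == pytest.approx(
            7 * users["daily_duration_min"].iloc[0]
        )
        assert users["weekly_distance_m"].iloc[0] == pytest.approx(
            7 * users["daily_distance_m"].iloc[0]
        )

    def test_unit_frequency_scalar_example(self):
        tot = gt.extrapolate_totals(1.0, 10.0, 500.0)
        assert tot["weekly_duration_min"] == pytest.approx(70.0)
        assert tot["weekly_distance_m"] == pytest.approx(3500.0)

    def test_daily_equals_frequency_times_mean(self):
        tot = gt.extrapolate_totals(1.3, 8.0, 350.0)
        assert tot["daily_duration_min"] == pytest.approx(1.3 * 8.0)
        assert tot["daily_distance_m"] == pytest.approx(1.3 * 350.0)


class TestDestinationTypes:
    def test_multi_type_trip_counts_in_both(self, two_park_map):
        recs = records_frame([
            record("A", "0", ids=("p1", "p2"), types=("local park", "woodland")),
        ])
        counts = gt.destination_type_counts(recs, two_park_map)
        assert counts["local park"] == 1 and counts["woodland"] == 1
        assert sum(counts.values()) == 2  # column sums may exceed trip count

    def test_no_trips_all_zero(self, two_park_map):
        recs = records_frame([record()]).iloc[0:0]
        counts = gt.destination_type_counts(recs, two_park_map)
        assert all(v == 0 for v in counts.values())

    def test_per_user_counts_each_space_once(self, two_park_map):
        recs = records_frame([
            record("A", "0", ids=("p1",), types=("local park",)),
            record("A", "1", ids=("p1",), types=("local park",)),
            record("A", "2", ids=("p2",), types=("woodland",)),
            record("B", "0", ids=("p1",), types=("local park",)),
        ])
        per_trip = gt.destination_type_counts(recs, two_park_map)
        per_user = gt.destination_type_counts(recs, two_park_map, per_user=True)
        assert per_trip["local park"] == 3
        assert per_user["local park"] == 2  # A once + B once
        assert per_user["woodland"] == 1

    def test_tally_matches_oracle_on_synthetic_trips(self, two_park_map):
        rng = np.random.default_rng(30)
        choices = [(("p1",), ("local park",)), (("p2",), ("woodland",)),
                   (("p1", "p2"), ("local park", "woodland"))]
        rows = []
        for i in range(30):
            ids, types = choices[rng.integers(0, 3)]
            rows.append(record(f"u{i % 5}", str(i), ids=ids, types=types))
        recs = records_frame(rows)
        counts = gt.destination_type_counts(recs, two_park_map)
        oracle = {"local park": 0, "woodland": 0}
        for r in rows:
            for t in set(r["greenspace_types_visited"]):
                oracle[t] += 1
        assert counts["local park"] == oracle["local park"]
        assert counts["woodland"] == oracle["woodland"]

    def test_histogram_figure_has_one_axes_per_characteristic(self):
        from greentrack.summary import plot_characteristics

        recs = records_frame([record("A", str(i), duration_min=float(i + 1))
                              for i in range(10)])
        fig = plot_characteristics(recs)
        assert len(fig.axes) == 5

    def test_zero_flag_filter_never_increases_counts(self, two_park_map):
        rng = np.random.default_rng(12)
        rows = [record(f"u{i}", "0", n_flags=int(rng.integers(0, 2))) for i in range(20)]
        recs = records_frame(rows)
        all_counts = gt.destination_type_counts(recs, two_park_map)
        zero = gt.destination_type_counts(recs[recs["n_flags"] == 0], two_park_map)
        assert all(zero[k] <= all_counts[k] for k in all_counts)
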