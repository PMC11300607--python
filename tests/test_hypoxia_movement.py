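"""DO classification, censored transitions, logger matching, movement metrics."""

import numpy as np
import pandas as pd
import pytest

import riskdays as rd

from conftest import make_detections

RMAP = {"R2": "2 OH", "R3": "3 OH/PA", "R3N": "3 ON", "R1": "1 OH"}
DISTRICTS = {"2 OH": 2, "3 OH/PA": 3, "3 ON": 3, "1 OH": 1}


def do_table(rows):
    return pd.DataFrame(rows, columns=["date", "location_type", "location_id",
                                       "do_mg_l", "temp_c"])


def smu_do(value=8.0, dates=("2021-07-01", "2021-08-31")):
    days = pd.date_range(*dates, freq="D").date
    return do_table([(d, "smu", s, value, np.nan)
                     for d in days for s in RMAP.values()])


class TestClassifyDo:
    @pytest.mark.parametrize("do,expected", [
        (1.9, "hypoxic"),       # strictly below the 2 mg/L threshold
        (2.0, "normoxic"),      # boundary: strict inequality
        (8.0, "normoxic"),
        (0.0, "hypoxic"),
    ])
    def test_threshold(self, do, expected):
        assert rd.classify_do(do) == expected

    def test_missing_is_unknown(self):
        assert rd.classify_do(float("nan")) == "unknown"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, 200)
        low = rd.classify_do(vals, threshold=1.5)
        high = rd.classify_do(vals, threshold=4.0)
        # raising the threshold never converts hypoxic -> normoxic
        assert not ((low == "hypoxic") & (high == "normoxic")).any()


class TestExtractTransitions:
    def test_eastward_by_one_district(self):
        det = make_detections([("T0", "R2", "2021-07-01 00:00"),
                               ("T0", "R3", "2021-07-06 00:00")])
        det["is_valid"] = True
        tr = rd.extract_transitions(det, RMAP, DISTRICTS, smu_do())
        assert len(tr) == 1
        assert tr.iloc[0]["rank_diff"] == 1

    def test_latitudinal_move_coded_zero(self):
        det = make_detections([("T0", "R3N", "2021-07-01 00:00"),
                               ("T0", "R3", "2021-07-03 00:00")])
        tr = rd.extract_transitions(det, RMAP, DISTRICTS, smu_do())
        assert tr.iloc[0]["rank_diff"] == 0

    def test_long_gap_censored(self):
        det = make_detections([("T0", "R3", "2021-07-01 00:00"),
                               ("T0", "R1", "2021-07-26 00:00")])
        tr = rd.extract_transitions(det, RMAP, DISTRICTS, smu_do())
        assert tr.empty

    def test_censor_is_strict(self):
        det = make_detections([("T0", "R2", "2021-07-01 00:00"),
                               ("T0", "R3", "2021-07-22 00:00")])  # exactly 21 d
        tr = rd.extract_transitions(det, RMAP, DISTRICTS, smu_do())
        assert tr.empty

    def test_same_smu_receiver_change_not_a_transition(self):
        det = make_detections([("T0", "R3", "2021-07-01 00:00"),
                               ("T0", "R3", "2021-07-02 00:00")])
        tr = rd.extract_transitions(det, RMAP, DISTRICTS, smu_do())
        assert tr.empty

    def test_outside_stratified_window_ignored(self):
        det = make_detections([("T0", "R2", "2021-03-01 00:00"),
                               ("T0", "R3", "2021-03-05 00:00")])
        tr = rd.extract_transitions(det, RMAP, DISTRICTS, smu_do())
        assert tr.empty

    def test_initial_condition_from_origin_smu_do(self):
        do = smu_do(8.0)
        do.loc[(do["location_id"] == "2 OH") & (do["date"] == pd.Timestamp("2021-07-01").date()),
               "do_mg_l"] = 1.5
        det = make_detections([("T0", "R2", "2021-07-01 06:00"),
                               ("T0", "R3", "2021-07-04 00:00")])
        tr = rd.extract_transitions(det, RMAP, DISTRICTS, do)
        assert tr.iloc[0]["initial_condition"] == "hypoxic"

    def test_missing_do_is_unknown(self):
        do = smu_do(dates=("2021-08-01", "2021-08-31"))  # July uncovered
        det = make_detections([("T0", "R2", "2021-07-01 00:00"),
                               ("T0", "R3", "2021-07-04 00:00")])
        tr = rd.extract_transitions(det, RMAP, DISTRICTS, do)
        assert tr.iloc[0]["initial_condition"] == "unknown"

    def test_rank_diff_antisymmetry(self):
        fwd = make_detections([("T0", "R2", "2021-07-01 00:00"),
                               ("T0", "R3", "2021-07-06 00:00")])
        rev = make_detections([("T0", "R3", "2021-07-01 00:00"),
                               ("T0", "R2", "2021-07-06 00:00")])
        tf = rd.extract_transitions(fwd, RMAP, DISTRICTS, smu_do())
        tb = rd.extract_transitions(rev, RMAP, DISTRICTS, smu_do())
        assert tf.iloc[0]["rank_diff"] == -tb.iloc[0]["rank_diff"]

    def test_never_spans_censor_limit(self, small_bundle):
        det = rd.filter_false_detections(small_bundle.detections)
        det = det[det["is_valid"]]
        rmap = small_bundle.receivers.set_index("receiver_id")["smu_id"]
        districts = {s.smu_id: s.district for s in small_bundle.smus}
        tr = rd.extract_transitions(det, rmap, districts, small_bundle.do_daily)
        if len(tr):
            assert (tr["duration_days"] < 21.0).all()


class TestRankDiffQuantiles:
    def _tr(self, diffs, cat):
        return pd.DataFrame({"rank_diff": diffs, "initial_condition": cat})

    def test_constant_distribution(self):
        q = rd.rank_diff_quantiles(self._tr([2, 2, 2], "hypoxic"))
        with pytest.warns(UserWarning):
            q = rd.rank_diff_quantiles(self._tr([2, 2, 2], "hypoxic"))
        assert q.iloc[0]["median"] == 2

    def test_symmetric_set_median_zero(self):
        tr = pd.concat([self._tr([-1, 0, 1], "hypoxic"), self._tr([0], "normoxic")])
        q = rd.rank_diff_quantiles(tr).set_index("initial_condition")
        assert q.loc["hypoxic", "median"] == 0

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(12)
        diffs = rng.integers(-3, 4, 100)
        tr = pd.concat([self._tr(diffs, "hypoxic"), self._tr([0, 1], "normoxic")])
        q = rd.rank_diff_quantiles(tr).set_index("initial_condition")
        assert q.loc["hypoxic", "median"] == np.quantile(diffs, 0.5)
        assert q.loc["hypoxic", "q25"] == np.quantile(diffs, 0.25)
        assert q.loc["hypoxic", "min"] == diffs.min()
        assert q.loc["hypoxic", "n"] == 100


def receivers_fixture():
    return pd.DataFrame({
        "receiver_id": ["L1", "L2", "X1"],
        "lon": [0.0, 0.1, 0.2], "lat": [0.0, 0.0, 0.0],
        "bottom_depth_m": [18.7, 22.0, 15.0],
        "has_logger": [True, True, False],
    })


def logger_do(rows):
    return pd.DataFrame(rows, columns=["date", "location_type", "location_id",
                                       "do_mg_l", "temp_c"])


class TestMatchLoggers:
    def test_depth_diff_sign_and_value(self):
        det = make_detections([("T0", "L1", "2021-07-01 03:00", 17.0)])
        do = logger_do([(pd.Timestamp("2021-07-01").date(), "receiver", "L1", 6.0, np.nan)])
        m = rd.match_loggers(det, do, receivers_fixture())
        assert m.iloc[0]["depth_diff_m"] == pytest.approx(1.7)
        assert m.iloc[0]["category"] == "normoxic"

    def test_first_detection_of_day_is_representative(self):
        det = make_detections([("T0", "L1", "2021-07-01 09:00", 12.0),
                               ("T0", "L1", "2021-07-01 02:00", 17.0)])
        do = logger_do([(pd.Timestamp("2021-07-01").date(), "receiver", "L1", 6.0, np.nan)])
        m = rd.match_loggers(det, do, receivers_fixture())
        assert len(m) == 1
        assert m.iloc[0]["tag_depth_m"] == pytest.approx(17.0)

    def test_same_receiver_pair_not_moved_no_deltas(self):
        det = make_detections([("T0", "L1", "2021-07-01 03:00", 17.0),
                               ("T0", "L1", "2021-07-02 04:00", 16.0)])
        do = logger_do([(pd.Timestamp("2021-07-01").date(), "receiver", "L1", 6.0, np.nan),
                        (pd.Timestamp("2021-07-02").date(), "receiver", "L1", 6.2, np.nan)])
        m = rd.match_loggers(det, do, receivers_fixture())
        assert m.iloc[0]["moved"] is False
        assert np.isnan(m.iloc[0]["delta_depth_m"])

    def test_between_receiver_deltas_hand_computed(self):
        det = make_detections([("T0", "L1", "2021-07-01 03:00", 17.0),
                               ("T0", "L2", "2021-07-02 04:00", 20.5)])
        do = logger_do([(pd.Timestamp("2021-07-01").date(), "receiver", "L1", 1.5, np.nan),
                        (pd.Timestamp("2021-07-02").date(), "receiver", "L2", 5.0, np.nan)])
        m = rd.match_loggers(det, do, receivers_fixture())
        first = m.iloc[0]
        assert first["moved"] is True
        assert first["delta_depth_m"] == pytest.approx(3.5)    # 20.5 - 17.0
        assert first["delta_do_mg_l"] == pytest.approx(3.5)    # 5.0 - 1.5
        assert first["pair_category"] == "hypoxic"             # earlier receiver

    def test_negative_depth_diff_retained(self):
        det = make_detections([("T0", "L1", "2021-07-01 03:00", 19.5)])
        do = logger_do([(pd.Timestamp("2021-07-01").date(), "receiver", "L1", 1.0, np.nan)])
        m = rd.match_loggers(det, do, receivers_fixture())
        assert m.iloc[0]["depth_diff_m"] == pytest.approx(-0.8)

    def test_detection_without_depth_skipped(self):
        det = make_detections([("T0", "L1", "2021-07-01 03:00")])
        do = logger_do([(pd.Timestamp("2021-07-01").date(), "receiver", "L1", 6.0, np.nan)])
        with pytest.warns(UserWarning, match="without depth"):
            m = rd.match_loggers(det, do, receivers_fixture())
        assert m.empty

    def test_non_logger_receiver_ignored(self):
        det = make_detections([("T0", "X1", "2021-07-01 03:00", 10.0)])
        m = rd.match_loggers(det, logger_do([]), receivers_fixture())
        assert m.empty


class TestMovementMetrics:
    def _matches(self, moved_flags, cat="hypoxic"):
        n = len(moved_flags)
        return pd.DataFrame({
            "tag_id": ["T0"] * n,
            "day": pd.date_range("2021-07-01", periods=n).date,
            "receiver_id": "L1",
            "tag_depth_m": 17.0, "receiver_depth_m": 18.7, "depth_diff_m": 1.7,
            "do_mg_l": 1.0, "category": cat,
            "moved": moved_flags,
            "delta_depth_m": [0.5 if f is True else np.nan for f in moved_flags],
            "delta_do_mg_l": [0.2 if f is True else np.nan for f in moved_flags],
            "pair_category": [cat if f is not None else "" for f in moved_flags],
        })

    def test_moved_proportion(self):
        m = self._matches([True, True, True, False, None])
        obs = rd.movement_metrics(m)
        moved = obs[obs["metric"] == "moved"]["value"]
        assert moved.mean() == pytest.approx(0.75)

    def test_no_between_receiver_pairs(self):
        m = self._matches([False, False, None])
        obs = rd.movement_metrics(m)
        assert (obs["metric"] == "delta_depth").sum() == 0
        assert (obs["metric"] == "depth_diff").sum() == 3

    def test_group_means_equal_brute_force(self, small_bundle):
        det = rd.filter_false_detections(small_bundle.detections)
        det = det[det["is_valid"]]
        m = rd.match_loggers(det, small_bundle.do_daily, small_bundle.receivers)
        obs = rd.movement_metrics(m)
        got = obs[(obs["metric"] == "depth_diff")].groupby("category")["value"].mean()
        want = m[m["category"].isin(["hypoxic", "normoxic"])].groupby("category")["depth_diff_m"].mean()
        for cat in got.index:
            assert got[cat] == pytest.approx(want[cat])
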