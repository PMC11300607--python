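"""Hypoxia-conditioned movement: transitions, rank differences, logger matches.

Summer stratification isolates the bottom layer of the central basin and
bottom dissolved oxygen (DO) can fall below the 2 mg/L hypoxia threshold.
To ask whether fish flee hypoxic water, consecutive detections of a tag in
different SMUs during the stratified window are turned into censored
transitions (gap < 21 days; longer gaps say little about a response to the
conditions at departure).  Each transition is coded by the longitudinal
district rank difference (destination minus origin ordinal: +1 = one
district east, 0 = a latitudinal move within a district) and by the DO
category of the origin SMU on the departure date.  A parallel fine-scale
analysis matches depth-sensing tags to DO loggers on the receivers
themselves, producing the four per-category movement metrics fed to the
mixed model: tag-vs-bottom depth difference, change in tag depth, change
in DO between successive logger receivers, and the moved/stayed indicator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

HYPOXIA_THRESHOLD_MG_L = 2.0
STRATIFIED_MONTHS = (6, 7, 8, 9, 10)
CENSOR_DAYS = 21.0


def classify_do(do_mg_l, threshold: float = HYPOXIA_THRESHOLD_MG_L):
    """Categorise bottom DO: hypoxic iff strictly below ``threshold`` mg/L,
    else normoxic; missing readings are unknown.  Accepts scalars or arrays.
    """
    arr = np.asarray(do_mg_l, dtype=float)
    out = np.where(np.isnan(arr), "unknown", np.where(arr < threshold, "hypoxic", "normoxic"))
    if np.ndim(do_mg_l) == 0:
        return str(out[()])
    return out


def _smu_do_table(do_daily: pd.DataFrame) -> pd.Series:
    smu = do_daily[do_daily["location_type"] == "smu"]
    return smu.groupby(["location_id", "date"])["do_mg_l"].mean()


def extract_transitions(
    detections: pd.DataFrame,
    receiver_smu: pd.Series | dict,
    districts: dict[str, int],
    do_daily: pd.DataFrame,
    stratified_months: tuple[int, ...] = STRATIFIED_MONTHS,
    max_days: float = CENSOR_DAYS,
    threshold: float = HYPOXIA_THRESHOLD_MG_L,
) -> pd.DataFrame:
    """Censored between-SMU transitions during the stratified window.

    Consecutive valid detections of a tag (both inside ``stratified_months``)
    in different SMUs with a gap strictly shorter than ``max_days`` become
    transitions.  ``rank_diff`` is the district ordinal difference
    (destination - origin); ``initial_condition`` is the DO category of the
    origin SMU on the departure date (unknown when the DO table has no
    reading there, reported but excluded from category contrasts).
    """
    rmap = pd.Series(receiver_smu) if isinstance(receiver_smu, dict) else receiver_smu
    df = detections.sort_values(["tag_id", "timestamp"], kind="stable").copy()
    df["smu_id"] = df["receiver_id"].map(rmap)
    df = df[df["timestamp"].dt.month.isin(stratified_months)]
    if df.empty:
        return pd.DataFrame(
            columns=["tag_id", "t_start", "t_end", "from_smu", "to_smu",
                     "from_district", "to_district", "rank_diff",
                     "duration_days", "initial_condition"]
        )
    do_lookup = _smu_do_table(do_daily)

    tag = df["tag_id"].to_numpy()
    smu = df["smu_id"].to_numpy()
    ts = df["timestamp"]
    same = tag[1:] == tag[:-1]
    gap_days = (ts.to_numpy()[1:] - ts.to_numpy()[:-1]) / np.timedelta64(1, "D")
    cross = same & (smu[1:] != smu[:-1]) & (gap_days < max_days)
    idx = np.flatnonzero(cross)

    rows = []
    for i in idx:
        from_smu, to_smu = smu[i], smu[i + 1]
        t_start, t_end = ts.iloc[i], ts.iloc[i + 1]
        key = (from_smu, t_start.date())
        do_val = do_lookup.get(key, np.nan)
        rows.append(
            {
                "tag_id": tag[i],
                "t_start": t_start,
                "t_end": t_end,
                "from_smu": from_smu,
                "to_smu": to_smu,
                "from_district": districts[from_smu],
                "to_district": districts[to_smu],
                "rank_diff": districts[to_smu] - districts[from_smu],
                "duration_days": float(gap_days[i]),
                "initial_condition": classify_do(do_val, threshold),
            }
        )
    return pd.DataFrame(rows)


def rank_diff_quantiles(transitions: pd.DataFrame) -> pd.DataFrame:
    """Per-category {min, 25%, 50%, 75%, max} of the district rank
    difference, with counts.  Empty or unknown-only categories are omitted
    with a warning."""
    out = []
    for cat in ("hypoxic", "normoxic"):
        sub = transitions[transitions["initial_condition"] == cat]["rank_diff"]
        if sub.empty:
            warnings.warn(f"rank_diff_quantiles: no transitions in category {cat!r}")
            continue
        q = sub.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        out.append(
            {
                "initial_condition": cat,
                "n": len(sub),
                "min": q.loc[0.0],
                "q25": q.loc[0.25],
                "median": q.loc[0.5],
                "q75": q.loc[0.75],
                "max": q.loc[1.0],
            }
        )
    return pd.DataFrame(out)


def match_loggers(
    detections: pd.DataFrame,
    do_daily: pd.DataFrame,
    receivers: pd.DataFrame,
    threshold: float = HYPOXIA_THRESHOLD_MG_L,
) -> pd.DataFrame:
    """Match depth-sensing detections to DO loggers on receivers, at tag-day
    resolution.

    The first detection of each tag-day at a logger-equipped receiver is the
    day's representative.  ``depth_diff_m`` = receiver bottom depth - tag
    depth (negative values — tags apparently below the bottom, a known
    detection-at-a-distance and sensor-accuracy artifact — are retained
    unmodified).  Successive representative days of a tag on *different*
    logger receivers yield the change in tag depth and in logger DO (later
    minus earlier), with the category taken from the earlier receiver;
    successive days on the same receiver mark ``moved = False``.
    Detections lacking a depth reading are skipped (counted in the log).
    """
    logger_ids = set(receivers.loc[receivers["has_logger"], "receiver_id"])
    depth_by_rec = receivers.set_index("receiver_id")["bottom_depth_m"]
    rec_do = do_daily[do_daily["location_type"] == "receiver"]
    do_lookup = rec_do.groupby(["location_id", "date"])["do_mg_l"].mean()

    df = detections[detections["receiver_id"].isin(logger_ids)].copy()
    n_nodepth = int(df["tag_depth_m"].isna().sum())
    if n_nodepth:
        warnings.warn(f"match_loggers: skipped {n_nodepth} detection(s) without depth")
    df = df.dropna(subset=["tag_depth_m"])
    df["day"] = df["timestamp"].dt.date
    df = df.sort_values(["tag_id", "timestamp"], kind="stable")
    rep = df.groupby(["tag_id", "day"], as_index=False).first()

    keys = list(zip(rep["receiver_id"], rep["day"]))
    rep["do_mg_l"] = [do_lookup.get(k, np.nan) for k in keys]
    rep["receiver_depth_m"] = rep["receiver_id"].map(depth_by_rec)
    rep["depth_diff_m"] = rep["receiver_depth_m"] - rep["tag_depth_m"]
    rep["category"] = classify_do(rep["do_mg_l"].to_numpy(), threshold)

    rep = rep.sort_values(["tag_id", "day"], kind="stable").reset_index(drop=True)
    same_tag = rep["tag_id"].to_numpy()[1:] == rep["tag_id"].to_numpy()[:-1]
    rec = rep["receiver_id"].to_numpy()
    moved = np.full(len(rep), np.nan, dtype=object)
    delta_depth = np.full(len(rep), np.nan)
    delta_do = np.full(len(rep), np.nan)
    pair_category = np.full(len(rep), "", dtype=object)
    # pair i -> attributes stored on the *earlier* row i
    for i in np.flatnonzero(same_tag):
        pair_category[i] = rep["category"].iloc[i]
        if rec[i + 1] != rec[i]:
            moved[i] = True
            delta_depth[i] = rep["tag_depth_m"].iloc[i + 1] - rep["tag_depth_m"].iloc[i]
            delta_do[i] = rep["do_mg_l"].iloc[i + 1] - rep["do_mg_l"].iloc[i]
        else:
            moved[i] = False
    rep["moved"] = moved
    rep["delta_depth_m"] = delta_depth
    rep["delta_do_mg_l"] = delta_do
    rep["pair_category"] = pair_category
    return rep[
        ["tag_id", "day", "receiver_id", "tag_depth_m", "receiver_depth_m",
         "depth_diff_m", "do_mg_l", "category", "moved",
         "delta_depth_m", "delta_do_mg_l", "pair_category"]
    ]


def movement_metrics(matches: pd.DataFrame) -> pd.DataFrame:
    """Long-format metric observations for the category mixed model.

    Metrics: ``depth_diff`` (per tag-day, category of that day),
    ``delta_depth`` and ``delta_do`` (per between-receiver day pair,
    category of the earlier receiver), and ``moved`` as a 0/1 indicator per
    successive day pair.  Unknown-category rows are dropped from contrasts.
    """
    if matches.empty:
        warnings.warn("movement_metrics: empty logger-match input")
        return pd.DataFrame(columns=["metric", "tag_id", "category", "value"])
    frames = []
    dd = matches[matches["category"].isin(["hypoxic", "normoxic"])]
    frames.append(
        pd.DataFrame(
            {"metric": "depth_diff", "tag_id": dd["tag_id"],
             "category": dd["category"], "value": dd["depth_diff_m"]}
        )
    )
    pairs = matches[matches["moved"].notna()]
    pairs = pairs[pairs["pair_category"].isin(["hypoxic", "normoxic"])]
    movers = pairs[pairs["moved"] == True]  # noqa: E712  (object column)
    for metric, col in (("delta_depth", "delta_depth_m"), ("delta_do", "delta_do_mg_l")):
        sub = movers.dropna(subset=[col])
        frames.append(
            pd.DataFrame(
                {"metric": metric, "tag_id": sub["tag_id"],
                 "category": sub["pair_category"], "value": sub[col]}
            )
        )
    frames.append(
        pd.DataFrame(
            {"metric": "moved", "tag_id": pairs["tag_id"],
             "category": pairs["pair_category"],
             "value": pairs["moved"].astype(float)}
        )
    )
    return pd.concat(frames, ignore_index=True).dropna(subset=["value"])
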