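"""Residency allocation and monthly summaries.

Every day between a tag's first and last valid detection is attributed to a
month x SMU cell.  For a pair of consecutive detections in different SMUs
the intervening gap is split evenly at its temporal midpoint — the first
half accrues to the origin SMU, the second to the destination — and each
accrued sub-interval is then partitioned across calendar-month boundaries.
This guarantees exact day conservation (allocated days sum to the
detection-history span of each tag) without biasing either SMU in the pair.

The monthly summary averages per-tag-year totals over the fish at large in
each month and normalises to proportions, and a descriptive random-intercept
trend of ordinal SMU code on month summarises the seasonal migration wave.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_NS_PER_DAY = 86400 * 10**9


def _month_edges(t_min: pd.Timestamp, t_max: pd.Timestamp) -> pd.DatetimeIndex:
    """UTC month-start instants bracketing [t_min, t_max]."""
    start = t_min.tz_convert("UTC").normalize().replace(day=1)
    end = (t_max.tz_convert("UTC").normalize().replace(day=1) + pd.DateOffset(months=2))
    return pd.date_range(start, end, freq="MS", tz="UTC")


def allocate_residency(
    detections: pd.DataFrame, receiver_smu: pd.Series | dict
) -> pd.DataFrame:
    """Allocate detection-history time to (tag_id, year, month, smu_id) cells.

    Parameters
    ----------
    detections
        Valid detections only (``is_valid`` rows), with ``tag_id``,
        ``receiver_id`` and tz-aware ``timestamp`` columns.
    receiver_smu
        Mapping receiver_id -> smu_id.

    Returns
    -------
    DataFrame with columns tag_id, year, month, smu_id, days. Per tag the
    days sum to (last - first valid detection), exactly.
    """
    rmap = pd.Series(receiver_smu) if isinstance(receiver_smu, dict) else receiver_smu
    df = detections.copy()
    df["smu_id"] = df["receiver_id"].map(rmap)
    if df["smu_id"].isna().any():
        bad = sorted(df.loc[df["smu_id"].isna(), "receiver_id"].unique())
        raise ValueError(f"detections at receiver(s) with no SMU assignment: {bad}")
    df = df.sort_values(["tag_id", "timestamp"], kind="stable")

    ts = df["timestamp"].astype("int64").to_numpy()
    tag = df["tag_id"].to_numpy()
    smu = df["smu_id"].to_numpy()
    n = len(df)
    if n == 0:
        return pd.DataFrame(columns=["tag_id", "year", "month", "smu_id", "days"])

    same_tag = tag[1:] == tag[:-1]
    if not (np.diff(ts)[same_tag] >= 0).all():  # guaranteed by sort; cheap check
        raise ValueError("detections not sorted by timestamp within tag")

    # consecutive pairs within each tag
    i0 = np.flatnonzero(same_tag)
    t0, t1 = ts[i0], ts[i0 + 1]
    s0, s1 = smu[i0], smu[i0 + 1]
    ptag = tag[i0]
    mid = t0 + (t1 - t0) // 2  # integer ns; exact conservation

    cross = s0 != s1
    # segment list: [start, end) in ns, SMU, tag
    seg_start = np.concatenate([t0, mid[cross]])
    seg_end = np.concatenate([np.where(cross, mid, t1), t1[cross]])
    seg_smu = np.concatenate([s0, s1[cross]])
    seg_tag = np.concatenate([ptag, ptag[cross]])

    keep = seg_end > seg_start
    seg_start, seg_end = seg_start[keep], seg_end[keep]
    seg_smu, seg_tag = seg_smu[keep], seg_tag[keep]

    edges_dt = _month_edges(df["timestamp"].min(), df["timestamp"].max())
    edges = edges_dt.astype("int64").to_numpy()

    # month index of segment start/end; segment i spans months k0..k1
    k0 = np.searchsorted(edges, seg_start, side="right") - 1
    k1 = np.searchsorted(edges, seg_end - 1, side="right") - 1
    counts = k1 - k0 + 1
    rep = np.repeat(np.arange(len(seg_start)), counts)
    # month index per expanded row
    offsets = np.arange(len(rep)) - np.repeat(np.cumsum(counts) - counts, counts)
    month_idx = k0[rep] + offsets
    m_start = edges[month_idx]
    m_end = edges[month_idx + 1]
    overlap = np.minimum(seg_end[rep], m_end) - np.maximum(seg_start[rep], m_start)

    out = pd.DataFrame(
        {
            "tag_id": seg_tag[rep],
            "year": edges_dt.year.to_numpy()[month_idx],
            "month": edges_dt.month.to_numpy()[month_idx],
            "smu_id": seg_smu[rep],
            "days": overlap / _NS_PER_DAY,
        }
    )
    out = (
        out.groupby(["tag_id", "year", "month", "smu_id"], as_index=False)["days"]
        .sum()
        .sort_values(["tag_id", "year", "month", "smu_id"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def summarize_residency(records: pd.DataFrame) -> pd.DataFrame:
    """Average residency across fish and years into month x SMU means.

    For each calendar month, the mean over (tag, year) pairs at large during
    any part of that month of the days spent in each SMU (tags at large but
    absent from an SMU contribute zero there), then normalised so per-month
    proportions sum to 1.
    """
    if records.empty:
        warnings.warn("summarize_residency: empty residency input")
        return pd.DataFrame(columns=["month", "smu_id", "mean_days", "proportion"])
    smus = sorted(records["smu_id"].unique())
    wide = (
        records.pivot_table(
            index=["tag_id", "year", "month"],
            columns="smu_id",
            values="days",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=smus, fill_value=0.0)
        .reset_index()
    )
    mean = wide.groupby("month")[smus].mean()
    out = mean.stack().rename("mean_days").reset_index()
    totals = out.groupby("month")["mean_days"].transform("sum")
    out["proportion"] = np.where(totals > 0, out["mean_days"] / totals, 0.0)
    return out.sort_values(["month", "smu_id"]).reset_index(drop=True)


def detection_summary(
    detections: pd.DataFrame, receiver_smu: pd.Series | dict
) -> pd.DataFrame:
    """Mean detections per at-large tag for each month x SMU cell.

    A tag is at large in a (year, month) iff its valid-detection history
    overlaps that month; at-large tags with zero detections in a cell count
    as zeros in the mean, so the summary reflects changing numbers of fish
    at large rather than raw detection totals.
    """
    rmap = pd.Series(receiver_smu) if isinstance(receiver_smu, dict) else receiver_smu
    df = detections.copy()
    df["smu_id"] = df["receiver_id"].map(rmap)
    df["year"] = df["timestamp"].dt.year
    df["month"] = df["timestamp"].dt.month
    counts = df.groupby(["tag_id", "year", "month", "smu_id"]).size().rename("n")

    # at-large (tag, year, month) grid from each tag's detection span
    spans = df.groupby("tag_id")["timestamp"].agg(["min", "max"])
    frames = []
    for tid, row in spans.iterrows():
        months = pd.period_range(row["min"], row["max"], freq="M")
        frames.append(pd.DataFrame({"tag_id": tid, "year": months.year, "month": months.month}))
    at_large = pd.concat(frames, ignore_index=True)

    smus = sorted(rmap.unique())
    wide = counts.unstack("smu_id", fill_value=0).reindex(columns=smus, fill_value=0)
    full = (
        at_large.set_index(["tag_id", "year", "month"])
        .join(wide, how="left")
        .fillna(0)
    )
    mean = full.groupby(level="month")[smus].mean()
    mean.columns.name = "smu_id"
    out = mean.stack().rename("mean_detections").reset_index()
    return out.sort_values(["month", "smu_id"]).reset_index(drop=True)


@dataclass
class TrendFit:
    """Descriptive seasonal trend of ordinal SMU code on month."""

    intercept: float
    slope: float
    slope_ci: tuple[float, float]
    tag_variance: float
    fitted: pd.DataFrame  # month, fit, lo, hi (95% band, fixed-effects)
    fallback: bool = False  # True when the mixed fit was singular and an
    # unweighted fixed-effects fit was used instead


def fit_seasonal_trend(
    detections: pd.DataFrame,
    receiver_smu: pd.Series | dict,
    ordinal_codes: dict[str, int],
    weighted: bool = True,
) -> TrendFit:
    """Gaussian random-intercept trend of ordinal SMU code on month.

    Each detection contributes one observation (response: the ordinal code
    of the SMU where it was heard; predictor: calendar month as a continuous
    covariate), so cells are weighted by their detection counts; tags enter
    as random intercepts.  ``weighted=False`` collapses to one observation
    per tag x month x SMU cell.  A singular mixed fit falls back to an
    unweighted OLS fixed-effects fit, flagged in the result.
    """
    rmap = pd.Series(receiver_smu) if isinstance(receiver_smu, dict) else receiver_smu
    df = detections.copy()
    df["smu_id"] = df["receiver_id"].map(rmap)
    df["ordinal"] = df["smu_id"].map(ordinal_codes).astype(float)
    df["month"] = df["timestamp"].dt.month.astype(float)
    if not weighted:
        df = df.drop_duplicates(["tag_id", "month", "smu_id", "ordinal"])
    if df["tag_id"].nunique() < 2 or df["month"].nunique() < 2:
        raise ValueError("trend fit requires >= 2 tags and >= 2 months")

    endog = df["ordinal"].to_numpy()
    exog = sm.add_constant(df[["month"]].to_numpy())
    months = np.arange(1.0, 13.0)
    grid = sm.add_constant(np.column_stack([months]), has_constant="add")

    fallback = False
    tag_var = 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog, exog, groups=df["tag_id"].to_numpy())
            res = model.fit(reml=True)
        if not np.all(np.isfinite(res.bse_fe.to_numpy() if hasattr(res.bse_fe, "to_numpy") else res.bse_fe)):
            raise np.linalg.LinAlgError("non-finite fixed-effect SEs")
        params = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[:2, :2]
        tag_var = float(np.asarray(res.cov_re).ravel()[0])
        # boundary fits (tag variance ~ 0) are refit as plain fixed effects
        if tag_var <= 1e-8 * max(float(np.var(endog)), 1e-12):
            raise np.linalg.LinAlgError("singular random-effects covariance")
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("singular mixed trend fit; falling back to OLS fixed effects")
        fallback = True
        res = sm.OLS(endog, exog).fit()
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())

    fit = grid @ params
    se = np.sqrt(np.einsum("ij,jk,ik->i", grid, cov, grid))
    band = 1.96 * se
    slope_se = float(np.sqrt(cov[1, 1]))
    fitted = pd.DataFrame({"month": months, "fit": fit, "lo": fit - band, "hi": fit + band})
    return TrendFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        slope_ci=(float(params[1] - 1.96 * slope_se), float(params[1] + 1.96 * slope_se)),
        tag_variance=tag_var,
        fitted=fitted,
        fallback=fallback,
    )
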