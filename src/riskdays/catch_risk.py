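"""Catch matrix, cumulative rank percentiles, and the risk-days product.

Commercial catch (pounds, demersal gears) is summed per month within each
year, averaged across years into a month x SMU matrix, and converted to a
cumulative rank percentile among the nonzero cells: percentile(c) =
(# nonzero cells with value <= value(c)) / (# nonzero cells), so the
largest cell is always 1.0 and ties share the maximal cumulative rank.
Zero-catch cells are excluded from the ranking (they carry no information
about relative fishing pressure) and receive a null percentile.

Risk days — the study's exploitation-risk proxy — is the product of mean
monthly residency (days) and the catch percentile of the same cell; a
zero-catch cell yields zero risk regardless of residency (a refuge).
"""

from __future__ import annotations

import importlib.resources
import warnings

import numpy as np
import pandas as pd

MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]


def published_mean_catch() -> pd.DataFrame:
    """The published 2019–2022 mean monthly commercial catch (pounds) of
    Lake Whitefish from demersal gears in Lake Erie, by month and SMU, as
    summarised from the Lake Erie Committee's binational catch reporting.

    Long format: month (1–12), smu_id, mean_catch_lb.  Used as the default
    intensity profile of the synthetic catch generator and as the worked
    example of the percentile ranking.
    """
    ref = importlib.resources.files("riskdays.data").joinpath(
        "lake_whitefish_mean_catch_2019_2022.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"smu_id": str})


def mean_catch_matrix(
    catch: pd.DataFrame, year_range: tuple[int, int], smu_ids: list[str] | None = None
) -> pd.DataFrame:
    """Month x SMU mean catch: per-year month sums averaged across all years
    of ``year_range`` (inclusive), with absent year x cell combinations
    counting as zero in the mean.
    """
    if (catch["pounds"] < 0).any():
        raise ValueError("catch: pounds must be non-negative")
    y0, y1 = year_range
    years = list(range(y0, y1 + 1))
    sub = catch[catch["year"].isin(years)]
    sums = sub.groupby(["year", "month", "smu_id"], as_index=False)["pounds"].sum()
    if smu_ids is None:
        smu_ids = sorted(catch["smu_id"].unique())
    grid = pd.MultiIndex.from_product([range(1, 13), smu_ids], names=["month", "smu_id"])
    total = sums.groupby(["month", "smu_id"])["pounds"].sum().reindex(grid, fill_value=0.0)
    out = (total / len(years)).rename("mean_catch_lb").reset_index()
    return out


def percentile_ranks(matrix: pd.DataFrame, value_col: str = "mean_catch_lb") -> pd.DataFrame:
    """Attach cumulative rank percentiles (fraction in (0, 1]) to the
    nonzero cells of a month x SMU matrix; zero cells get NaN.

    Ties share the maximal cumulative rank ("<=" counting), so the maximum
    cell — and an all-equal matrix — ranks 1.0.
    """
    out = matrix.copy()
    values = out[value_col].to_numpy(dtype=float)
    nonzero = values > 0
    n = int(nonzero.sum())
    pct = np.full(len(out), np.nan)
    if n == 0:
        warnings.warn("percentile_ranks: all cells are zero; all percentiles null")
    else:
        vals = values[nonzero]
        order = np.sort(vals)
        pct[nonzero] = np.searchsorted(order, vals, side="right") / n
    out["percentile"] = pct
    return out


def compute_risk_days(
    monthly_summary: pd.DataFrame,
    pct_matrix: pd.DataFrame,
    smu_order: list[str] | None = None,
) -> pd.DataFrame:
    """Risk days = mean residency days x catch percentile, per month x SMU.

    A null percentile (zero catch) or zero residency gives zero risk.  The
    two tables must cover the same SMU keys; output is ordered by month then
    ``smu_order`` (west to east) when given.
    """
    left = set(monthly_summary["smu_id"])
    right = set(pct_matrix["smu_id"])
    if left != right:
        raise ValueError(
            f"SMU key mismatch between residency summary and catch matrix: "
            f"only-residency={sorted(left - right)}, only-catch={sorted(right - left)}"
        )
    merged = monthly_summary.merge(
        pct_matrix[["month", "smu_id", "percentile"]], on=["month", "smu_id"], how="left"
    )
    merged["risk_days"] = merged["mean_days"] * merged["percentile"].fillna(0.0)
    if smu_order is not None:
        merged["smu_id"] = pd.Categorical(merged["smu_id"], categories=smu_order, ordered=True)
    merged = merged.sort_values(["month", "smu_id"]).reset_index(drop=True)
    merged["smu_id"] = merged["smu_id"].astype(str)
    return merged[["month", "smu_id", "mean_days", "percentile", "risk_days"]]
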