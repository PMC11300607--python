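"""Gaussian random-intercept comparison of movement metrics between DO categories.

Each metric (including the 0/1 moved indicator, treated as a linear
probability on the same Gaussian contract) is modelled as

    value_ij = mu_category(i,j) + b_i + e_ij,   b_i ~ N(0, s2_tag)

with a random intercept b_i per tag to absorb the correlation of repeated
measurements within fish.  Reported are the least-squares category means,
their difference (normoxic minus hypoxic by default), and 95% confidence
intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("hypoxic", "normoxic")  # difference = second - first
_Z95 = 1.959963984540054


@dataclass
class ModelEstimate:
    metric: str
    mean_hypoxic: float
    mean_normoxic: float
    difference: float  # normoxic - hypoxic
    ci_low: float
    ci_high: float
    mean_hypoxic_ci: tuple[float, float]
    mean_normoxic_ci: tuple[float, float]
    tag_variance: float
    n_obs: int
    n_tags: int
    df_method: str
    significant: bool
    fallback: bool = False


def fit_category_mixed_model(
    observations: pd.DataFrame,
    metric: str,
    category_order: tuple[str, str] = CATEGORY_ORDER,
) -> ModelEstimate:
    """Fit the random-intercept category contrast for one metric.

    ``observations`` is the long table from
    :func:`riskdays.hypoxia_movement.movement_metrics` (columns metric,
    tag_id, category, value).  Confidence intervals use the large-sample
    normal approximation (recorded in ``df_method``).  Degenerate inputs
    (zero total variance) collapse to raw category means with a [0, 0]
    difference interval; a singular random-effects fit falls back to OLS,
    flagged in the result.
    """
    df = observations[observations["metric"] == metric].copy()
    cats = set(df["category"].unique())
    missing = [c for c in category_order if c not in cats]
    if missing:
        raise ValueError(f"metric {metric!r}: category {missing} absent from observations")
    df = df[df["category"].isin(category_order)]
    n_tags = df["tag_id"].nunique()
    if n_tags < 2:
        raise ValueError(f"metric {metric!r}: need >= 2 tags, got {n_tags}")

    # cell-means parameterisation: one column per category
    X = np.column_stack([(df["category"] == c).to_numpy(float) for c in category_order])
    y = df["value"].to_numpy(float)
    contrast = np.array([-1.0, 1.0])  # second - first

    degenerate = np.ptp(y) == 0.0
    fallback = False
    tag_var = 0.0
    if degenerate:
        params = np.array([y.mean(), y.mean()])
        cov = np.zeros((2, 2))
        method = "degenerate"
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, X, groups=df["tag_id"].to_numpy()).fit(reml=True)
            params = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[:2, :2]
            tag_var = float(np.asarray(res.cov_re).ravel()[0])
            # a boundary fit (tag variance ~ 0) can leave garbage fixed
            # effects behind; the fixed-effects model is then the right one
            if tag_var <= 1e-8 * max(float(np.var(y)), 1e-12):
                raise np.linalg.LinAlgError("singular random-effects covariance")
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError("non-finite covariance")
            method = "normal"
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("metric %s: singular mixed fit, OLS fallback", metric)
            res = sm.OLS(y, X).fit()
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            method = "normal-ols"
            fallback = True

    means = params
    mean_se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    diff = float(contrast @ params)
    diff_se = float(np.sqrt(max(contrast @ cov @ contrast, 0.0)))
    lo, hi = diff - _Z95 * diff_se, diff + _Z95 * diff_se
    return ModelEstimate(
        metric=metric,
        mean_hypoxic=float(means[0]),
        mean_normoxic=float(means[1]),
        difference=diff,
        ci_low=float(lo),
        ci_high=float(hi),
        mean_hypoxic_ci=(float(means[0] - _Z95 * mean_se[0]), float(means[0] + _Z95 * mean_se[0])),
        mean_normoxic_ci=(float(means[1] - _Z95 * mean_se[1]), float(means[1] + _Z95 * mean_se[1])),
        tag_variance=tag_var,
        n_obs=len(df),
        n_tags=n_tags,
        df_method=method,
        significant=bool(lo > 0 or hi < 0),
        fallback=fallback,
    )


def fit_all_metrics(observations: pd.DataFrame) -> pd.DataFrame:
    """Fit every metric present in the observation table; returns the
    estimates as one row per metric (estimates.csv dialect)."""
    rows = []
    for metric in observations["metric"].unique():
        try:
            est = fit_category_mixed_model(observations, metric)
        except ValueError as exc:
            logger.warning("skipping metric %s: %s", metric, exc)
            continue
        rows.append(
            {
                "metric": est.metric,
                "mean_hypoxic": est.mean_hypoxic,
                "mean_normoxic": est.mean_normoxic,
                "difference": est.difference,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "tag_variance": est.tag_variance,
                "n_obs": est.n_obs,
                "n_tags": est.n_tags,
                "df_method": est.df_method,
                "significant": est.significant,
            }
        )
    return pd.DataFrame(rows)
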