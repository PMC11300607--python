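"""Input reading, validation, detection QC, tag-fate censoring and SMU assignment.

The raw material of the analysis is a set of acoustic telemetry detection
records (one row per tag transmission heard at a receiver), a receiver
table, tag metadata, a GeoJSON of spatial management unit (SMU) polygons,
a commercial catch table, and a daily bottom dissolved-oxygen table.  This
module turns the on-disk CSV/GeoJSON dialects into typed pandas tables,
flags false detections with the minimum-lag criterion, classifies tag fates
(retained vs. excluded), and assigns receivers to SMUs by point-in-polygon.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["tag_id", "receiver_id", "timestamp_utc", "tag_depth_m"]
RECEIVER_COLUMNS = ["receiver_id", "lon", "lat", "bottom_depth_m", "has_logger"]
TAG_COLUMNS = [
    "tag_id",
    "release_site",
    "release_time_utc",
    "total_length_mm",
    "tag_model",
    "battery_days",
    "fate_override",
]
CATCH_COLUMNS = ["year", "month", "smu_id", "pounds"]
DO_COLUMNS = ["date", "location_type", "location_id", "do_mg_l", "temp_c"]


class SchemaError(ValueError):
    """A required column is missing or a value violates the input contract."""


@dataclass(frozen=True)
class Smu:
    """One spatial management unit: a polygon carrying a west-to-east
    district ordinal (0 reserved for the river corridor) and a jurisdiction
    label, plus the 1..n ordinal code used by the seasonal trend model."""

    smu_id: str
    district: int
    jurisdiction: str
    ordinal_code: int
    polygon: BaseGeometry


@dataclass
class StudyData:
    """Validated input bundle consumed by the downstream stages."""

    detections: pd.DataFrame
    receivers: pd.DataFrame
    tags: pd.DataFrame
    smus: list[Smu]
    catch: pd.DataFrame | None = None
    do_daily: pd.DataFrame | None = None
    unknown_receivers: list[str] = field(default_factory=list)


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _parse_utc(series: pd.Series, name: str) -> pd.Series:
    parsed = pd.to_datetime(series, utc=True, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise SchemaError(f"{name}: unparseable timestamp(s) at line(s) {lines[:20]}")
    return parsed


def read_smus_geojson(path: str | Path) -> list[Smu]:
    """Read an SMU FeatureCollection (properties: smu_id, district,
    jurisdiction, ordinal_code)."""
    with open(path) as fh:
        collection = json.load(fh)
    smus = []
    for feat in collection["features"]:
        props = feat["properties"]
        for key in ("smu_id", "district", "jurisdiction", "ordinal_code"):
            if key not in props:
                raise SchemaError(f"smus.geojson: feature missing property {key!r}")
        smus.append(
            Smu(
                smu_id=str(props["smu_id"]),
                district=int(props["district"]),
                jurisdiction=str(props["jurisdiction"]),
                ordinal_code=int(props["ordinal_code"]),
                polygon=shape(feat["geometry"]),
            )
        )
    codes = [s.ordinal_code for s in smus]
    if len(set(codes)) != len(codes):
        raise SchemaError("smus.geojson: ordinal_code values must be unique")
    return smus


def write_smus_geojson(smus: list[Smu], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(s.polygon),
            "properties": {
                "smu_id": s.smu_id,
                "district": s.district,
                "jurisdiction": s.jurisdiction,
                "ordinal_code": s.ordinal_code,
            },
        }
        for s in smus
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str, "receiver_id": str})
    _require_columns(df, DETECTION_COLUMNS[:3], "detections")
    if "tag_depth_m" not in df.columns:
        df["tag_depth_m"] = np.nan
    df["timestamp"] = _parse_utc(df["timestamp_utc"], "detections")
    df["tag_depth_m"] = pd.to_numeric(df["tag_depth_m"], errors="coerce")
    if (df["tag_depth_m"].dropna() < 0).any():
        raise SchemaError("detections: tag_depth_m must be non-negative")
    df = df.sort_values(["tag_id", "timestamp"], kind="stable").reset_index(drop=True)
    return df.drop(columns=["timestamp_utc"])


def read_receivers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"receiver_id": str})
    _require_columns(df, RECEIVER_COLUMNS[:4], "receivers")
    if "has_logger" not in df.columns:
        df["has_logger"] = False
    df["has_logger"] = df["has_logger"].astype(bool)
    if (df["bottom_depth_m"] <= 0).any():
        raise SchemaError("receivers: bottom_depth_m must be positive")
    return df


def read_tags(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str, "fate_override": str})
    _require_columns(df, TAG_COLUMNS[:2], "tags")
    if "release_time_utc" in df.columns:
        df["release_time"] = _parse_utc(df["release_time_utc"], "tags")
        df = df.drop(columns=["release_time_utc"])
    if "fate_override" not in df.columns:
        df["fate_override"] = pd.NA
    return df


def read_catch(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"smu_id": str})
    _require_columns(df, CATCH_COLUMNS, "catch")
    if (df["pounds"] < 0).any():
        raise SchemaError("catch: pounds must be non-negative")
    return df


def read_do_daily(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"location_id": str})
    _require_columns(df, DO_COLUMNS[:4], "do_daily")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if (df["do_mg_l"].dropna() < 0).any():
        raise SchemaError("do_daily: do_mg_l must be non-negative")
    return df


def read_inputs(
    detections: str | Path,
    receivers: str | Path,
    tags: str | Path,
    smus: str | Path,
    catch: str | Path | None = None,
    do_daily: str | Path | None = None,
) -> StudyData:
    """Read and validate the full input bundle.

    Detections referencing receivers absent from the receiver table are
    retained but reported in ``StudyData.unknown_receivers``.
    """
    det = read_detections(detections)
    rec = read_receivers(receivers)
    tag = read_tags(tags)
    smu_list = read_smus_geojson(smus)
    unknown = sorted(set(det["receiver_id"]) - set(rec["receiver_id"]))
    if unknown:
        logger.warning("detections reference %d unknown receiver(s): %s", len(unknown), unknown[:10])
    data = StudyData(
        detections=det,
        receivers=rec,
        tags=tag,
        smus=smu_list,
        catch=read_catch(catch) if catch else None,
        do_daily=read_do_daily(do_daily) if do_daily else None,
        unknown_receivers=unknown,
    )
    logger.info(
        "read %d detections, %d receivers, %d tags, %d SMUs",
        len(det), len(rec), len(tag), len(smu_list),
    )
    return data


def filter_false_detections(detections: pd.DataFrame, min_lag_max_s: float = 3600.0) -> pd.DataFrame:
    """Flag false detections with the minimum-lag criterion.

    A detection is valid iff another detection of the same tag on the same
    receiver lies within ``min_lag_max_s`` seconds of it; isolated pings —
    the signature of code collisions and environmental noise — are flagged
    invalid.  Rows are never dropped, only flagged via ``is_valid``.
    Idempotent: the flag depends only on (tag, receiver, timestamp) triples.
    """
    if min_lag_max_s <= 0:
        raise ValueError("min_lag_max_s must be positive")
    df = detections.sort_values(["tag_id", "receiver_id", "timestamp"], kind="stable")
    ts = df["timestamp"].astype("int64").to_numpy()
    grp = (df["tag_id"].astype(str) + "\x00" + df["receiver_id"].astype(str)).to_numpy()
    same_prev = np.empty(len(df), dtype=bool)
    same_next = np.empty(len(df), dtype=bool)
    if len(df):
        same_prev[0] = False
        same_prev[1:] = grp[1:] == grp[:-1]
        same_next[:-1] = same_prev[1:]
        same_next[-1] = False
    lag_ns = int(min_lag_max_s * 1e9)
    prev_ok = same_prev & (np.r_[0, np.diff(ts)] <= lag_ns)
    next_ok = same_next & (np.r_[np.diff(ts), 0] <= lag_ns)
    valid = prev_ok | next_ok
    out = detections.copy()
    out.loc[df.index, "is_valid"] = valid
    out["is_valid"] = out["is_valid"].astype(bool)
    return out


def classify_tag_fates(
    detections: pd.DataFrame, tag_meta: pd.DataFrame, min_days: float = 35.0
) -> pd.DataFrame:
    """Partition tags into retained vs. excluded(reason).

    Exclusion reasons: ``never_detected`` (no valid detection),
    ``short_span`` (first-to-last valid detection span < ``min_days``), or a
    non-blank ``fate_override`` value from the tag table (e.g. "harvested").
    The span is computed on QC-valid detections only, so the false-detection
    filter must run first.
    """
    if "is_valid" not in detections.columns:
        raise ValueError("detections must carry an is_valid QC flag; run filter_false_detections first")
    known = set(tag_meta["tag_id"])
    stray = sorted(set(detections["tag_id"]) - known)
    if stray:
        raise ValueError(f"detections contain tag_id(s) absent from tag metadata: {stray}")
    valid = detections[detections["is_valid"]]
    spans = valid.groupby("tag_id")["timestamp"].agg(["min", "max"])
    span_days = (spans["max"] - spans["min"]).dt.total_seconds() / 86400.0
    rows = []
    for _, trow in tag_meta.iterrows():
        tid = trow["tag_id"]
        override = trow.get("fate_override")
        if pd.notna(override) and str(override).strip():
            fate, reason = "excluded", str(override).strip()
        elif tid not in span_days.index:
            fate, reason = "excluded", "never_detected"
        elif span_days.loc[tid] < min_days:
            fate, reason = "excluded", "short_span"
        else:
            fate, reason = "retained", ""
        rows.append(
            {
                "tag_id": tid,
                "fate": fate,
                "reason": reason,
                "span_days": float(span_days.get(tid, np.nan)),
            }
        )
    return pd.DataFrame(rows)


def retained_tags(fates: pd.DataFrame) -> list[str]:
    return fates.loc[fates["fate"] == "retained", "tag_id"].tolist()


def assign_smu(receivers: pd.DataFrame, smus: list[Smu]) -> pd.DataFrame:
    """Assign each receiver to its containing SMU by point-in-polygon.

    A receiver sitting exactly on a shared boundary is assigned to the SMU
    with the smaller district ordinal, ties broken by lexicographic smu_id;
    a receiver outside every polygon is an error.
    """
    order = sorted(smus, key=lambda s: (s.district, s.smu_id))
    assigned = []
    for _, row in receivers.iterrows():
        pt = Point(row["lon"], row["lat"])
        hits = [s for s in order if s.polygon.covers(pt)]
        if not hits:
            raise ValueError(f"receiver {row['receiver_id']} lies outside all SMU polygons")
        assigned.append(hits[0].smu_id)
    out = receivers.copy()
    out["smu_id"] = assigned
    assert len(out) == len(receivers)
    return out
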