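"""Seeded synthetic study generator with known ground truth.

The generator emulates the phenomenology of a large, seasonally stratified
lake fishery: a rectangular lake split into four west-to-east districts,
each divided into a northern (Canadian) and southern (US) spatial
management unit; a grid of acoustic receivers with DO loggers confined to
the central basin (districts 2-3); summer bottom-water hypoxia in the
central basin; fish that concentrate in the western district each November
to spawn, otherwise reside in the central basin, and — when the water
under them goes hypoxic — shift east with configurable avoidance strength;
a detection process with ~1 km range (fish are snapped to one receiver of
their SMU), per-transmission detection probability, and +/-0.9 m depth
sensor noise; and a commercial catch matrix whose intensity profile is the
published mean monthly demersal-gear catch, dominated by the November
western-district trap-net spike.

Every output is a deterministic function of the master seed; each
component (DO noise, tracks, detections, catch) draws from its own child
stream so components can be regenerated independently.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from shapely.geometry import box

from .catch_risk import published_mean_catch
from .io_qc import Smu, write_smus_geojson

KM_PER_DEG_LAT = 110.57
KM_PER_DEG_LON = 82.6  # at ~42 N

LON_WEST = -83.4
DISTRICT_WIDTH_DEG = 1.1
LAT_SOUTH = 41.3
LAT_MID = 42.1
LAT_NORTH = 42.9

SOUTH_SMU = {1: "1 OH", 2: "2 OH", 3: "3 OH/PA", 4: "4 NY/PA"}
NORTH_SMU = {1: "1 ON", 2: "2 ON", 3: "3 ON", 4: "4 ON"}
SMU_ORDER = ["1 OH", "1 ON", "2 OH", "2 ON", "3 OH/PA", "3 ON", "4 NY/PA", "4 ON"]
DISTRICT_DEPTH_M = {1: 7.4, 2: 18.5, 3: 20.0, 4: 24.4}

TAG_SITES = [
    ("Crib Reef", "V13-TP ADST", 584, 612.0, 30.6),
    ("Colchester Reef", "V16TP", 1825, 514.0, 53.1),
    ("Turtle Island Reef", "V13-TP", 824, 453.0, 11.7),
]

# month -> target district distribution; None = unbiased random walk.
# The summer window is deliberately symmetric: the eastward summer shift
# emerges from hypoxia avoidance, not from a built-in drift.
DEFAULT_SCHEDULE: dict[int, dict[int, float] | None] = {
    1: {2: 0.5, 3: 0.5},
    2: {2: 0.5, 3: 0.5},
    3: {2: 0.5, 3: 0.5},
    4: {2: 0.5, 3: 0.5},
    5: {2: 0.3, 3: 0.7},
    6: None,
    7: None,
    8: None,
    9: None,
    10: None,
    11: {1: 1.0},
    12: {2: 0.5, 3: 0.5},
}


class HypoxiaConfig(BaseModel):
    onset_month: int = 7
    end_month: int = 9
    districts: tuple[int, ...] = (2, 3)
    severity: float = Field(1.0, ge=0.0, le=1.0)
    do_base_mg_l: float = 8.5
    do_min_mg_l: float = 1.0  # curve bottom at severity 1


class ScenarioConfig(BaseModel):
    """Study conditions of the synthetic scenario (defaults ARE the study)."""

    seed: int = 0
    n_fish: int = 50
    start: dt.date = dt.date(2021, 1, 1)
    n_months: int = 12
    receiver_spacing_km: float = Field(10.0, gt=0.0)
    detection_p_per_transmission: float = Field(0.5, ge=0.0, le=1.0)
    transmit_interval_s: float = Field(120.0, gt=0.0)
    burst_rate_per_day: float = Field(4.0, gt=0.0)
    mean_burst_detections: float = Field(3.0, ge=1.0)
    depth_sensor_sd_m: float = 0.9
    depth_jitter_sd_m: float = 0.5
    logger_noise_sd: float = 0.3
    avoidance_strength: float = Field(5.0, ge=0.0)
    move_prob: float = 0.4  # toward the monthly target, per day
    summer_move_prob: float = 0.15  # symmetric random walk, per day
    drift_prob: float = 0.05  # wander when already at target
    side_switch_prob: float = 0.02
    spawn_south_pull: float = 0.15  # November north->south switching
    restation_prob: float = 0.2  # per-day chance of shifting receiver in-SMU
    early_silence_fraction: float = 0.1
    catch_years: tuple[int, int] = (2019, 2022)
    catch_sigma: float = 0.5
    catch_intensity_scale: float = Field(1.0, ge=0.0)
    do_threshold_mg_l: float = 2.0
    fate_min_days: float = 35.0
    censor_days: float = 21.0
    hypoxia: HypoxiaConfig = HypoxiaConfig()

    def schedule(self) -> dict[int, dict[int, float] | None]:
        return DEFAULT_SCHEDULE

    def dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.start)
        end = start + pd.DateOffset(months=self.n_months)
        return pd.date_range(start, end - pd.Timedelta(days=1), freq="D")


@dataclass
class ScenarioBundle:
    """All generated tables of one scenario, plus the ground truth."""

    config: ScenarioConfig
    smus: list[Smu]
    receivers: pd.DataFrame
    tags: pd.DataFrame
    detections: pd.DataFrame
    do_daily: pd.DataFrame
    catch: pd.DataFrame
    true_tracks: pd.DataFrame
    true_occupancy: pd.DataFrame


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ["do", "tracks", "detections", "catch"]
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


def smu_id_of(district: int, side: str) -> str:
    return SOUTH_SMU[district] if side == "S" else NORTH_SMU[district]


def build_lake(config: ScenarioConfig) -> tuple[list[Smu], pd.DataFrame]:
    """Construct the 8 SMU rectangles and the receiver grid.

    Receivers sit on a regular grid at ``receiver_spacing_km``; every
    central-basin (district 2-3) receiver carries a DO logger.  Bottom
    depth is the district mean plus a smooth positional undulation.
    """
    smus: list[Smu] = []
    for d in range(1, 5):
        x0 = LON_WEST + (d - 1) * DISTRICT_WIDTH_DEG
        x1 = x0 + DISTRICT_WIDTH_DEG
        for side, (lat0, lat1) in (("S", (LAT_SOUTH, LAT_MID)), ("N", (LAT_MID, LAT_NORTH))):
            sid = smu_id_of(d, side)
            juris = sid.split(" ", 1)[1]
            smus.append(
                Smu(
                    smu_id=sid,
                    district=d,
                    jurisdiction=juris,
                    ordinal_code=(d - 1) * 2 + (1 if side == "S" else 2),
                    polygon=box(x0, lat0, x1, lat1),
                )
            )

    dlon = config.receiver_spacing_km / KM_PER_DEG_LON
    dlat = config.receiver_spacing_km / KM_PER_DEG_LAT
    lon_east = LON_WEST + 4 * DISTRICT_WIDTH_DEG
    lons = np.arange(LON_WEST + dlon / 2, lon_east, dlon)
    lats = np.arange(LAT_SOUTH + dlat / 2, LAT_NORTH, dlat)
    if len(lons) == 0 or len(lats) == 0:
        raise ValueError("receiver spacing larger than the lake extent")
    gl, gt = np.meshgrid(lons, lats)
    lon_flat, lat_flat = gl.ravel(), gt.ravel()
    district = np.clip(((lon_flat - LON_WEST) / DISTRICT_WIDTH_DEG).astype(int) + 1, 1, 4)
    side = np.where(lat_flat < LAT_MID, "S", "N")
    depth = (
        np.vectorize(DISTRICT_DEPTH_M.get)(district)
        + 2.0 * np.sin(lon_flat * 9.0) * np.cos(lat_flat * 7.0)
    )
    receivers = pd.DataFrame(
        {
            "receiver_id": [f"R{i:04d}" for i in range(len(lon_flat))],
            "lon": lon_flat,
            "lat": lat_flat,
            "bottom_depth_m": np.round(depth, 2),
            "has_logger": np.isin(district, (2, 3)),
            "smu_id": [smu_id_of(d, s) for d, s in zip(district, side)],
            "district": district,
        }
    )
    return smus, receivers


def _severity_curve(dates: pd.DatetimeIndex, hyp: HypoxiaConfig) -> np.ndarray:
    """Smooth 0..1 drawdown over the hypoxic season (sin^2 bell)."""
    years = dates.year.to_numpy()
    t = dates.to_numpy().astype("datetime64[D]").astype(float)
    bell = np.zeros(len(dates))
    for y in np.unique(years):
        w0 = np.datetime64(f"{y}-{hyp.onset_month:02d}-01").astype(float)
        w1 = (
            np.datetime64(f"{y}-{hyp.end_month:02d}-01").astype("datetime64[M]")
            + np.timedelta64(1, "M")
        ).astype("datetime64[D]").astype(float)
        inside = (t >= w0) & (t < w1)
        x = (t[inside] - w0) / (w1 - w0)
        bell[inside] = np.sin(np.pi * x) ** 2
    return bell


def simulate_do_field(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily bottom DO per SMU, plus noisy logger readings at logger
    receivers.  Central-basin districts draw down below the hypoxia
    threshold at peak season per the severity curve; the western and
    eastern districts stay normoxic."""
    dates = config.dates()
    hyp = config.hypoxia
    bell = _severity_curve(dates, hyp)
    doy = dates.dayofyear.to_numpy()
    wiggle = 0.4 * np.sin(2 * np.pi * doy / 365.0)
    frames = []
    for smu in SMU_ORDER:
        district = int(smu.split(" ")[0])
        do = hyp.do_base_mg_l + wiggle.copy()
        if district in hyp.districts:
            do = do - hyp.severity * (hyp.do_base_mg_l - hyp.do_min_mg_l) * bell
        frames.append(
            pd.DataFrame(
                {
                    "date": dates.date,
                    "location_type": "smu",
                    "location_id": smu,
                    "do_mg_l": np.maximum(do, 0.05),
                    "temp_c": 12.0 + 10.0 * np.sin(2 * np.pi * (doy - 120) / 365.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _logger_readings(
    config: ScenarioConfig,
    do_smu: pd.DataFrame,
    receivers: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    loggers = receivers[receivers["has_logger"]]
    smu_series = do_smu.pivot_table(index="date", columns="location_id", values="do_mg_l")
    frames = []
    for _, row in loggers.iterrows():
        base = smu_series[row["smu_id"]]
        noise = rng.normal(0.0, config.logger_noise_sd, len(base))
        frames.append(
            pd.DataFrame(
                {
                    "date": base.index,
                    "location_type": "receiver",
                    "location_id": row["receiver_id"],
                    "do_mg_l": np.maximum(base.to_numpy() + noise, 0.0),
                    "temp_c": np.nan,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_tracks(
    config: ScenarioConfig, do_field: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Daily district/side tracks from the month-dependent movement kernel.

    Each day a fish moves at most one district: toward the monthly target
    district when the schedule names one, as an unbiased random walk in the
    summer window.  When the fish's current SMU is hypoxic that day, the
    eastward step probability is multiplied by (1 + avoidance_strength).
    Fish switch lake sides rarely, with a southward pull in November
    (spawning aggregation in the south-western SMU).  True depth follows
    the demersal mean of the current district with small noise.
    """
    dates = config.dates()
    n = config.n_fish
    schedule = config.schedule()
    smu_do = do_field[do_field["location_type"] == "smu"].pivot_table(
        index="date", columns="location_id", values="do_mg_l"
    )
    hypoxic_by_date = smu_do < config.do_threshold_mg_l

    district = rng.choice([2, 3], size=n)
    side = np.where(rng.random(n) < 0.75, "S", "N")
    recs = {"tag_id": [], "date": [], "district": [], "side": [], "depth_m": []}
    tag_ids = [f"T{i:03d}" for i in range(n)]

    for day in dates:
        month = day.month
        kernel = schedule.get(month)
        if kernel is None:
            p_east = np.full(n, config.summer_move_prob / 2)
            p_west = np.full(n, config.summer_move_prob / 2)
        else:
            targets = rng.choice(
                list(kernel.keys()), size=n, p=np.array(list(kernel.values()))
            )
            step = np.sign(targets - district)
            p_east = np.where(step > 0, config.move_prob, 0.0) + np.where(
                step == 0, config.drift_prob / 2, 0.0
            )
            p_west = np.where(step < 0, config.move_prob, 0.0) + np.where(
                step == 0, config.drift_prob / 2, 0.0
            )
        if config.avoidance_strength > 0:
            hyp_row = hypoxic_by_date.loc[day.date()]
            cur_smu = [smu_id_of(d, s) for d, s in zip(district, side)]
            is_hyp = hyp_row[cur_smu].to_numpy()
            p_east = np.where(is_hyp, p_east * (1 + config.avoidance_strength), p_east)
        p_east = np.where(district == 4, 0.0, p_east)
        p_west = np.where(district == 1, 0.0, p_west)
        total = p_east + p_west
        scale = np.where(total > 0.95, 0.95 / np.maximum(total, 1e-12), 1.0)
        p_east, p_west = p_east * scale, p_west * scale
        u = rng.random(n)
        district = district + np.where(u < p_east, 1, 0) - np.where(
            (u >= p_east) & (u < p_east + p_west), 1, 0
        )

        if month == 11:
            to_south = (side == "N") & (rng.random(n) < config.spawn_south_pull)
            to_north = (side == "S") & (rng.random(n) < 0.005)
        else:
            flip = rng.random(n) < config.side_switch_prob
            to_south = (side == "N") & flip
            to_north = (side == "S") & flip
        side = np.where(to_south, "S", np.where(to_north, "N", side))

        depth = (
            np.vectorize(DISTRICT_DEPTH_M.get)(district)
            - 1.0
            + rng.normal(0.0, config.depth_jitter_sd_m, n)
        )
        recs["tag_id"].append(tag_ids)
        recs["date"].append(np.full(n, day.date()))
        recs["district"].append(district.copy())
        recs["side"].append(side.copy())
        recs["depth_m"].append(np.clip(depth, 0.5, None))

    out = pd.DataFrame({k: np.concatenate(v) for k, v in recs.items()})
    out["smu_id"] = [smu_id_of(d, s) for d, s in zip(out["district"], out["side"])]
    return out.sort_values(["tag_id", "date"], kind="stable").reset_index(drop=True)


def simulate_detections(
    tracks: pd.DataFrame,
    receivers: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection records and tag metadata from the true tracks.

    A fish is located at one receiver of its current SMU (re-stationing
    with a small daily probability, always on SMU change — detection range
    ~1 km is far below receiver spacing, so only that receiver hears it).
    Detections arrive in encounter bursts, as they do on real receiver
    arrays: each fish-day holds at least one and on average
    ``burst_rate_per_day`` bursts at uniform times, a burst logs on average
    ``mean_burst_detections`` transmissions spaced ``transmit_interval_s``
    apart, and every logged transmission is retained with probability
    ``detection_p_per_transmission``.  Recorded depth = true depth plus
    N(0, depth_sensor_sd_m) sensor noise.  A configurable fraction of tags
    falls silent within the first weeks (early mortality/tag failure), and
    no tag transmits past its battery life.
    """
    pools = {
        smu: idx.to_numpy()
        for smu, idx in receivers.groupby("smu_id").groups.items()
    }
    rec_ids = receivers["receiver_id"].to_numpy()

    df = tracks.sort_values(["tag_id", "date"], kind="stable").reset_index(drop=True)
    tag_arr = df["tag_id"].to_numpy()
    smu_arr = df["smu_id"].to_numpy()
    new_tag = np.r_[True, tag_arr[1:] != tag_arr[:-1]]
    smu_change = np.r_[True, smu_arr[1:] != smu_arr[:-1]] | new_tag
    restation = rng.random(len(df)) < config.restation_prob
    event = smu_change | restation
    seg = np.cumsum(event) - 1
    n_seg = seg[-1] + 1
    seg_first = np.flatnonzero(event)
    seg_rec = np.empty(n_seg, dtype=int)
    for s, i in enumerate(seg_first):
        pool = pools[smu_arr[i]]
        seg_rec[s] = pool[rng.integers(len(pool))]
    df["receiver_id"] = rec_ids[seg_rec[seg]]

    # tag metadata and per-tag active window
    tag_ids = sorted(df["tag_id"].unique())
    n = len(tag_ids)
    site_idx = np.arange(n) % len(TAG_SITES)
    meta_rows = []
    release = pd.Timestamp(config.start, tz="UTC")
    n_early = int(np.floor(config.early_silence_fraction * n))
    early = set(rng.choice(n, size=n_early, replace=False).tolist()) if n_early else set()
    last_day = {}
    for i, tid in enumerate(tag_ids):
        site, model, battery, mu, sd = TAG_SITES[site_idx[i]]
        meta_rows.append(
            {
                "tag_id": tid,
                "release_site": site,
                "release_time": release,
                "total_length_mm": float(np.round(rng.normal(mu, sd), 1)),
                "tag_model": model,
                "battery_days": battery,
                "fate_override": "",
            }
        )
        cutoff = battery
        if i in early:
            cutoff = min(cutoff, int(rng.integers(5, 26)))
        last_day[tid] = cutoff
    tags = pd.DataFrame(meta_rows)

    day_index = df.groupby("tag_id").cumcount().to_numpy()
    active = day_index < np.vectorize(last_day.get)(tag_arr)
    df = df[active].reset_index(drop=True)

    # encounter bursts: >= 1 per fish-day so p=1 detects every tracked day
    nb = np.maximum(rng.poisson(config.burst_rate_per_day, len(df)), 1)
    burst_day = np.repeat(np.arange(len(df)), nb)
    m = 1 + rng.poisson(config.mean_burst_detections - 1.0, len(burst_day))
    interval_s = np.int64(round(config.transmit_interval_s))
    latest_start = np.maximum(86400 - m * interval_s, 1)
    burst_start = (rng.random(len(burst_day)) * latest_start).astype(np.int64)
    rep = np.repeat(burst_day, m)
    cum = np.cumsum(m)
    within = np.arange(int(cum[-1]) if len(m) else 0, dtype=np.int64) - np.repeat(cum - m, m)
    # whole-second timestamps, as receiver logs record them
    offsets = (np.repeat(burst_start, m) + within * interval_s) * (10**9)

    keep_p = rng.random(len(rep)) < config.detection_p_per_transmission
    rep, offsets = rep[keep_p], offsets[keep_p]
    day_start = pd.to_datetime(df["date"]).dt.tz_localize("UTC").astype("int64").to_numpy()
    timestamps = pd.to_datetime(day_start[rep] + offsets, utc=True)
    depth = df["depth_m"].to_numpy()[rep] + rng.normal(
        0.0, config.depth_sensor_sd_m, len(rep)
    )
    detections = pd.DataFrame(
        {
            "tag_id": df["tag_id"].to_numpy()[rep],
            "receiver_id": df["receiver_id"].to_numpy()[rep],
            "timestamp": timestamps,
            "tag_depth_m": np.round(np.maximum(depth, 0.0), 2),
        }
    )
    detections = detections.sort_values(["tag_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )
    return detections, tags


def simulate_catch(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Poisson-lognormal yearly catch draws around the intensity profile
    (the published mean-catch matrix), so the November district-1-south
    cell has the largest expected value by construction."""
    profile = published_mean_catch()
    y0, y1 = config.catch_years
    sigma = config.catch_sigma
    rows = []
    for year in range(y0, y1 + 1):
        lam = profile["mean_catch_lb"].to_numpy(dtype=float) * config.catch_intensity_scale
        mult = rng.lognormal(-0.5 * sigma**2, sigma, len(lam))
        pounds = rng.poisson(lam * mult)
        rows.append(
            pd.DataFrame(
                {
                    "year": year,
                    "month": profile["month"],
                    "smu_id": profile["smu_id"],
                    "pounds": pounds,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def true_occupancy(tracks: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth days per tag x year x month x SMU (one day per row of
    the daily track)."""
    df = tracks.copy()
    d = pd.to_datetime(df["date"])
    df["year"] = d.dt.year
    df["month"] = d.dt.month
    out = (
        df.groupby(["tag_id", "year", "month", "smu_id"])
        .size()
        .rename("days")
        .astype(float)
        .reset_index()
    )
    return out


def simulate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Generate the full bundle: lake, DO field, tracks, detections, catch,
    and ground truth.  Deterministic per ``config.seed``."""
    streams = _streams(config.seed)
    smus, receivers = build_lake(config)
    do_smu = simulate_do_field(config, streams["do"])
    do_logger = _logger_readings(config, do_smu, receivers, streams["do"])
    do_daily = pd.concat([do_smu, do_logger], ignore_index=True)
    tracks = simulate_tracks(config, do_smu, streams["tracks"])
    detections, tags = simulate_detections(tracks, receivers, config, streams["detections"])
    catch = simulate_catch(config, streams["catch"])
    return ScenarioBundle(
        config=config,
        smus=smus,
        receivers=receivers,
        tags=tags,
        detections=detections,
        do_daily=do_daily,
        catch=catch,
        true_tracks=tracks,
        true_occupancy=true_occupancy(tracks),
    )


def write_bundle(bundle: ScenarioBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the exact CSV/GeoJSON dialects the QC stage
    reads, plus the ground-truth files used by recovery tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    det = bundle.detections.copy()
    det["timestamp_utc"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    det[["tag_id", "receiver_id", "timestamp_utc", "tag_depth_m"]].to_csv(
        out / "detections.csv", index=False
    )
    paths["detections"] = out / "detections.csv"

    bundle.receivers[["receiver_id", "lon", "lat", "bottom_depth_m", "has_logger"]].to_csv(
        out / "receivers.csv", index=False
    )
    paths["receivers"] = out / "receivers.csv"

    tags = bundle.tags.copy()
    tags["release_time_utc"] = pd.to_datetime(tags["release_time"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    tags[
        ["tag_id", "release_site", "release_time_utc", "total_length_mm",
         "tag_model", "battery_days", "fate_override"]
    ].to_csv(out / "tags.csv", index=False)
    paths["tags"] = out / "tags.csv"

    write_smus_geojson(bundle.smus, out / "smus.geojson")
    paths["smus"] = out / "smus.geojson"

    bundle.catch.to_csv(out / "catch.csv", index=False)
    paths["catch"] = out / "catch.csv"
    bundle.do_daily.to_csv(out / "do_daily.csv", index=False)
    paths["do_daily"] = out / "do_daily.csv"
    bundle.true_tracks.to_csv(out / "true_tracks.csv", index=False)
    paths["true_tracks"] = out / "true_tracks.csv"
    bundle.true_occupancy.to_csv(out / "true_occupancy.csv", index=False)
    paths["true_occupancy"] = out / "true_occupancy.csv"
    return paths
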