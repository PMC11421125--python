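"""GPS track tables, step construction, and covariate assignment.

Fixes are rows of (animal_id, iy_id, timestamp, x, y) with projected
coordinates in meters and a nominal 3-hour sampling rate. Steps join
consecutive fixes; a step carries its length l, turning angle phi (signed,
counterclockwise positive, wrapped to (-pi, pi], undefined at the start of a
contiguous segment), absolute bearing, endpoint coordinates, endpoint
covariates, and the two temporal factors used by the habitat-selection
models: hunting pressure (none / high / low, from the Swedish moose-season
calendar) and time of day (day / night by solar elevation).
"""

from __future__ import annotations

import logging
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd

from .raster import Raster

__all__ = [
    "read_tracks",
    "write_tracks",
    "filter_season",
    "build_steps",
    "hunting_season_opener",
    "assign_hunting_pressure",
    "solar_elevation",
    "assign_time_of_day",
    "extract_covariates",
    "zscore_by_individual",
    "COVARIATE_NAMES",
]

logger = logging.getLogger(__name__)

COVARIATE_NAMES = ("dist_forest", "dist_settlement", "dist_road")
REQUIRED_COLUMNS = ("animal_id", "iy_id", "timestamp", "x", "y")

NOMINAL_INTERVAL = pd.Timedelta(hours=3)
GAP_TOLERANCE = pd.Timedelta(minutes=15)


def read_tracks(path) -> pd.DataFrame:
    """Read a GPS fix table from CSV, validate, and sort.

    Requires columns animal_id, iy_id, timestamp (ISO-8601, UTC assumed if
    naive), x, y. Rejects duplicate timestamps within an individual-year.
    """
    fixes = pd.read_csv(path)
    if fixes.empty:
        raise ValueError(f"empty GPS file: {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"GPS file {path} missing column(s): {', '.join(missing)}")
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    if fixes[["x", "y"]].isna().any().any():
        bad = fixes.index[fixes[["x", "y"]].isna().any(axis=1)].tolist()
        raise ValueError(f"non-numeric coordinates at rows {bad[:10]}")
    fixes = fixes.sort_values(["iy_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )
    dup = fixes.duplicated(subset=["iy_id", "timestamp"])
    if dup.any():
        row = fixes[dup].iloc[0]
        raise ValueError(
            f"duplicate timestamp {row['timestamp']} within iy_id {row['iy_id']}"
        )
    return fixes


def write_tracks(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def filter_season(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep fixes from Aug 1 through Dec 31 (months 8–12) of each year."""
    ts = pd.to_datetime(fixes["timestamp"], utc=True)
    keep = ts.dt.month.isin([8, 9, 10, 11, 12])
    kept = fixes[keep].reset_index(drop=True)
    for iy, n in fixes.groupby("iy_id").size().items():
        n_kept = int((kept["iy_id"] == iy).sum())
        if n_kept < n:
            logger.info("filter_season: %s kept %d/%d fixes", iy, n_kept, n)
    return kept


def build_steps(
    fixes: pd.DataFrame,
    nominal_interval: pd.Timedelta = NOMINAL_INTERVAL,
    tolerance: pd.Timedelta = GAP_TOLERANCE,
) -> pd.DataFrame:
    """Construct steps from consecutive fixes at the nominal interval.

    A step joins two fixes whose spacing is within ``tolerance`` of
    ``nominal_interval``; larger or smaller gaps break contiguity, starting a
    new segment (``seg_id``). The turning angle phi is the signed difference
    of consecutive bearings within a segment, counterclockwise positive,
    wrapped to (-pi, pi]; it is NaN for the first step of each segment.
    Individual-years with fewer than 3 contiguous fixes everywhere are
    dropped with a warning.
    """
    if nominal_interval <= pd.Timedelta(0):
        raise ValueError("nominal interval must be positive")
    from .hmm import wrap_angle

    out = []
    for iy, g in fixes.groupby("iy_id", sort=False):
        g = g.sort_values("timestamp")
        ts = pd.to_datetime(g["timestamp"], utc=True).dt.tz_localize(None).to_numpy()
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        dt = np.diff(ts)
        ok = np.abs(dt - nominal_interval.to_numpy()) <= tolerance.to_numpy()
        if not ok.any():
            logger.warning("build_steps: %s has no contiguous fixes; dropped", iy)
            continue
        # segment label per step: breaks wherever a gap interrupts
        seg = np.concatenate([[0], np.cumsum(~ok)])[:-1]
        dx = np.diff(x)
        dy = np.diff(y)
        l = np.hypot(dx, dy)
        bearing = np.arctan2(dy, dx)
        phi = np.full(l.shape, np.nan)
        same_seg = seg[1:] == seg[:-1]
        phi[1:][same_seg] = wrap_angle(bearing[1:][same_seg] - bearing[:-1][same_seg])
        df = pd.DataFrame(
            {
                "iy_id": iy,
                "seg_id": [f"{iy}#{s}" for s in seg],
                "t_end": ts[1:],
                "start_x": x[:-1],
                "start_y": y[:-1],
                "end_x": x[1:],
                "end_y": y[1:],
                "l": l,
                "bearing": bearing,
                "phi": phi,
            }
        )
        df = df[ok]
        # re-derive phi validity: after dropping gap rows, first row of each
        # segment keeps phi = NaN by construction above
        if len(df) < 2:
            logger.warning("build_steps: %s has <3 contiguous fixes; dropped", iy)
            continue
        out.append(df)
    if not out:
        raise ValueError("no individual-year produced any steps")
    steps = pd.concat(out, ignore_index=True)
    steps["t_end"] = pd.to_datetime(steps["t_end"], utc=True)
    return steps


# -- hunting-pressure calendar --------------------------------------------


def hunting_season_opener(year: int) -> date:
    """Second Monday of October: first day of the moose hunting season."""
    oct1 = date(year, 10, 1)
    first_monday = oct1 + timedelta(days=(7 - oct1.weekday()) % 7)
    return first_monday + timedelta(days=7)


def assign_hunting_pressure(t_end) -> pd.Series:
    """Hunting-pressure period of each timestamp.

    none: Aug 1 up to the day before the season opener; high: the opener and
    the following three weeks (21 calendar days in total); low: thereafter
    through Dec 31. Boundaries are whole calendar days.
    """
    ts = pd.to_datetime(pd.Series(t_end), utc=True)
    if ts.dt.month.isin([1, 2, 3, 4, 5, 6, 7]).any():
        bad = ts[ts.dt.month < 8].iloc[0]
        raise ValueError(f"timestamp outside the Aug-Dec window: {bad}")
    out = pd.Series("none", index=ts.index, dtype=object)
    for year in ts.dt.year.unique():
        opener = hunting_season_opener(int(year))
        start = pd.Timestamp(datetime.combine(opener, time.min), tz=timezone.utc)
        end_high = start + pd.Timedelta(days=21)  # exclusive
        in_year = ts.dt.year == year
        out[in_year & (ts >= start) & (ts < end_high)] = "high"
        out[in_year & (ts >= end_high)] = "low"
    return out


# -- time of day ----------------------------------------------------------


def solar_elevation(t, latitude: float, longitude: float) -> np.ndarray:
    """Solar elevation angle (degrees) of the sun's center, NOAA algorithm.

    `t` is a timestamp or array of timestamps (UTC assumed if naive).
    No atmospheric refraction: day is defined by geometric elevation >= 0.
    """
    ts = pd.to_datetime(pd.Series(np.atleast_1d(t)), utc=True)
    doy = ts.dt.dayofyear.to_numpy(dtype=float)
    hours = (
        ts.dt.hour + ts.dt.minute / 60 + ts.dt.second / 3600
    ).to_numpy(dtype=float)
    leap = ts.dt.is_leap_year.to_numpy()
    ndays = np.where(leap, 366.0, 365.0)

    g = 2 * np.pi / ndays * (doy - 1 + (hours - 12) / 24)  # fractional year, rad
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    tst = hours * 60.0 + eqtime + 4.0 * longitude  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle
    lat = np.deg2rad(latitude)
    cos_zen = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    elev = 90.0 - np.rad2deg(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    return elev if np.ndim(t) or isinstance(t, (pd.Series, list)) else float(elev[0])


def assign_time_of_day(t_end, latitude: float = 57.0, longitude: float = 15.5):
    """'day' iff the sun's center is at or above the horizon, else 'night'."""
    elev = np.atleast_1d(solar_elevation(t_end, latitude, longitude))
    out = np.where(elev >= 0.0, "day", "night")
    if np.ndim(t_end) or isinstance(t_end, (pd.Series, list, np.ndarray)):
        return pd.Series(out, index=getattr(t_end, "index", None))
    return str(out[0])


# -- covariates -----------------------------------------------------------


def extract_covariates(steps: pd.DataFrame, rasters: dict[str, Raster]) -> pd.DataFrame:
    """Attach raster values at step endpoints (nearest-cell semantics)."""
    steps = steps.copy()
    ref = next(iter(rasters.values()))
    inside = ref.contains(steps["end_x"].to_numpy(), steps["end_y"].to_numpy())
    if not np.all(inside):
        bad = steps.index[~inside].tolist()
        raise ValueError(f"step endpoints outside raster extent at rows {bad[:20]}")
    for name, raster in rasters.items():
        steps[name] = raster.value_at(
            steps["end_x"].to_numpy(), steps["end_y"].to_numpy()
        )
    return steps


def zscore_by_individual(
    table: pd.DataFrame,
    columns=COVARIATE_NAMES,
    group: str = "iy_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize covariates to mean 0, SD 1 within each individual-year.

    Uses the sample SD (n-1 denominator), computed over all rows of the unit
    (used and available endpoints jointly when applied to strata tables).
    Returns the transformed table and a parameter table (group, column,
    mean, sd) for back-transformation. Zero variance within a unit is an
    error naming the unit and covariate.
    """
    table = table.copy()
    params = []
    for unit, g in table.groupby(group, sort=False):
        for col in columns:
            v = g[col].to_numpy(dtype=float)
            if len(v) < 2:
                raise ValueError(f"fewer than 2 values for {col} in {group}={unit}")
            mu = v.mean()
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero-variance covariate {col} in {group}={unit}")
            table.loc[g.index, col] = (v - mu) / sd
            params.append({group: unit, "column": col, "mean": mu, "sd": sd})
    return table, pd.DataFrame(params)
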