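"""Per-file predictor assignment: lunar phase, tidal phase, day/night, season.

All timestamps in this package are timezone-naive UTC; each recording station
carries a fixed UTC offset (hours) that converts to the local civil time used
for hour-of-day, diel and weekday assignment.

Lunar and tidal phases are quarter-cycle categorizations: the synodic month
(29.530588 d) is split into four equal windows centered on the new, first
quarter, full, and third quarter moments, and each semidiurnal tidal cycle is
split into quartiles centered on the high and low water extrema.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

SYNODIC_DAYS = 29.530588

#: A reference new moon (UTC) close to the default simulated period.
DEFAULT_NEW_MOON = dt.datetime(2017, 12, 18, 6, 30)

LUNAR_CATEGORIES = ("new", "first_quarter", "full", "third_quarter")
TIDAL_CATEGORIES = ("high", "falling", "low", "rising")
SEASONS = ("winter", "spring", "summer", "fall")

#: Astronomical season start dates (month, day), Northern Hemisphere.
SEASON_STARTS = {"spring": (3, 20), "summer": (6, 21),
                 "fall": (9, 22), "winter": (12, 21)}


# ----------------------------------------------------------------------------
# Lunar phase
# ----------------------------------------------------------------------------

def lunar_phase(t, reference_new_moon: dt.datetime = DEFAULT_NEW_MOON):
    """Quarter-cycle lunar category for timestamp(s) *t*.

    The phase fraction ``f = ((t − ref) / synodic_month) mod 1`` maps to
    categories: new for f in [0.875, 1) ∪ [0, 0.125), first_quarter
    [0.125, 0.375), full [0.375, 0.625), third_quarter [0.625, 0.875).
    """
    ts = pd.to_datetime(t)
    scalar = not isinstance(ts, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([ts]) if scalar else pd.DatetimeIndex(ts)
    frac = ((idx - pd.Timestamp(reference_new_moon)).total_seconds()
            / (SYNODIC_DAYS * 86400.0)) % 1.0
    cat = np.select(
        [frac < 0.125, frac < 0.375, frac < 0.625, frac < 0.875],
        ["new", "first_quarter", "full", "third_quarter"], default="new")
    return cat[0] if scalar else np.asarray(cat)


# ----------------------------------------------------------------------------
# Tidal phase
# ----------------------------------------------------------------------------

def _tidal_extrema(depth_series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Alternating (times_ns, is_high) extrema of a depth record."""
    depth = depth_series.to_numpy(dtype=float)
    times = depth_series.index.asi8
    # Semidiurnal period 12.42 h; require peaks at least half a cycle apart.
    step_s = np.median(np.diff(times)) / 1e9
    dist = max(1, int(0.4 * 12.42 * 3600 / step_s))
    highs, _ = find_peaks(depth, distance=dist)
    lows, _ = find_peaks(-depth, distance=dist)
    order = np.argsort(np.concatenate([highs, lows]))
    idx = np.concatenate([highs, lows])[order]
    is_high = np.concatenate([np.ones_like(highs), np.zeros_like(lows)])[order]
    return times[idx], is_high.astype(bool)


def tidal_phase(t, depth_series: pd.Series):
    """Tidal category at timestamp(s) *t* from a depth record.

    Each cycle between consecutive extrema is split in half-quartiles: the
    quarter-cycle centred on a high-water extremum is ``high``, the descending
    half-cycle core is ``falling``, and symmetrically for ``low``/``rising``.
    """
    ext_times, ext_is_high = _tidal_extrema(depth_series)
    if ext_times.size < 2:
        raise ValueError("depth series too short to locate tidal extrema")
    ts = pd.to_datetime(t)
    scalar = not isinstance(ts, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([ts]) if scalar else pd.DatetimeIndex(ts)
    tq = idx.asi8
    if tq.min() < ext_times[0] or tq.max() > ext_times[-1]:
        raise ValueError("timestamp outside the span of located tidal extrema; "
                         "extend the depth series")
    pos = np.clip(np.searchsorted(ext_times, tq, side="right") - 1,
                  0, ext_times.size - 2)
    t0, t1 = ext_times[pos], ext_times[pos + 1]
    u = (tq - t0) / (t1 - t0)
    from_high = ext_is_high[pos]
    desc = np.select([u < 0.25, u < 0.75], ["high", "falling"], default="low")
    asc = np.select([u < 0.25, u < 0.75], ["low", "rising"], default="high")
    cat = np.where(from_high, desc, asc)
    return cat[0] if scalar else np.asarray(cat)


# ----------------------------------------------------------------------------
# Solar calculator and day/night
# ----------------------------------------------------------------------------

def _solar_events(date: dt.date, lat_deg: float, lon_deg: float,
                  utc_offset_h: float) -> tuple[dt.datetime, dt.datetime]:
    """NOAA-style sunrise/sunset (local civil time) for one date."""
    doy = date.timetuple().tm_yday
    # Fractional year (radians), evaluated at local noon.
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + (12 - utc_offset_h) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma)
                       - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma)
                       - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))
    lat = np.deg2rad(lat_deg)
    cos_ha = (np.cos(np.deg2rad(90.833)) / (np.cos(lat) * np.cos(decl))
              - np.tan(lat) * np.tan(decl))
    cos_ha = float(np.clip(cos_ha, -1.0, 1.0))
    ha = np.rad2deg(np.arccos(cos_ha))
    # Minutes UTC, then shifted to local civil time.
    noon_utc = 720 - 4 * lon_deg - eqtime
    rise_min = noon_utc - 4 * ha + utc_offset_h * 60
    set_min = noon_utc + 4 * ha + utc_offset_h * 60
    base = dt.datetime.combine(date, dt.time())
    return (base + dt.timedelta(minutes=float(rise_min)),
            base + dt.timedelta(minutes=float(set_min)))


def build_sun_table(start_date: dt.date, end_date: dt.date, lat_deg: float,
                    lon_deg: float, utc_offset_h: float) -> pd.DataFrame:
    """Sunrise/sunset table (local civil time) for [start_date, end_date]."""
    rows = []
    d = start_date
    while d <= end_date:
        rise, sset = _solar_events(d, lat_deg, lon_deg, utc_offset_h)
        rows.append({"date": d, "sunrise": rise, "sunset": sset})
        d += dt.timedelta(days=1)
    return pd.DataFrame(rows).set_index("date")


def day_night(t_local, sun_table: pd.DataFrame):
    """Classify local timestamp(s) as day (sunrise ≤ t < sunset) or night."""
    ts = pd.to_datetime(t_local)
    scalar = not isinstance(ts, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([ts]) if scalar else pd.DatetimeIndex(ts)
    out = np.empty(idx.size, dtype=object)
    dates = idx.normalize()
    for i, (t, d) in enumerate(zip(idx, dates)):
        key = d.date()
        if key not in sun_table.index:
            raise KeyError(f"sun table has no entry for date {key}")
        row = sun_table.loc[key]
        out[i] = "day" if row["sunrise"] <= t < row["sunset"] else "night"
    return out[0] if scalar else out


# ----------------------------------------------------------------------------
# Season
# ----------------------------------------------------------------------------

def season(t):
    """Astronomical season: spring from Mar 20, summer Jun 21, fall Sep 22,
    winter Dec 21 (year-wrapped)."""
    ts = pd.to_datetime(t)
    scalar = not isinstance(ts, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([ts]) if scalar else pd.DatetimeIndex(ts)
    md = idx.month * 100 + idx.day
    cat = np.select(
        [md < 320, md < 621, md < 922, md < 1221],
        ["winter", "spring", "summer", "fall"], default="winter")
    return cat[0] if scalar else np.asarray(cat)


# ----------------------------------------------------------------------------
# Assembly
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateConfig:
    lunar_reference: dt.datetime = DEFAULT_NEW_MOON
    temp_match_tolerance_s: float = 600.0  # logger sample within 10 min


def nearest_temperature(times: pd.DatetimeIndex, env: pd.DataFrame,
                        tolerance_s: float = 600.0) -> np.ndarray:
    """Nearest-sample water temperature for each timestamp (NaN if no
    environmental sample lies within the tolerance)."""
    env_times = env.index.asi8
    tq = times.asi8
    pos = np.clip(np.searchsorted(env_times, tq), 1, env_times.size - 1)
    left, right = env_times[pos - 1], env_times[pos]
    use_right = (right - tq) < (tq - left)
    nearest = np.where(use_right, pos, pos - 1)
    dist_s = np.abs(env_times[nearest] - tq) / 1e9
    temp = env["water_temp_c"].to_numpy()[nearest]
    return np.where(dist_s <= tolerance_s, temp, np.nan)


def assemble_covariates(schedule: pd.DataFrame, env: pd.DataFrame,
                        sun_tables: dict[str, pd.DataFrame],
                        utc_offsets: dict[str, float],
                        config: CovariateConfig = CovariateConfig()) -> pd.DataFrame:
    """One covariate row per file.

    ``schedule`` needs columns ``file_id, station, start`` (UTC); ``env`` is
    indexed by UTC timestamp with ``water_temp_c`` and ``depth_m`` columns;
    ``sun_tables`` maps station -> sunrise/sunset table in that station's
    local time.  Files whose temperature cannot be matched within the
    tolerance are flagged ``missing_env`` (callers exclude them from models).
    """
    rows = []
    for station, grp in schedule.groupby("station", sort=False):
        starts = pd.DatetimeIndex(grp["start"])
        offset = pd.Timedelta(hours=utc_offsets[station])
        local = starts + offset
        temp = nearest_temperature(starts, env, config.temp_match_tolerance_s)
        diel = day_night(local, sun_tables[station])
        tidal = tidal_phase(starts, env["depth_m"])
        lunar = lunar_phase(starts, config.lunar_reference)
        rows.append(pd.DataFrame({
            "file_id": grp["file_id"].to_numpy(),
            "station": station,
            "timestamp": starts,
            "month": local.month,
            "local_hour": local.hour + local.minute / 60.0,
            "water_temp_c": temp,
            "lunar_phase": lunar,
            "tidal_phase": tidal,
            "diel": np.asarray(diel, dtype=object),
            "weekday": local.day_name(),
            "season": season(local),
            "missing_env": np.isnan(temp),
        }))
    out = pd.concat(rows, ignore_index=True)
    n_missing = int(out["missing_env"].sum())
    if n_missing:
        import logging
        logging.getLogger(__name__).warning(
            "%d files lack a matched environmental sample", n_missing)
    return out
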