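"""Manual-review data model and the survey summary tables.

An annotation row holds, per 2-minute file: an intensity score 0–3 for each
fish species (0 = no calls, 1 = one call, 2 = multiple calls, 3 = overlapping
calls / chorusing), dolphin vocalization counts by type, and binary flags for
anthropogenic noise, rain, and right-whale presence.

The summaries reproduce the survey's tabular semantics: per-station
prevalence (detection counts, percentages to one decimal with half-up
rounding, and summed intensities/counts), chorusing timelines (first/last
calling dates at intensity >= 2, temperatures at the endpoints, and the number
of distinct chorusing days at intensity 3), and the anthropogenic-noise
exclusion subset used for the biological SPL re-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .covariates import nearest_temperature
from .scene_sim import FISH_SPECIES

log = logging.getLogger(__name__)

DOLPHIN_COLS = ("dolphin_echolocation", "dolphin_whistles", "dolphin_burst")

#: Fish intensity counting as a detection, and as a "calling date".
DETECTION_THRESHOLD = 1
CALLING_THRESHOLD = 2
CHORUS_SCORE = 3


def percent_1dp(count: int, total: int) -> float:
    """Percentage to one decimal, round-half-up (survey-table convention)."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def hourly_subsample(table: pd.DataFrame) -> pd.DataFrame:
    """Keep the file starting on the hour (minute 00) from the 20-min grid,
    mirroring the one-file-per-hour manual review protocol."""
    if table.empty:
        return table.copy()
    ts = pd.DatetimeIndex(table["timestamp"] if "timestamp" in table
                          else table["start"])
    return table.loc[ts.minute == 0].reset_index(drop=True)


def prevalence_table(annotations: pd.DataFrame,
                     fish_species: tuple[str, ...] = FISH_SPECIES,
                     detection_threshold: int = DETECTION_THRESHOLD) -> pd.DataFrame:
    """Per station x sound class: files with detections, percent, summed
    intensity (fish) or summed counts (dolphins).

    The total-fish row counts each file once no matter how many species
    called in it (a union, so the total can be below the per-species sum).
    """
    present = [sp for sp in fish_species if sp in annotations.columns]
    rows = []
    for station, grp in annotations.groupby("station", sort=True):
        n = len(grp)

        def add(sound_class, detections, sum_int):
            rows.append({"station": station, "sound_class": sound_class,
                         "files_with_detections": int(detections),
                         "percent": percent_1dp(int(detections), n),
                         "sum_intensity": sum_int, "files_reviewed": n})

        any_fish = np.zeros(n, dtype=bool)
        for sp in present:
            scores = grp[sp].to_numpy()
            det = scores >= detection_threshold
            any_fish |= det
            add(sp, det.sum(), int(scores.sum()))
        add("total_fish", any_fish.sum(), np.nan)
        for col in DOLPHIN_COLS:
            counts = grp[col].to_numpy()
            add(col, (counts >= 1).sum(), int(counts.sum()))
        dol_sum = grp["dolphin_sum"].to_numpy()
        add("dolphin_sum", (dol_sum >= 1).sum(), int(dol_sum.sum()))
        for col in ("noise", "rain", "right_whale"):
            if col in grp:
                add(col, int(grp[col].sum()), np.nan)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChorusTimeline:
    station: str
    species: str
    year: int
    first_calling_date: object   # date or None
    last_calling_date: object
    temp_at_first: float
    temp_at_last: float
    days_chorusing: int
    open_ended: bool


def chorusing_timeline(annotations: pd.DataFrame, env: pd.DataFrame,
                       fish_species: tuple[str, ...] = FISH_SPECIES,
                       calling_threshold: int = CALLING_THRESHOLD,
                       chorus_score: int = CHORUS_SCORE,
                       open_end_window_days: int = 7) -> pd.DataFrame:
    """Per station/species/year calling timeline.

    A "calling date" requires intensity >= 2; ``days_chorusing`` counts
    distinct calendar days containing at least one intensity-3 file.  When the
    last calling date falls within ``open_end_window_days`` of the end of that
    station's record, the season is flagged open-ended (the recording stopped
    before calling did) and the last date/temperature are not reported.
    """
    present = [sp for sp in fish_species if sp in annotations.columns]
    ts_all = pd.DatetimeIndex(annotations["timestamp"])
    rows = []
    for station, grp in annotations.groupby("station", sort=True):
        ts = pd.DatetimeIndex(grp["timestamp"])
        record_end = ts.max()
        for year, ygrp in grp.groupby(ts.year):
            yts = pd.DatetimeIndex(ygrp["timestamp"])
            for sp in present:
                scores = ygrp[sp].to_numpy()
                calling = scores >= calling_threshold
                if not calling.any():
                    rows.append(ChorusTimeline(station, sp, int(year), None,
                                               None, np.nan, np.nan, 0, False))
                    continue
                call_ts = yts[calling]
                first, last = call_ts.min(), call_ts.max()
                chor_days = len(set(
                    yts[scores >= chorus_score].normalize()))
                open_ended = (record_end - last) <= pd.Timedelta(
                    days=open_end_window_days)
                t_first = float(nearest_temperature(
                    pd.DatetimeIndex([first]), env)[0])
                t_last = float(nearest_temperature(
                    pd.DatetimeIndex([last]), env)[0])
                rows.append(ChorusTimeline(
                    station, sp, int(year), first.date(),
                    None if open_ended else last.date(), t_first,
                    np.nan if open_ended else t_last, chor_days, open_ended))
    return pd.DataFrame([r.__dict__ for r in rows])


def exclude_noise(spl_table: pd.DataFrame, annotations: pd.DataFrame,
                  strict: bool = False) -> tuple[pd.DataFrame, dict]:
    """Drop SPL rows whose annotation flags anthropogenic noise.

    Returns the retained subset plus counts of retained/removed rows.  SPL
    files without an annotation are excluded with a warning (error in strict
    mode).
    """
    flags = annotations.set_index("file_id")["noise"]
    known = spl_table["file_id"].isin(flags.index)
    if not known.all():
        missing = spl_table.loc[~known, "file_id"].unique()
        msg = f"{len(missing)} SPL files lack annotations"
        if strict:
            raise ValueError(msg)
        log.warning("%s; excluding them", msg)
    matched = spl_table.loc[known].copy()
    noisy = flags.reindex(matched["file_id"]).to_numpy() == 1
    subset = matched.loc[~noisy].reset_index(drop=True)
    stats = {"retained": int(len(subset)),
             "removed_noise": int(noisy.sum()),
             "removed_unannotated": int((~known).sum())}
    return subset, stats
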