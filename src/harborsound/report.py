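"""Pipeline orchestration and tabular/visual outputs.

Temporal heat maps use a noon-to-noon layout (rows run from 12:00 to 11:59
the next day) so that overnight fish chorusing appears as a contiguous block;
gaps stay blank rather than being imputed.  Every figure-shaped output has a
CSV sidecar holding the exact plotted numbers — the CSVs are the tested
surface, image rendering is thin and optional.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import acoustics, annotations as ann, covariates as cov
from . import models, scene_sim

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------------
# Heat maps
# ----------------------------------------------------------------------------

@dataclass
class HeatmapMatrix:
    station: str
    quantity: str
    matrix: pd.DataFrame       # index: time-of-day bins from noon; cols: dates

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def build_heatmap(values: pd.DataFrame, quantity: str, grid: str = "20min",
                  station: str = "", value_col: str | None = None,
                  noon_aligned: bool = True) -> HeatmapMatrix:
    """Pivot a timestamped value series into a noon-to-noon day matrix.

    ``values`` needs ``timestamp`` plus a value column (``quantity`` by
    default).  Rows are the 72 twenty-minute (or 24 hourly) time-of-day bins
    starting at 12:00; columns are the calendar dates of the noon opening
    each row window.  Missing slots stay NaN; duplicate slots are an error.
    """
    step_min = {"20min": 20, "hourly": 60}[grid]
    value_col = value_col or quantity
    ts = pd.DatetimeIndex(values["timestamp"])
    shift = pd.Timedelta(hours=12) if noon_aligned else pd.Timedelta(0)
    shifted = ts - shift
    dates = shifted.normalize()
    minutes = shifted.hour * 60 + shifted.minute
    binned = (minutes // step_min) * step_min
    frame = pd.DataFrame({"date": dates.date, "bin": binned,
                          "value": values[value_col].to_numpy()})
    if frame.duplicated(["date", "bin"]).any():
        dup = frame.loc[frame.duplicated(["date", "bin"]), ["date", "bin"]]
        raise ValueError(f"duplicate heat map cells, first at {dup.iloc[0].tolist()}")
    mat = frame.pivot(index="bin", columns="date", values="value")
    origin = dt.time(12, 0) if noon_aligned else dt.time(0, 0)
    full_bins = range(0, 24 * 60, step_min)
    mat = mat.reindex(index=full_bins)
    mat.index = [
        f"{(origin.hour * 60 + b) // 60 % 24:02d}:{b % 60:02d}"
        for b in full_bins]
    mat.index.name = "time_of_day"
    return HeatmapMatrix(station, quantity, mat)


def render_heatmap_png(hm: HeatmapMatrix, path) -> None:
    """Optional image rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(10, 4))
    data = hm.matrix.to_numpy(dtype=float)
    im = ax.imshow(data, aspect="auto", origin="upper", cmap="viridis")
    ax.set_title(f"{hm.quantity} — {hm.station}")
    ax.set_xlabel("date")
    ax.set_ylabel("time of day (from noon)")
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ----------------------------------------------------------------------------
# Prevalence rendering
# ----------------------------------------------------------------------------

def prevalence_report(prevalence: pd.DataFrame) -> str:
    """Render the prevalence table as per-station blocks with
    ``count (percent%)`` cells."""
    lines = []
    for station, grp in prevalence.groupby("station", sort=True):
        n = int(grp["files_reviewed"].iloc[0])
        lines.append(f"== Station {station} ({n} files reviewed) ==")
        for row in grp.itertuples():
            cell = f"{row.files_with_detections} ({row.percent:.1f}%)"
            extra = ("" if pd.isna(row.sum_intensity)
                     else f"  sum={int(row.sum_intensity)}")
            lines.append(f"  {row.sound_class:<22s} {cell}{extra}")
        lines.append("")
    return "\n".join(lines)


def parse_prevalence_cell(cell: str) -> tuple[int, float]:
    """Inverse of the ``count (percent%)`` rendering."""
    count, rest = cell.split(" (")
    return int(count), float(rest.rstrip("%)"))


# ----------------------------------------------------------------------------
# Pipeline
# ----------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    output_dir: Path
    scene: scene_sim.SceneConfig
    rng_seed: int = 0
    model_trees: int = 100
    model_iters: int = 25
    run_models: bool = True

    @classmethod
    def demo(cls, output_dir, days: int = 14, seed: int = 0) -> "PipelineConfig":
        scene = scene_sim.default_scene_config(days=days, n_stations=1,
                                               rng_seed=seed)
        return cls(Path(output_dir), scene, rng_seed=seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate → SPL → covariates → summaries → models → manifest.

    Deterministic stages rerun bit-identically for the same config; the
    manifest records the seed, the config repr hash, and a SHA-256 of every
    artifact.  Any stage failure aborts with the stage named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "simulate"
    try:
        schedule = scene_sim.build_schedule(config.scene)
        env = scene_sim.simulate_environment(config.scene)
        truth = scene_sim.simulate_events(schedule, env, config.scene)
        annot = scene_sim.export_truth_annotations(truth)
        env.to_csv(out / "environment.csv", date_format="%Y-%m-%dT%H:%M:%SZ")
        annot.to_csv(out / "annotations.csv", index=False,
                     date_format="%Y-%m-%dT%H:%M:%SZ")
        artifacts["environment"] = out / "environment.csv"
        artifacts["annotations"] = out / "annotations.csv"

        stage = "spl"
        spl = scene_sim.spl_table_from_truth(truth)
        spl.to_csv(out / "band_spl.csv", index=False,
                   date_format="%Y-%m-%dT%H:%M:%SZ")
        artifacts["band_spl"] = out / "band_spl.csv"

        stage = "covariates"
        suns = scene_sim.sun_tables_for(config.scene)
        offsets = {st.name: st.utc_offset_h for st in config.scene.stations}
        covs = cov.assemble_covariates(scene_sim.schedule_frame(schedule),
                                       env, suns, offsets)
        covs.to_csv(out / "covariates.csv", index=False,
                    date_format="%Y-%m-%dT%H:%M:%SZ")
        artifacts["covariates"] = out / "covariates.csv"

        stage = "summaries"
        hourly = ann.hourly_subsample(annot)
        prev = ann.prevalence_table(hourly)
        prev.to_csv(out / "prevalence.csv", index=False)
        artifacts["prevalence"] = out / "prevalence.csv"
        (out / "prevalence.txt").write_text(prevalence_report(prev))
        artifacts["prevalence_text"] = out / "prevalence.txt"
        timeline = ann.chorusing_timeline(hourly, env)
        timeline.to_csv(out / "chorusing_timeline.csv", index=False)
        artifacts["chorusing_timeline"] = out / "chorusing_timeline.csv"
        station0 = config.scene.stations[0].name
        low = spl.loc[(spl["band"] == "low") & (spl["station"] == station0),
                      ["timestamp", "spl_db"]]
        hm = build_heatmap(low, "spl_db", grid="20min", station=station0)
        hm.to_csv(out / f"heatmap_low_{station0}.csv")
        artifacts["heatmap_low"] = out / f"heatmap_low_{station0}.csv"

        stage = "models"
        model_report = {}
        if config.run_models:
            hourly_ids = set(hourly["file_id"])
            spl_hourly = spl.loc[spl["file_id"].isin(hourly_ids)]
            excluded, excl_stats = ann.exclude_noise(spl_hourly, hourly)
            model_report["noise_exclusion"] = excl_stats
            merged_cov = covs.set_index("file_id")
            for label, tbl in (("full", spl), ("no_noise", excluded)):
                for band in ("low", "high"):
                    sub = tbl.loc[tbl["band"] == band].join(
                        merged_cov[["diel"]], on="file_id")
                    ph = models.dtk_posthoc(sub["spl_db"].to_numpy(),
                                            sub["diel"].to_numpy(),
                                            factor="diel")
                    model_report[f"{band}_{label}_diel_order"] = ph.ordering
                    model_report[f"{band}_{label}_diel_significant"] = bool(
                        ph.pairs["significant"].iloc[0])
            (out / "model_report.json").write_text(
                json.dumps(model_report, indent=2, default=str))
            artifacts["model_report"] = out / "model_report.json"

        stage = "manifest"
        manifest = {
            "seed": config.rng_seed,
            "config_hash": hashlib.sha256(
                repr(config.scene).encode()).hexdigest(),
            "artifacts": {k: {"path": str(p.name), "sha256": _sha256(p)}
                          for k, p in artifacts.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
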