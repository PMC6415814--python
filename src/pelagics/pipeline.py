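"""Orchestration: forcing -> cohorts -> simulation -> metrics -> files.

``run_simulation`` binds the modules into one reproducible pipeline:
it generates (or reads) the per-site forcing, builds the cohorts,
integrates the biokinetic balance at every site, extracts the
radioecological metrics, and writes the long-format CSV outputs plus
a manifest recording the seed, the configuration digest and the file
paths.  A fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, config_digest, dump_config
from .dynamics import SimulationResult, build_cohorts, simulate
from .metrics import metrics_table, species_summary
from .scenarios import ForcingSeries, build_forcings, build_grid, default_site_peaks

__all__ = ["RunManifest", "run_simulation", "write_results", "make_forcings", "read_forcing_csv"]

SERIES_COLUMNS = ["site_id", "species_id", "cohort_year", "date", "conc_Bq_kg_wet"]
FORCING_COLUMNS = ["site_id", "date", "water_Bq_l", "temp_C"]


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_digest: str
    seed: int
    version: str
    started: str
    finished: str
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def make_forcings(config: RunConfig) -> list[ForcingSeries]:
    """Per-site forcing from the configured scenario (or a user CSV)."""
    if config.forcing_csv is not None:
        return read_forcing_csv(config.forcing_csv)
    grid = build_grid(
        config.grid.n_sites,
        (config.grid.lat_north, config.grid.lat_south),
        config.grid.longitude,
        config.grid.high_resolution,
    )
    base = config.scenario.base_spec(config.seed)
    peaks = default_site_peaks(
        grid,
        peak_max_Bq_l=config.scenario.peak_max_Bq_l,
        peak_min_Bq_l=config.scenario.peak_min_Bq_l,
        center_lat=config.scenario.peak_center_lat,
        width_deg=config.scenario.peak_width_deg,
    )
    return build_forcings(
        grid,
        base,
        site_peaks=peaks,
        northern_second_peak=config.scenario.northern_second_peak,
        northern_lat=config.scenario.northern_lat,
        second_peak_shape=config.scenario.second_peak(),
    )


def read_forcing_csv(path) -> list[ForcingSeries]:
    """Read a long-format forcing CSV (site_id, date, water_Bq_l, temp_C)."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"forcing CSV is missing columns: {missing}")
    out = []
    for sid, g in df.groupby("site_id", sort=False):
        g = g.sort_values("date")
        out.append(
            ForcingSeries(
                str(sid),
                pd.DatetimeIndex(g["date"]),
                g["water_Bq_l"].to_numpy(),
                g["temp_C"].to_numpy(),
            )
        )
    return out


def forcings_to_frame(forcings: list[ForcingSeries]) -> pd.DataFrame:
    return pd.concat([f.to_frame() for f in forcings], ignore_index=True)[FORCING_COLUMNS]


def write_results(series: pd.DataFrame, metrics: pd.DataFrame, outdir) -> dict[str, str]:
    """Write the long-format series and metrics CSVs (UTF-8, ISO dates)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series = series.copy()
    if len(series) == 0:
        series = pd.DataFrame(columns=SERIES_COLUMNS)
    series = series[SERIES_COLUMNS]
    series["date"] = pd.to_datetime(series["date"]).dt.strftime("%Y-%m-%d")
    series_path = outdir / "series.csv"
    series.to_csv(series_path, index=False)
    metrics_path = outdir / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    return {"series": str(series_path), "metrics": str(metrics_path)}


def run_simulation(config: RunConfig, outdir) -> tuple[SimulationResult, RunManifest]:
    """Execute the full pipeline and write all outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()

    try:
        forcings = make_forcings(config)
    except Exception as e:  # noqa: BLE001 - stage-tagged abort
        raise StageError("forcing", e) from e
    try:
        species = config.species()
        cohorts = build_cohorts(species, forcings[0].dates, seed=config.seed)
    except Exception as e:  # noqa: BLE001
        raise StageError("cohorts", e) from e
    try:
        result = simulate(
            forcings,
            cohorts,
            cp=config.contaminant.params(),
            sel=config.selectivity.params(),
            plankton=config.plankton.params(),
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    try:
        mtable = metrics_table(result, config.scenario.accident_date)
        summary = species_summary(mtable) if len(mtable) else pd.DataFrame()
        series = result.to_frame()
        paths = write_results(series, mtable, outdir)
        forcing_path = outdir / "forcing.csv"
        forcings_to_frame(forcings).to_csv(forcing_path, index=False)
        paths["forcing"] = str(forcing_path)
        summary_path = outdir / "species_summary.csv"
        summary.to_csv(summary_path)
        paths["species_summary"] = str(summary_path)
        config_path = outdir / "config.yaml"
        dump_config(config, config_path)
        paths["config"] = str(config_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("output", e) from e

    manifest = RunManifest(
        config_digest=config_digest(config),
        seed=config.seed,
        version=__version__,
        started=started,
        finished=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        outputs=paths,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return result, manifest
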