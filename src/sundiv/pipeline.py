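"""Config-driven orchestration of the full analysis, with a run manifest.

A run executes, in order: census load (or synthetic generation), the four
partitioning designs with summaries, temporal representativeness, the
zone-mean representativeness series, composition/range change metrics, and —
when plot coordinates exist — kriged diversity surfaces with leave-one-out
cross-validation and between-epoch change fractions.  Every artifact is a
tidy CSV, an ESRI ASCII grid, or the JSON manifest; identical config + seed
reproduces every output byte for byte.

The single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence``; each stage's seed is recorded in the
manifest, so no stage consumes unlogged randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .census import CensusTable, read_census, table1_fixture, write_census
from .change import abundance_change_table, zone_totals
from .geostat import change_fraction, map_diversity, surface_to_frame, write_ascii_grid
from .partition import (
    DesignSpec,
    build_design,
    run_design,
    summarize,
    temporal_representativeness,
    zone_representativeness_series,
)
from .synthetic import homogenization_scenario, simulate_scenario

log = logging.getLogger("sundiv.pipeline")

_FLOAT_FMT = "%.12g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (TOML-serializable)."""

    census_path: str | None = None        # with metadata_path: load user data
    metadata_path: str | None = None
    scenario_strength: float | None = None  # else: synthetic scenario...
    use_fixture: bool = False               # ...or the packaged abundance table
    q_list: tuple[float, ...] = (0.0, 1.0, 2.0)
    n_per_zone: int = 30
    iterations: int = 100
    cell_size: float = 25.0
    n_bins: int = 12
    change_years: tuple[int, int] | None = None  # default: first and last census
    map_measures: tuple[str, ...] = ("alpha_bar", "rho_bar", "gamma_sub")
    map_q: float = 1.0
    seed: int = 0
    out_dir: str = "sundiv_run"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "rb") as f:
            raw = tomllib.load(f)
        cfg = cls(**raw)
        for name in ("q_list", "change_years", "map_measures"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                setattr(cfg, name, tuple(val))
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; return (and write) the run manifest.

    The manifest lists, per stage, the derived seed, the artifact paths with
    SHA-256 hashes, and input/output row counts.  A stage failure aborts
    with the stage name; artifacts already written are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(
            ("simulate", "designs", "temporal", "change", "map"),
            np.random.SeedSequence(config.seed).spawn(5),
        )
    }
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }

    def record(stage: str, paths: list[Path], **info) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in paths},
            **info,
        }
        log.info("stage %s: %d artifact(s) %s", stage, len(paths), info)

    # ---- stage: acquire census ------------------------------------------
    try:
        if config.census_path is not None:
            table = read_census(config.census_path, config.metadata_path)
            source = "file"
        elif config.use_fixture:
            table = table1_fixture()
            source = "fixture"
        else:
            strength = (
                config.scenario_strength if config.scenario_strength is not None else 0.5
            )
            table = simulate_scenario(
                homogenization_scenario(strength, seed=stage_seeds["simulate"])
            )
            source = f"synthetic(strength={strength})"
        cpath, mpath = out / "census.csv", out / "metadata.csv"
        write_census(table, cpath, mpath)
        record("census", [cpath, mpath], source=source, records=len(table.records))
    except Exception as exc:
        raise StageError("census", exc) from exc

    # ---- stage: partition designs ---------------------------------------
    try:
        paths = []
        multi_plot = table.metadata.groupby("zone")["plot_id"].count().max() > 1
        spatial_kinds = ["spatial_zone", "spatial_ecosystem"] if multi_plot else []
        zone_counts = table.metadata.groupby("zone")["plot_id"].count()
        n_per_zone = config.n_per_zone if multi_plot else None
        if multi_plot and zone_counts.min() < config.n_per_zone:
            n_per_zone = int(zone_counts.min())
        for kind in spatial_kinds:
            frames, summaries = [], []
            for year in table.years:
                spec = DesignSpec(
                    kind, census_year=year, n_per_zone=n_per_zone,
                    iterations=config.iterations, seed=stage_seeds["designs"],
                )
                res = run_design(build_design(table, spec), config.q_list)
                frames.append(res)
                for q in config.q_list:
                    summaries.append(summarize(res, q, seed=stage_seeds["designs"]))
            p1 = out / f"diversity_{kind}.csv"
            _write_csv(pd.concat(frames, ignore_index=True), p1)
            p2 = out / f"summary_{kind}.csv"
            _write_csv(pd.concat(summaries, ignore_index=True), p2)
            paths += [p1, p2]
        for kind in ("temporal_psp", "temporal_zone"):
            res = run_design(build_design(table, DesignSpec(kind)), config.q_list)
            p = out / f"diversity_{kind}.csv"
            _write_csv(res, p)
            paths.append(p)
        record("designs", paths, kinds=spatial_kinds + ["temporal_psp", "temporal_zone"])
    except Exception as exc:
        raise StageError("designs", exc) from exc

    # ---- stage: temporal representativeness -----------------------------
    try:
        paths = []
        levels = ["zone"] + (["psp"] if multi_plot else [])
        for level in levels:
            df = temporal_representativeness(table, level, config.q_list)
            p = out / f"temporal_rho_{level}.csv"
            _write_csv(df, p)
            paths.append(p)
        series = pd.concat(
            [zone_representativeness_series(table, q) for q in config.q_list],
            ignore_index=True,
        )
        p = out / "zone_rho_series.csv"
        _write_csv(series, p)
        paths.append(p)
        record("temporal", paths, levels=levels)
    except Exception as exc:
        raise StageError("temporal", exc) from exc

    # ---- stage: change metrics ------------------------------------------
    try:
        y0, y1 = config.change_years or (table.years[0], table.years[-1])
        change = abundance_change_table(table, y0, y1)
        p1 = out / f"change_{y0}_{y1}.csv"
        _write_csv(change, p1)
        p2 = out / f"zone_totals_{y0}_{y1}.csv"
        _write_csv(zone_totals(table, [y0, y1]), p2)
        record("change", [p1, p2], years=[y0, y1], species=change["species"].nunique())
    except Exception as exc:
        raise StageError("change", exc) from exc

    # ---- stage: mapping (skipped without coordinates) --------------------
    if not table.has_coordinates() or not multi_plot:
        manifest["stages"]["map"] = {"skipped": "no plot coordinates available"}
        log.info("stage map skipped: no plot coordinates available")
    else:
        try:
            paths = []
            cv_rows, cf_rows = [], []
            y0, y1 = table.years[0], table.years[-1]
            for measure in config.map_measures:
                maps = map_diversity(
                    table, measure, config.map_q, years=[y0, y1],
                    cell_size=config.cell_size, n_bins=config.n_bins,
                )
                for year, m in maps.items():
                    stem = f"{measure}_q{config.map_q:g}_{year}"
                    pa = out / f"{stem}.asc"
                    write_ascii_grid(m["surface"], pa)
                    pc = out / f"{stem}.csv"
                    _write_csv(surface_to_frame(m["surface"]), pc)
                    paths += [pa, pc]
                    cv_rows.append({
                        "measure": measure, "q": config.map_q, "year": year,
                        "family": m["model"].family, "nugget": m["model"].nugget,
                        "partial_sill": m["model"].partial_sill,
                        "range": m["model"].range_,
                        "effective_range": m["model"].effective_range,
                        "rmse": m["cv"].rmse, "nrmse": m["cv"].nrmse,
                    })
                for direction in ("increase", "decrease"):
                    cf_rows.append({
                        "measure": measure, "q": config.map_q,
                        "year_start": y0, "year_end": y1, "direction": direction,
                        "fraction": change_fraction(
                            maps[y0]["surface"], maps[y1]["surface"], direction
                        ),
                    })
            pcv = out / "kriging_cv.csv"
            _write_csv(pd.DataFrame(cv_rows), pcv)
            pcf = out / "change_fractions.csv"
            _write_csv(pd.DataFrame(cf_rows), pcf)
            paths += [pcv, pcf]
            record("map", paths, measures=list(config.map_measures))
        except Exception as exc:
            raise StageError("map", exc) from exc

    mpath = Path(config.out_dir) / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
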