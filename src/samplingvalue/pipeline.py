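"""End-to-end orchestration: filter -> trends -> leverage -> grids -> value.

`run_all` glues the stages together for one input table (real EBD-style or
simulated), running every grain size, and writes an auditable artifact
directory with a manifest of SHA-256 hashes and the seeds used. Stages are
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import io_formats, filtering, trend_model, leverage as leverage_mod
from . import grid_params as gp
from . import value_model as vm
from .synthetic_data import SyntheticWorldConfig, simulate_world, write_world

logger = logging.getLogger("samplingvalue")


@dataclasses.dataclass
class PipelineConfig:
    input_tsv: str | None = None          # None -> simulate a default world
    output_dir: str = "artifacts"
    grains_km: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0)
    day_origin: _dt.date = _dt.date(2010, 1, 1)
    eval_year: int | None = None          # default: last calendar year in data
    seed: int = 42
    filter_config: filtering.FilterConfig = dataclasses.field(
        default_factory=filtering.FilterConfig
    )
    world_config: SyntheticWorldConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key in ("input_tsv", "output_dir", "eval_year", "seed"):
            if key in raw:
                kw[key] = raw[key]
        if "grains_km" in raw:
            kw["grains_km"] = tuple(float(g) for g in raw["grains_km"])
        if "day_origin" in raw:
            kw["day_origin"] = _dt.date.fromisoformat(str(raw["day_origin"]))
        if "filter" in raw:
            kw["filter_config"] = filtering.FilterConfig(**raw["filter"])
        if "world" in raw:
            kw["world_config"] = SyntheticWorldConfig(**raw["world"])
        return cls(**kw)


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage at every grain; returns the manifest dict."""
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[pathlib.Path] = []
    counts: dict[str, object] = {}

    # ---- input ------------------------------------------------------------
    if config.input_tsv is None:
        wcfg = config.world_config or SyntheticWorldConfig(seed=config.seed)
        table, _truth = simulate_world(wcfg)
        input_path = out / "world.tsv"
        write_world(table, input_path)
        artifacts.append(input_path)
    else:
        input_path = pathlib.Path(config.input_tsv)

    obs = io_formats.read_observations(input_path)
    checklists = io_formats.collapse_to_checklists(obs)
    counts["observation_rows"] = len(obs)
    counts["checklists_in"] = len(checklists)

    # ---- filtering --------------------------------------------------------
    retained, report = filtering.filter_checklists(checklists, config.filter_config)
    if len(retained) == 0:
        raise RuntimeError("stage filtering: no checklists retained")
    species = filtering.select_species(retained, config.filter_config, report)
    report.to_frame().to_csv(out / "filter_report.csv", index=False)
    io_formats.write_checklists(retained, out / "checklists.csv")
    artifacts += [out / "filter_report.csv", out / "checklists.csv"]
    counts["checklists_retained"] = len(retained)
    counts["species_modelled"] = len(species)

    # ---- trends -----------------------------------------------------------
    presence = io_formats.zero_fill(retained, species)
    design = trend_model.build_design(retained, day_origin=config.day_origin)
    fits = trend_model.fit_all_trends(design, presence)
    coef_rows = []
    for sp in species:
        f = fits[sp]
        if f.converged:
            se = f.bse()
            for term in f.params.index:
                coef_rows.append(
                    (sp, term, f.params[term], se[term], True)
                )
        else:
            coef_rows.append((sp, trend_model.DAY_COLUMN, np.nan, np.nan, False))
    pd.DataFrame(
        coef_rows, columns=["species_code", "term", "estimate", "se", "converged"]
    ).to_csv(out / "trend_coefficients.csv", index=False)
    artifacts.append(out / "trend_coefficients.csv")
    counts["species_converged"] = sum(f.converged for f in fits.values())

    # ---- leverage ---------------------------------------------------------
    lev = leverage_mod.build_leverage_table(fits)
    lev.to_frame().to_csv(out / "leverage.csv")
    lev.marginal_value.to_frame().to_csv(out / "marginal_value.csv")
    artifacts += [out / "leverage.csv", out / "marginal_value.csv"]

    # ---- spatial stages per grain -----------------------------------------
    lon = retained["longitude"].to_numpy(float)
    lat = retained["latitude"].to_numpy(float)
    origin = (float(lon.min()), float(lat.min()))
    x, y = gp.project_lonlat(lon, lat, origin)
    pad = 1e-9
    region = (
        float(x.min()), float(y.min()),
        float(x.max()) + pad, float(y.max()) + pad,
    )
    days = np.array(
        [gp.day_number(d, config.day_origin) for d in retained["date"]], dtype=int
    )
    eval_year = config.eval_year or max(d.year for d in retained["date"])
    eval_dates = pd.date_range(
        f"{eval_year}-01-01", f"{eval_year}-12-31", freq="D"
    ).date
    eval_days = np.array(
        [gp.day_number(d, config.day_origin) for d in eval_dates], dtype=int
    )
    in_eval = np.array([d.year == eval_year for d in retained["date"]])
    counts["eval_year"] = eval_year
    counts["eval_checklists"] = int(in_eval.sum())
    if not in_eval.any():
        raise RuntimeError(f"stage value_model: no checklists in {eval_year}")

    master_rng = np.random.default_rng(config.seed)
    grain_seeds = {g: int(master_rng.integers(2**31)) for g in config.grains_km}

    for grain in config.grains_km:
        label = f"{grain:g}km"
        gdir = out / f"grain_{label}"
        gdir.mkdir(exist_ok=True)
        grid = gp.make_grid(region, grain, grain_label=label)
        grid.to_geojson(gdir / "grid.geojson")
        cells = gp.assign_cells(x, y, grid)
        history = gp.SamplingHistory.from_assignments(cells, days)
        panel = gp.daily_parameters_panel(grid, history, list(eval_days))
        panel.to_csv(gdir / "daily_parameters.csv", index=False)

        eval_rows = pd.DataFrame(
            {
                "checklist_id": retained.loc[in_eval, "checklist_id"].to_numpy(),
                "cell_id": cells[in_eval],
                "day": days[in_eval],
            }
        )
        eval_rows = eval_rows[eval_rows["cell_id"] >= 0]
        rows = vm.join_training_table(lev.marginal_value, panel, eval_rows)
        screen, _ = vm.collinearity_screen(rows)
        screen.to_csv(gdir / "collinearity.csv", index=False)
        degenerate = vm.degenerate_covariates(rows)
        if degenerate:
            logger.warning(
                "grain %s: covariate(s) %s degenerate; excluded from this "
                "grain's model", label, degenerate,
            )
        usable = tuple(c for c in vm.COVARIATES if c not in degenerate)
        fit = vm.fit_value_model(rows, grain_label=label, covariates=usable)
        fit.summary_frame().to_csv(gdir / "value_model.csv")
        effect = vm.test_unsampled_effect(rows, grain_label=label)
        with open(gdir / "effect_test.json", "w") as fh:
            json.dump(dataclasses.asdict(effect), fh, indent=1)

        rng = np.random.default_rng(grain_seeds[grain])
        maps = []
        day_cells = pd.Series(cells[in_eval], index=days[in_eval])
        for d in eval_days:
            dp = panel[panel["day"] == d]
            observed = day_cells[day_cells.index == d].to_numpy()
            maps.append(vm.predict_daily_map(fit, dp, observed, rng))
        pd.concat(maps, ignore_index=True).to_csv(
            gdir / "daily_maps.csv", index=False
        )
        artifacts += [
            gdir / "grid.geojson", gdir / "daily_parameters.csv",
            gdir / "collinearity.csv", gdir / "value_model.csv",
            gdir / "effect_test.json", gdir / "daily_maps.csv",
        ]
        counts[f"cells_{label}"] = grid.n_cells
        counts[f"value_model_r2_{label}"] = fit.r_squared

    manifest = {
        "seed": config.seed,
        "grain_seeds": {f"{g:g}km": s for g, s in grain_seeds.items()},
        "counts": counts,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
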