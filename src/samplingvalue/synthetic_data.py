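"""Synthetic checklist worlds with known truth.

Emulates the structure of unstructured citizen-science bird atlasing: square
region, hotspot-biased effort over grid cells, multi-year daily coverage,
and complete checklists whose species lists are drawn from per-species
logistic models with a linear day trend, county effects, and a latent
per-checklist effort score shared across species. List length arises from
the simulated detections themselves (no separate draw), so the effort /
list-length-offset relationship is internally consistent. The emitted table
uses the EBD headers and round-trips through ``read_observations``
unchanged; a truth object records every generating parameter.

Counties are Voronoi regions over randomly placed seeds, giving the
categorical spatial term in the trend model real structure.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import DEFAULT_COLUMN_MAP
from .grid_params import Grid, make_grid

logger = logging.getLogger("samplingvalue")

_KM_PER_DEG = 111.32


@dataclass
class SyntheticWorldConfig:
    """Generating parameters for one synthetic world.

    Defaults give a 200 x 200 km region at 5 km grain (1,600 cells), 3
    counties, 20 species, 4 years and 6,000 checklists — large enough for
    stable GLMs and for non-degenerate grids at every grain size up to
    50 km. Effort is spatially clustered the way urban citizen science is:
    ``n_hotspots`` Gaussian-kernel hotspots (sd ``hotspot_sigma_km``) whose
    placement is biased toward one corner of the region (the "city"; beta-
    distributed coordinates with shape ``hotspot_center_bias``) and whose
    intensities fall off as rank^-``hotspot_exponent``. Cells far from every
    hotspot have vanishing weight and stay unsampled for years, as in real
    regional atlases. Day-trend slopes are per-day on the logit scale
    (sd 5e-4 ~= a drift of 0.7 logits over the 4-year record); ``effort_sd``
    is the sd of the latent per-checklist effort score added to every
    species' logit.
    """

    width_km: float = 200.0
    height_km: float = 200.0
    grain_km: float = 5.0
    n_counties: int = 3
    n_species: int = 20
    n_years: int = 4
    n_checklists: int = 6000
    n_hotspots: int = 10
    hotspot_sigma_km: float = 12.0
    hotspot_center_bias: float = 3.0
    hotspot_exponent: float = 1.5
    background_effort: float = 0.02
    beta_day_mean: float = 0.0
    beta_day_sd: float = 5e-4
    prevalence_range: tuple[float, float] = (0.10, 0.60)
    county_sd: float = 0.5
    effort_sd: float = 1.0
    duration_log_mean: float = math.log(60.0)   # minutes
    duration_log_sd: float = 0.6
    distance_log_mean: float = 0.0              # log km
    distance_log_sd: float = 0.8
    frac_stationary: float = 0.3
    frac_incomplete: float = 0.03
    frac_nocturnal: float = 0.05
    frac_short_duration: float = 0.02
    frac_long_duration: float = 0.02
    start_date: _dt.date = _dt.date(2010, 1, 1)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_counties, self.n_species, self.n_years, self.n_checklists) <= 0:
            raise ValueError("all counts must be positive")
        lo, hi = self.prevalence_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("prevalence range must be inside (0, 1)")

    @property
    def n_days(self) -> int:
        return 365 * self.n_years


@dataclass
class SyntheticTruth:
    """Generating values aligned with the emitted checklist table."""

    beta_day: np.ndarray                 # per species, logit per day
    intercept: np.ndarray                # per species, logit at day 0
    county_effects: np.ndarray           # species x counties (col 0 = reference)
    cell_weight: np.ndarray              # effort weight per cell
    cell_county: np.ndarray              # county index per cell
    grid: Grid
    species: list[str] = field(default_factory=list)
    counties: list[str] = field(default_factory=list)
    config: SyntheticWorldConfig | None = None


def _logit(p):
    return np.log(p / (1.0 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _biased_points(n: int, cfg: SyntheticWorldConfig, rng) -> np.ndarray:
    """Corner-biased (x, y) positions: dense near the 'city' at (0, 0)."""
    b = cfg.hotspot_center_bias
    return np.column_stack(
        [cfg.width_km * rng.beta(1.0, b, n), cfg.height_km * rng.beta(1.0, b, n)]
    )


def _effort_weights(grid: Grid, cfg: SyntheticWorldConfig, rng) -> np.ndarray:
    """Per-cell visit weights from clustered, power-law-intensity hotspots."""
    cent = grid.centroids()
    centers = _biased_points(cfg.n_hotspots, cfg, rng)
    intensity = (np.arange(cfg.n_hotspots) + 1.0) ** (-cfg.hotspot_exponent)
    d2 = ((cent[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    w = (intensity[None, :] * np.exp(-d2 / (2.0 * cfg.hotspot_sigma_km**2))).sum(axis=1)
    w /= w.sum()
    # a thin uniform layer of "background birding" far from any hotspot, so
    # isolated cells get occasional first visits as in real atlas data
    bg = cfg.background_effort
    return (1.0 - bg) * w + bg / grid.n_cells


def _voronoi_counties(grid: Grid, cfg: SyntheticWorldConfig, rng) -> np.ndarray:
    cent = grid.centroids()
    seeds = _biased_points(cfg.n_counties, cfg, rng)
    d2 = ((cent[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def simulate_world(
    config: SyntheticWorldConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one world; returns (EBD-style observation table, truth).

    Identical seed => byte-identical table. Species that end up undetected
    on every checklist (infeasible prevalence) have their intercept redrawn
    upward and their detections resimulated, with a warning.
    """
    cfg = config or SyntheticWorldConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    grid = make_grid((0.0, 0.0, cfg.width_km, cfg.height_km), cfg.grain_km)
    n_cells = grid.n_cells

    weight = _effort_weights(grid, cfg, rng)
    county_of_cell = _voronoi_counties(grid, cfg, rng)
    counties = [f"county_{k + 1}" for k in range(cfg.n_counties)]
    species = [f"species_{s + 1:03d}" for s in range(cfg.n_species)]

    beta_day = rng.normal(cfg.beta_day_mean, cfg.beta_day_sd, cfg.n_species)
    prevalence = rng.uniform(*cfg.prevalence_range, cfg.n_species)
    intercept = _logit(prevalence)
    county_eff = np.zeros((cfg.n_species, cfg.n_counties))
    county_eff[:, 1:] = rng.normal(0.0, cfg.county_sd, (cfg.n_species, cfg.n_counties - 1))

    n = cfg.n_checklists
    cell = rng.choice(n_cells, size=n, p=weight)
    cent = grid.centroids()
    x = cent[cell, 0] + rng.uniform(-0.5, 0.5, n) * cfg.grain_km
    y = cent[cell, 1] + rng.uniform(-0.5, 0.5, n) * cfg.grain_km
    day = rng.integers(0, cfg.n_days, size=n)
    county_idx = county_of_cell[cell]

    nocturnal = rng.random(n) < cfg.frac_nocturnal
    start_hour = np.where(
        nocturnal, rng.uniform(20.5, 23.5, n), rng.uniform(5.5, 19.5, n)
    )
    duration = np.exp(rng.normal(cfg.duration_log_mean, cfg.duration_log_sd, n))
    u_dur = rng.random(n)
    duration = np.where(u_dur < cfg.frac_short_duration, rng.uniform(1, 5, n), duration)
    duration = np.where(
        (u_dur >= cfg.frac_short_duration)
        & (u_dur < cfg.frac_short_duration + cfg.frac_long_duration),
        rng.uniform(250, 400, n),
        duration,
    )
    stationary = rng.random(n) < cfg.frac_stationary
    distance = np.exp(rng.normal(cfg.distance_log_mean, cfg.distance_log_sd, n))
    complete = rng.random(n) >= cfg.frac_incomplete
    effort = rng.normal(0.0, cfg.effort_sd, n)

    # per-species Bernoulli detections
    detect = np.empty((n, cfg.n_species), dtype=bool)
    for s in range(cfg.n_species):
        eta = (
            intercept[s]
            + beta_day[s] * day
            + county_eff[s, county_idx]
            + effort
        )
        detect[:, s] = rng.random(n) < _sigmoid(eta)
    for _ in range(20):
        dead = np.flatnonzero(detect.sum(axis=0) == 0)
        if len(dead) == 0:
            break
        for s in dead:
            logger.warning(
                "species %s undetected everywhere; intercept redrawn", species[s]
            )
            prevalence[s] = min(0.95, prevalence[s] + 0.2)
            intercept[s] = _logit(prevalence[s])
            eta = (
                intercept[s]
                + beta_day[s] * day
                + county_eff[s, county_idx]
                + effort
            )
            detect[:, s] = rng.random(n) < _sigmoid(eta)

    rows = _emit_rows(
        cfg, species, counties, county_idx, cell, x, y, day, start_hour,
        duration, distance, stationary, complete, detect,
    )
    truth = SyntheticTruth(
        beta_day=beta_day,
        intercept=intercept,
        county_effects=county_eff,
        cell_weight=weight,
        cell_county=county_of_cell,
        grid=grid,
        species=species,
        counties=counties,
        config=cfg,
    )
    return rows, truth


def _emit_rows(
    cfg, species, counties, county_idx, cell, x, y, day, start_hour,
    duration, distance, stationary, complete, detect,
):
    # planar km -> decimal degrees near (0, 0); equirectangular inverse
    lat = y / _KM_PER_DEG
    lon = x / _KM_PER_DEG
    n = len(cell)
    recs = []
    for c in range(n):
        sp_idx = np.flatnonzero(detect[c])
        if len(sp_idx) == 0:
            continue  # a checklist with no species produces no EBD rows
        cid = f"S{c + 1:06d}"
        date_iso = (cfg.start_date + _dt.timedelta(days=int(day[c]))).isoformat()
        hh = int(start_hour[c])
        mm = int(round((start_hour[c] - hh) * 60)) % 60
        for s in sp_idx:
            recs.append(
                (
                    cid,
                    species[s],
                    f"{lat[c]:.6f}",
                    f"{lon[c]:.6f}",
                    counties[county_idx[c]],
                    date_iso,
                    f"{hh:02d}:{mm:02d}",
                    f"{duration[c]:.1f}",
                    "" if stationary[c] else f"{distance[c]:.3f}",
                    "",
                    "1" if complete[c] else "0",
                )
            )
    headers = [
        DEFAULT_COLUMN_MAP[f]
        for f in (
            "checklist_id", "species_code", "latitude", "longitude", "county",
            "date", "start_time", "duration_minutes", "distance_km", "area_ha",
            "is_complete",
        )
    ]
    return pd.DataFrame(recs, columns=headers)


def write_world(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-species generating parameters as a flat table (sidecar CSV)."""
    out = pd.DataFrame(
        {
            "species_code": truth.species,
            "beta_day": truth.beta_day,
            "intercept": truth.intercept,
        }
    )
    for k, name in enumerate(truth.counties):
        out[f"county_effect[{name}]"] = truth.county_effects[:, k]
    return out


# --------------------------------------------------------------------------
# Hand-auditable fixtures for the unit suite

def _filter_fixture_rows() -> pd.DataFrame:
    """8 complete-looking checklists, exactly 3 single-rule violations.

    C2 is incomplete, C3 lasted 4 minutes, C4 travelled 6 km: the other five
    pass every rule, so filtering retains {C1, C5, C6, C7, C8} and the
    report reads complete=1, diurnal=0, duration=1, distance_area=1,
    list_length=0.
    """
    base = dict(
        lat="-33.800000", lon="151.100000", county="county_a",
        date="2018-03-10", time="08:30", duration="60.0", dist="1.000",
        area="", complete="1",
    )
    per_checklist = {
        "C1": {},
        "C2": {"complete": "0"},
        "C3": {"duration": "4.0"},
        "C4": {"dist": "6.000"},
        "C5": {"dist": "", "area": ""},          # stationary: passes travel rule
        "C6": {"time": "17:45"},
        "C7": {"duration": "239.0"},
        "C8": {"dist": "4.900"},
    }
    species = [f"sp_{k}" for k in range(1, 7)]
    recs = []
    for cid, override in per_checklist.items():
        v = dict(base, **override)
        for s in species[:5] if cid != "C8" else species:  # C8 has 6 species
            recs.append(
                (cid, s, v["lat"], v["lon"], v["county"], v["date"], v["time"],
                 v["duration"], v["dist"], v["area"], v["complete"])
            )
    headers = [
        DEFAULT_COLUMN_MAP[f]
        for f in (
            "checklist_id", "species_code", "latitude", "longitude", "county",
            "date", "start_time", "duration_minutes", "distance_km", "area_ha",
            "is_complete",
        )
    ]
    return pd.DataFrame(recs, columns=headers)


def _gaussian_toy() -> pd.DataFrame:
    """n=5 (x, y) pairs for the exact leave-one-out dfBeta identity."""
    return pd.DataFrame(
        {"x": [0.0, 1.0, 2.0, 3.0, 4.0], "y": [1.0, 1.8, 1.3, 3.7, 2.9]}
    )


def make_fixtures() -> dict[str, object]:
    """Tiny deterministic fixtures used across the unit suite.

    ``filter_fixture``: EBD-style table of 8 checklists (see
    :func:`_filter_fixture_rows`); ``gaussian_toy``: the n=5 linear-model
    dataset; ``grid_history``: a 4x4 grid with one cell sampled on days
    {1, 3, 7}.
    """
    grid = make_grid((0.0, 0.0, 20.0, 20.0), 5.0)
    return {
        "filter_fixture": _filter_fixture_rows(),
        "gaussian_toy": _gaussian_toy(),
        "grid_history": {"grid": grid, "cell_days": {5: np.array([1, 3, 7])}},
    }


def write_fixtures(outdir) -> None:
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fx = make_fixtures()
    fx["filter_fixture"].to_csv(out / "filter_fixture.tsv", sep="\t", index=False)
    fx["gaussian_toy"].to_csv(out / "gaussian_toy.csv", index=False)


def reduced_config(**overrides) -> SyntheticWorldConfig:
    """Default config with overrides (convenience for tests/scripts)."""
    return replace(SyntheticWorldConfig(), **overrides)
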