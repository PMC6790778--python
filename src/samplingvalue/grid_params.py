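"""Square grids and causal per-cell sampling-history covariates.

The study region is tiled with square cells ("sites") at one or more grain
sizes, where the grain is the cell *side* in km. For each cell and each
query date d, seven covariates summarise the sampling history using only
checklists dated strictly before d (causality: nothing after d may leak in):

  ever_sampled            — any visit before d
  dist_nearest_sampled    — km from the cell centroid to the centroid of the
                            nearest *other* sampled cell (the focal cell is
                            excluded from its own search; 0 only in the
                            degenerate case of a single sampled cell)
  median_interval         — median gap in days between consecutive distinct
                            sampled dates (floor 1; 1 when only one distinct
                            sampled day exists)
  neighbor_median_interval— the median_interval of that nearest sampled cell
  days_since_last         — d minus the last sampled date (>= 1)
  sampling_duration       — last sampled date minus first (days)
  n_unique_days           — count of distinct sampled dates

All geometry is planar (km). Geographic coordinates must be projected first;
an equirectangular local projection is provided for that.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger("samplingvalue")

PARAM_FIELDS = (
    "ever_sampled",
    "dist_nearest_sampled",
    "median_interval",
    "neighbor_median_interval",
    "days_since_last",
    "sampling_duration",
    "n_unique_days",
)

_KM_PER_DEG = 111.32


def project_lonlat(
    lon: np.ndarray, lat: np.ndarray, origin: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection of lon/lat degrees to local km.

    Adequate for regional extents (tens of km); x is scaled by cos of the
    origin latitude.
    """
    lon0, lat0 = origin
    x = (np.asarray(lon) - lon0) * _KM_PER_DEG * math.cos(math.radians(lat0))
    y = (np.asarray(lat) - lat0) * _KM_PER_DEG
    return x, y


@dataclass
class Grid:
    """Row-major square tiling of a planar bounding box.

    Cells are clipped to the region extent (x1, y1), as when a grid is
    intersected with a study region: a boundary cell is the part of the
    square inside the region and its centroid is that part's centroid, so
    centroid spacing is irregular near the boundary unless the extent is an
    exact multiple of the side.
    """

    grain_label: str
    side_km: float
    x0: float
    y0: float
    nx: int
    ny: int
    x1: float | None = None
    y1: float | None = None

    def __post_init__(self):
        if self.x1 is None:
            self.x1 = self.x0 + self.nx * self.side_km
        if self.y1 is None:
            self.y1 = self.y0 + self.ny * self.side_km

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) clipped-cell centroids, row-major (y outer, x inner)."""
        ids = self.cell_ids()
        left = self.x0 + (ids % self.nx) * self.side_km
        bottom = self.y0 + (ids // self.nx) * self.side_km
        right = np.minimum(left + self.side_km, self.x1)
        top = np.minimum(bottom + self.side_km, self.y1)
        return np.column_stack([(left + right) / 2.0, (bottom + top) / 2.0])

    def cell_polygon(self, cell_id: int) -> list[list[float]]:
        i, j = divmod(int(cell_id), self.nx)
        x = self.x0 + j * self.side_km
        y = self.y0 + i * self.side_km
        xr = min(x + self.side_km, self.x1)
        yt = min(y + self.side_km, self.y1)
        return [[x, y], [xr, y], [xr, yt], [x, yt], [x, y]]

    def to_geojson(self, path=None) -> dict:
        features = [
            {
                "type": "Feature",
                "properties": {"cell_id": int(cid)},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [self.cell_polygon(cid)],
                },
            }
            for cid in self.cell_ids()
        ]
        gj = {"type": "FeatureCollection", "features": features}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(gj, fh)
        return gj


def make_grid(
    region: tuple[float, float, float, float],
    side_km: float,
    grain_label: str | None = None,
    geographic: bool = False,
    projection_origin: tuple[float, float] | None = None,
) -> Grid:
    """Tile a region's bounding box with square cells of the given side.

    ``region`` is (x0, y0, x1, y1) in planar km. If the coordinates are
    geographic (lon/lat degrees), set ``geographic=True`` and give a
    projection origin; unprojected geographic input is fatal because degree
    distances are not metric.
    """
    if side_km <= 0:
        raise ValueError("cell side must be positive")
    x0, y0, x1, y1 = region
    if x1 <= x0 or y1 <= y0:
        raise ValueError("region must have positive area")
    if geographic:
        if projection_origin is None:
            raise ValueError(
                "geographic region requires a projection origin (lon, lat)"
            )
        xs, ys = project_lonlat(
            np.array([x0, x1]), np.array([y0, y1]), projection_origin
        )
        x0, x1 = float(xs[0]), float(xs[1])
        y0, y1 = float(ys[0]), float(ys[1])
    nx = math.ceil((x1 - x0) / side_km)
    ny = math.ceil((y1 - y0) / side_km)
    return Grid(
        grain_label=grain_label or f"{side_km:g}km",
        side_km=side_km,
        x0=x0,
        y0=y0,
        nx=nx,
        ny=ny,
        x1=x1,
        y1=y1,
    )


def assign_cells(x: np.ndarray, y: np.ndarray, grid: Grid) -> np.ndarray:
    """Map planar points to row-major cell ids; -1 for points outside.

    Boundary points follow the half-open convention [x0, x1) x [y0, y1) per
    cell, so a point on a shared edge belongs to the cell on its upper-right.
    """
    j = np.floor((np.asarray(x, dtype=float) - grid.x0) / grid.side_km).astype(int)
    i = np.floor((np.asarray(y, dtype=float) - grid.y0) / grid.side_km).astype(int)
    inside = (j >= 0) & (j < grid.nx) & (i >= 0) & (i < grid.ny)
    ids = np.where(inside, i * grid.nx + j, -1)
    n_out = int((~inside).sum())
    if n_out:
        logger.info("assign_cells: %d point(s) outside the grid dropped", n_out)
    return ids


class SamplingHistory:
    """Distinct sampled day numbers per cell, sorted ascending.

    Day numbers are integer days since an arbitrary origin; only their
    differences matter.
    """

    def __init__(self, cell_days: dict[int, np.ndarray]):
        self.cell_days = {
            int(c): np.unique(np.asarray(d, dtype=int)) for c, d in cell_days.items()
        }

    @classmethod
    def from_assignments(
        cls, cell_ids: np.ndarray, day_numbers: np.ndarray
    ) -> "SamplingHistory":
        cell_ids = np.asarray(cell_ids)
        day_numbers = np.asarray(day_numbers, dtype=int)
        keep = cell_ids >= 0
        out: dict[int, list] = {}
        for c, d in zip(cell_ids[keep], day_numbers[keep]):
            out.setdefault(int(c), []).append(int(d))
        return cls({c: np.array(v) for c, v in out.items()})


def _median_interval(days_before: np.ndarray) -> float:
    """Median gap between consecutive distinct sampled days; floor 1."""
    if len(days_before) < 2:
        return 1.0
    return max(1.0, float(np.median(np.diff(days_before))))


def daily_parameters(
    grid: Grid, history: SamplingHistory, day: int
) -> pd.DataFrame:
    """The seven sampling-history covariates for every cell at one date.

    Uses strictly pre-``day`` samples only. If no cell anywhere was sampled
    before ``day``, every cell is returned unsampled (downstream imputation
    handles the degenerate map).
    """
    n = grid.n_cells
    ever = np.zeros(n, dtype=bool)
    med = np.full(n, np.nan)
    dsl = np.full(n, np.nan)
    dur = np.full(n, np.nan)
    nud = np.zeros(n, dtype=int)

    for c, days in history.cell_days.items():
        prior = days[days < day]
        if len(prior) == 0:
            continue
        ever[c] = True
        nud[c] = len(prior)
        dsl[c] = day - prior[-1]
        dur[c] = prior[-1] - prior[0]
        med[c] = _median_interval(prior)

    cent = grid.centroids()
    dist = np.full(n, np.nan)
    nmi = np.full(n, np.nan)
    sampled = np.flatnonzero(ever)
    if len(sampled) == 1:
        s = sampled[0]
        dist[s] = 0.0                        # no other sampled cell exists
        nmi[s] = med[s]
        others = np.flatnonzero(~ever)
        dist[others] = np.sqrt(((cent[others] - cent[s]) ** 2).sum(axis=1))
        nmi[others] = med[s]
    elif len(sampled) > 1:
        tree = cKDTree(cent[sampled])
        d2, j2 = tree.query(cent, k=2)
        # for a sampled cell the nearest hit is itself; take the runner-up
        take = ever.astype(int)
        rows = np.arange(n)
        dist[:] = d2[rows, take]
        nmi[:] = med[sampled[j2[rows, take]]]
    else:
        logger.warning("no cell sampled before day %d; all-unsampled record", day)

    return pd.DataFrame(
        {
            "cell_id": grid.cell_ids(),
            "day": day,
            "ever_sampled": ever,
            "dist_nearest_sampled": dist,
            "median_interval": med,
            "neighbor_median_interval": nmi,
            "days_since_last": dsl,
            "sampling_duration": dur,
            "n_unique_days": nud,
        }
    )


def daily_parameters_panel(
    grid: Grid, history: SamplingHistory, days: list[int]
) -> pd.DataFrame:
    """Long-format panel of daily parameters over many dates."""
    return pd.concat(
        [daily_parameters(grid, history, d) for d in days], ignore_index=True
    )


def day_number(date: _dt.date, origin: _dt.date) -> int:
    return (date - origin).days
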