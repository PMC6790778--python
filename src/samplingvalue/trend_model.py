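"""Per-species binomial trend models.

Each species' presence/absence across checklists is modelled with a logistic
GLM whose linear predictor contains an intercept, a continuous day term
(days since a configurable origin), county as a categorical spatial term
(reference coding), and an offset of log(list length) — the standard
list-length correction for observer effort. The day coefficient is the
population trend of interest.

Fitting is delegated to statsmodels' IRLS; the fit object retains the
weighted-design quantities (IRLS weights, working residuals, hat diagonals,
unscaled covariance) that downstream influence diagnostics need.

`slope_convergence` quantifies how the day-slope estimate stabilises as the
number of checklists grows, by refitting on subsamples and tracking the mean
absolute deviation of the subsample slope from the full-data slope.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("samplingvalue")

DEFAULT_DAY_ORIGIN = _dt.date(2010, 1, 1)
DAY_COLUMN = "day"


@dataclass
class DesignMatrix:
    """Shared design for every species' trend model.

    ``X`` columns: intercept, day (integer days since origin), then one-hot
    county columns with the first sorted county as reference. ``offset`` is
    log(list_length).
    """

    X: pd.DataFrame               # n x p, index = checklist ids
    offset: np.ndarray            # n, log list length
    day_origin: _dt.date
    county_levels: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class GLMFit:
    """A converged GLM with the pieces influence diagnostics need.

    ``xtwx_inv`` is (X'WX)^{-1} with W the IRLS weights at convergence; for
    a binomial family (dispersion 1) it is also the coefficient covariance.
    ``working_residuals`` are (y - mu) / (dmu/deta). For the Gaussian/identity
    case the weights are 1 and the working residuals are ordinary residuals.
    """

    species_code: str | None
    params: pd.Series
    cov_params: pd.DataFrame
    xtwx_inv: np.ndarray
    weights: np.ndarray
    working_residuals: np.ndarray
    hat_diag: np.ndarray
    converged: bool
    n: int
    p: int
    X: pd.DataFrame
    offset: np.ndarray | None = None

    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )


def build_design(
    checklists: pd.DataFrame,
    county_levels: list[str] | None = None,
    day_origin: _dt.date = DEFAULT_DAY_ORIGIN,
) -> DesignMatrix:
    """Build the shared design matrix from retained checklists."""
    if county_levels is None:
        county_levels = sorted(checklists["county"].astype(str).unique())
    county_levels = sorted(county_levels)
    unseen = set(checklists["county"].astype(str)) - set(county_levels)
    if unseen:
        raise ValueError(f"county level(s) not declared: {sorted(unseen)}")

    days = np.array(
        [(d - day_origin).days for d in checklists["date"]], dtype=float
    )
    X = pd.DataFrame(index=pd.Index(checklists["checklist_id"], name="checklist_id"))
    X["intercept"] = 1.0
    X[DAY_COLUMN] = days
    for level in county_levels[1:]:  # first sorted level is the reference
        X[f"county[{level}]"] = (
            checklists["county"].astype(str) == level
        ).to_numpy(dtype=float)
    ll = checklists["list_length"].to_numpy(dtype=float)
    if (ll <= 0).any():
        raise ValueError("list_length must be positive for the log offset")
    return DesignMatrix(
        X=X, offset=np.log(ll), day_origin=day_origin, county_levels=county_levels
    )


def _fit_glm_core(
    X: pd.DataFrame,
    y: np.ndarray,
    offset: np.ndarray | None,
    family,
    species_code: str | None = None,
) -> GLMFit:
    Xa = X.to_numpy(dtype=float)
    n, p = Xa.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Xa, family=family, offset=offset)
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:  # separation / singular design
            logger.warning("GLM fit failed for %s: %s", species_code, exc)
            return _unconverged(species_code, X, offset)

    mu = np.asarray(res.mu, dtype=float)
    if isinstance(family, sm.families.Binomial):
        w = mu * (1.0 - mu)                     # IRLS weights on logit scale
        work = np.where(w > 0, (y - mu) / np.where(w > 0, w, 1.0), 0.0)
        converged = (
            bool(getattr(res, "converged", True))
            and np.all(w > 0)
            and np.all(np.isfinite(work))
        )
    else:  # Gaussian/identity
        w = np.ones(n)
        work = y - mu
        converged = True

    xtwx = Xa.T @ (Xa * w[:, None])
    try:
        xtwx_inv = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        return _unconverged(species_code, X, offset)
    M = Xa @ xtwx_inv
    hat = w * np.einsum("ij,ij->i", M, Xa)
    if not np.all(np.isfinite(res.params)) or not converged:
        return _unconverged(species_code, X, offset)

    cols = list(X.columns)
    scale = res.scale if not isinstance(family, sm.families.Binomial) else 1.0
    return GLMFit(
        species_code=species_code,
        params=pd.Series(res.params, index=cols),
        cov_params=pd.DataFrame(xtwx_inv * scale, index=cols, columns=cols),
        xtwx_inv=xtwx_inv,
        weights=w,
        working_residuals=np.asarray(work, dtype=float),
        hat_diag=hat,
        converged=True,
        n=n,
        p=p,
        X=X,
        offset=offset,
    )


def _unconverged(species_code, X, offset) -> GLMFit:
    n, p = X.shape
    cols = list(X.columns)
    nan = np.full(p, np.nan)
    return GLMFit(
        species_code=species_code,
        params=pd.Series(nan, index=cols),
        cov_params=pd.DataFrame(np.full((p, p), np.nan), index=cols, columns=cols),
        xtwx_inv=np.full((p, p), np.nan),
        weights=np.full(n, np.nan),
        working_residuals=np.full(n, np.nan),
        hat_diag=np.full(n, np.nan),
        converged=False,
        n=n,
        p=p,
        X=X,
        offset=offset,
    )


def fit_species_trend(
    design: DesignMatrix, y: np.ndarray, species_code: str | None = None
) -> GLMFit:
    """Fit one species' logistic trend GLM with the list-length offset.

    A species observed on every checklist or on none carries no information
    about the trend; such fits (and any separation or non-convergence) are
    returned flagged ``converged=False`` and excluded downstream.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n:
        raise ValueError("response length does not match design rows")
    if y.min() == y.max():
        logger.warning("species %s has constant presence; flagged", species_code)
        return _unconverged(species_code, design.X, design.offset)
    return _fit_glm_core(
        design.X, y, design.offset, sm.families.Binomial(), species_code
    )


def fit_linear(X: pd.DataFrame, y: np.ndarray) -> GLMFit:
    """Ordinary least squares expressed as a Gaussian GLM fit.

    Exposes the same weighted-design quantities as the logistic fits so the
    influence code is family-agnostic (weights 1, working residuals =
    ordinary residuals).
    """
    return _fit_glm_core(X, np.asarray(y, dtype=float), None, sm.families.Gaussian())


def fit_all_trends(
    design: DesignMatrix, presence: pd.DataFrame
) -> dict[str, GLMFit]:
    """Fit every species column of the presence matrix against the design."""
    if not design.X.index.equals(presence.index):
        raise ValueError("presence matrix rows do not align with the design")
    fits = {}
    for sp in presence.columns:
        fits[sp] = fit_species_trend(design, presence[sp].to_numpy(), sp)
    bad = [s for s, f in fits.items() if not f.converged]
    if bad:
        logger.warning("unconverged species excluded downstream: %s", bad)
    return fits


def slope_convergence(
    checklists: pd.DataFrame,
    presence: pd.DataFrame,
    species: list[str],
    sample_sizes: list[int],
    replicates: int,
    seed: int,
    day_origin: _dt.date = DEFAULT_DAY_ORIGIN,
) -> tuple[pd.DataFrame, int | None]:
    """Track day-slope stability as a function of the number of checklists.

    For each sample size, ``replicates`` subsamples (without replacement) are
    drawn, the per-species GLMs refitted, and two metrics recorded: the mean
    over species and replicates of |day slope - full-data day slope|, and the
    mean standard error of the day slope. Returns the per-size table and the
    smallest sample size at which the deviation metric falls to half its
    value at the smallest size (None if never).
    """
    n = len(checklists)
    if any(k > n for k in sample_sizes):
        raise ValueError("sample size exceeds the number of checklists")
    if min(sample_sizes) < 100:
        logger.warning("sample sizes below 100 give unstable GLM fits")
    rng = np.random.default_rng(seed)
    sizes = sorted(sample_sizes)

    full_design = build_design(checklists, day_origin=day_origin)
    full_slope = {}
    for sp in species:
        f = fit_species_trend(full_design, presence[sp].to_numpy(), sp)
        if f.converged:
            full_slope[sp] = f.params[DAY_COLUMN]
    usable = sorted(full_slope)

    rows = []
    for k in sizes:
        devs, ses = [], []
        for _ in range(replicates):
            idx = np.sort(rng.choice(n, size=k, replace=False))
            sub = checklists.iloc[idx].reset_index(drop=True)
            sub_design = build_design(sub, day_origin=day_origin)
            for sp in usable:
                f = fit_species_trend(
                    sub_design, presence[sp].to_numpy()[idx], sp
                )
                if f.converged:
                    devs.append(abs(f.params[DAY_COLUMN] - full_slope[sp]))
                    ses.append(f.bse()[DAY_COLUMN])
        rows.append(
            {
                "n_checklists": k,
                "mean_abs_deviation": float(np.mean(devs)) if devs else np.nan,
                "mean_day_se": float(np.mean(ses)) if ses else np.nan,
                "n_fits": len(devs),
            }
        )
    table = pd.DataFrame(rows)
    base = table["mean_abs_deviation"].iloc[0]
    hit = table[table["mean_abs_deviation"] <= 0.5 * base]
    n50 = int(hit["n_checklists"].iloc[0]) if len(hit) else None
    return table, n50
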