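"""Per-checklist influence (dfBeta) on the trend coefficient.

dfBeta measures how much a single coefficient would change if one
observation were deleted. For a fitted GLM with weighted design
(W the IRLS weights at convergence, e the working residuals, h the hat
diagonals), the one-step approximation for observation i on coefficient j is

    dfbeta_ij = [ (X'WX)^{-1} x_i' ]_j  *  w_i e_i / (1 - h_i)

with the sign convention beta_hat - beta_hat_(i): a positive value means
deleting the observation would decrease the coefficient. In the Gaussian
linear case (W = I, e the ordinary residuals) this one-step form is exactly
the leave-one-out refit difference; for logistic fits it is the standard
one-step approximation.

A checklist's *marginal value* is the sum over species of |dfBeta| on the
day (trend) coefficient — its aggregate influence on our knowledge of
species trends. Because absences are observations under zero-filling,
failing to record a species contributes a dfBeta too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trend_model import DAY_COLUMN, GLMFit

logger = logging.getLogger("samplingvalue")

_HAT_EPS = 1e-8


def dfbeta_one_step(
    fit: GLMFit, target: str = DAY_COLUMN, standardized: bool = False
) -> np.ndarray:
    """One-step dfBeta of every observation on one coefficient.

    Entries with hat diagonal within ``1e-8`` of 1 are returned as NaN (the
    deleted fit is undefined there); callers flag and exclude them. With
    ``standardized=True`` the raw values are divided by the coefficient's
    standard error.
    """
    if not fit.converged:
        raise ValueError("dfbeta requires a converged fit")
    if target not in fit.params.index:
        raise KeyError(f"no coefficient {target!r} in fit")
    j = list(fit.params.index).index(target)
    Xa = fit.X.to_numpy(dtype=float)
    a = fit.xtwx_inv[j]                       # row of (X'WX)^{-1}
    denom = 1.0 - fit.hat_diag
    ok = denom > _HAT_EPS
    num = (Xa @ a) * fit.weights * fit.working_residuals
    out = np.where(ok, num / np.where(ok, denom, 1.0), np.nan)
    if (~ok).any():
        logger.warning(
            "%d observation(s) with leverage ~1 flagged non-finite", int((~ok).sum())
        )
    if standardized:
        out = out / np.sqrt(fit.cov_params.iloc[j, j])
    return out


def exact_dfbeta(fit: GLMFit, target: str = DAY_COLUMN) -> np.ndarray:
    """Exact leave-one-out dfBeta by refitting without each observation.

    Brute-force oracle for the one-step approximation: for each i, refit the
    model on the remaining n-1 rows and return beta_hat - beta_hat_(i).
    O(n) refits — use on small problems only.
    """
    from .trend_model import _fit_glm_core  # local import to avoid cycle
    import statsmodels.api as sm

    y = _recover_response(fit)
    family = (
        sm.families.Gaussian()
        if np.allclose(fit.weights, 1.0)
        else sm.families.Binomial()
    )
    full = fit.params[target]
    n = fit.n
    out = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi = fit.X.iloc[mask]
        offs = fit.offset[mask] if fit.offset is not None else None
        sub = _fit_glm_core(Xi, y[mask], offs, family)
        out[i] = full - sub.params[target]
        mask[i] = True
    return out


def _recover_response(fit: GLMFit) -> np.ndarray:
    """Reconstruct y from mu and working residuals stored on the fit."""
    # working residual e = (y - mu)/w' with w' = dmu/deta; for logit w' = w.
    Xa = fit.X.to_numpy(dtype=float)
    eta = Xa @ fit.params.to_numpy()
    if fit.offset is not None:
        eta = eta + fit.offset
    if np.allclose(fit.weights, 1.0) and fit.offset is None:
        mu = eta
        return mu + fit.working_residuals
    mu = 1.0 / (1.0 + np.exp(-eta))
    return np.round(mu + fit.working_residuals * fit.weights)


@dataclass
class LeverageTable:
    """Per-checklist x per-species dfBeta and the row-wise marginal value."""

    dfbetas: pd.DataFrame          # checklists x species
    marginal_value: pd.Series      # sum over species of |dfbeta|
    nonfinite_flag: pd.Series      # True where any species entry was NaN

    def to_frame(self) -> pd.DataFrame:
        out = self.dfbetas.copy()
        out["marginal_value"] = self.marginal_value
        return out


def build_leverage_table(
    fits: dict[str, GLMFit],
    target: str = DAY_COLUMN,
    standardized: bool = False,
) -> LeverageTable:
    """Assemble the dfBeta table across species and sum to marginal values.

    Unconverged species contribute nothing (logged). Non-finite entries
    (leverage ~1) are zeroed in the marginal sum with a per-checklist flag,
    so one pathological species cannot poison a checklist's value.
    """
    converged = {s: f for s, f in fits.items() if f.converged}
    skipped = sorted(set(fits) - set(converged))
    if skipped:
        logger.warning("leverage table skips unconverged species: %s", skipped)
    if not converged:
        raise ValueError("no converged fits to build a leverage table from")

    index = None
    cols = {}
    for sp in sorted(converged):
        f = converged[sp]
        if index is None:
            index = f.X.index
        elif not f.X.index.equals(index):
            raise ValueError("fits do not share the same checklist rows")
        cols[sp] = dfbeta_one_step(f, target=target, standardized=standardized)

    table = pd.DataFrame(cols, index=index)
    nonfinite = table.isna().any(axis=1)
    mv = table.abs().fillna(0.0).sum(axis=1)
    mv.name = "marginal_value"
    return LeverageTable(dfbetas=table, marginal_value=mv, nonfinite_flag=nonfinite)
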