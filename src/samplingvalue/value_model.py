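"""Modelling and forecasting the marginal value of sampling.

The evaluation-year checklists provide the training rows: each checklist's
response is its (log) marginal value, and its covariates are the sampling
history of its grid cell on its date, computed causally from strictly
earlier sampling. Five covariates enter the linear model — median sampling
interval, number of unique days sampled, days since the last sample,
distance to the nearest sampled cell, and that neighbour's median interval —
each log-transformed then standardized so the fitted coefficients are
directly comparable effect sizes. Sampling duration is excluded up front
for collinearity with the median interval.

Whether visiting a never-sampled cell is more valuable is tested in a
separate two-group model (unsampled cells lack the other covariates), one
test per grain size. Predicted maps assign never-sampled cells the mean of
the sampled cells' predictions, and where a cell has several same-day
checklists, one of its predicted values is kept uniformly at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("samplingvalue")

#: the five model covariates, in canonical order
COVARIATES = (
    "median_interval",
    "n_unique_days",
    "days_since_last",
    "dist_nearest_sampled",
    "neighbor_median_interval",
)

#: log1p where zeros are legal (distance is 0 for sampled cells), log elsewhere
LOG1P_COVARIATES = frozenset({"dist_nearest_sampled"})


def _log_transform(name: str, x: np.ndarray) -> np.ndarray:
    return np.log1p(x) if name in LOG1P_COVARIATES else np.log(x)


def join_training_table(
    marginal_value: pd.Series,
    params_panel: pd.DataFrame,
    eval_checklists: pd.DataFrame,
) -> pd.DataFrame:
    """One regression row per evaluation-year checklist.

    ``eval_checklists`` needs columns checklist_id, cell_id, day;
    ``params_panel`` is the long-format (cell_id, day, covariates) panel.
    Rows from never-before-sampled cells are flagged ``unsampled`` and feed
    the two-group test rather than the main fit. A missing parameter record
    is fatal — it indicates a causality bug upstream.
    """
    if len(eval_checklists) == 0:
        raise ValueError("no evaluation-year checklists to train on")
    merged = eval_checklists.merge(
        params_panel, on=["cell_id", "day"], how="left", validate="many_to_one"
    )
    if merged["ever_sampled"].isna().any():
        missing = merged.loc[
            merged["ever_sampled"].isna(), ["cell_id", "day"]
        ].drop_duplicates()
        raise ValueError(
            f"missing grid-day parameter record(s):\n{missing.to_string(index=False)}"
        )
    merged["marginal_value"] = (
        merged["checklist_id"].map(marginal_value).astype(float)
    )
    if merged["marginal_value"].isna().any():
        raise ValueError("checklist(s) missing from the leverage table")
    merged["unsampled"] = ~merged["ever_sampled"].astype(bool)
    return merged


def collinearity_screen(
    rows: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise correlations of log-covariates; duration always excluded.

    Sampling duration is dropped unconditionally (it tracks the median
    sampling interval); any other pair with |r| above the threshold is
    reported but not auto-dropped.
    """
    sampled = rows[~rows["unsampled"]]
    cols = {}
    for name in COVARIATES + ("sampling_duration",):
        x = sampled[name].to_numpy(dtype=float)
        if name == "sampling_duration":
            x = np.log1p(x)  # duration can be 0 on a single-day history
        else:
            x = _log_transform(name, x)
        cols[name] = x
    corr = pd.DataFrame(cols).corr()
    pairs = []
    names = list(corr.columns)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = corr.loc[a, b]
            if abs(r) > threshold:
                pairs.append({"covariate_a": a, "covariate_b": b, "r": float(r)})
    report = pd.DataFrame(pairs, columns=["covariate_a", "covariate_b", "r"])
    retained = [c for c in COVARIATES]  # duration never retained
    return report, retained


@dataclass
class ValueModelFit:
    """OLS of log marginal value on log-standardized history covariates."""

    grain_label: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    n: int
    n_dropped_nonpositive: int
    transforms: dict[str, tuple[float, float]] = field(default_factory=dict)
    # covariate -> (training mean, training sd) on the log scale
    covariates: tuple[str, ...] = COVARIATES

    def design(self, covariate_rows: pd.DataFrame) -> np.ndarray:
        """Intercept + standardized log covariates, using TRAINING transforms."""
        X = np.ones((len(covariate_rows), 1 + len(self.covariates)))
        for k, name in enumerate(self.covariates):
            mean, sd = self.transforms[name]
            z = (_log_transform(name, covariate_rows[name].to_numpy(float)) - mean) / sd
            X[:, 1 + k] = z
        return X

    def predict(self, covariate_rows: pd.DataFrame) -> np.ndarray:
        """Expected log marginal value for rows of grid-day covariates."""
        return self.design(covariate_rows) @ self.params.to_numpy()

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        )


def degenerate_covariates(rows: pd.DataFrame) -> list[str]:
    """Covariates taking a single value across the sampled training rows.

    At a coarse grain with a long sampling history a covariate can be
    degenerate (e.g. every cell's nearest sampled neighbour at exactly the
    lattice spacing); such a column carries no information and cannot enter
    that grain's model.
    """
    data = rows[~rows["unsampled"]]
    return [
        name for name in COVARIATES
        if np.ptp(data[name].to_numpy(float)) == 0.0
    ]


def fit_value_model(
    rows: pd.DataFrame,
    grain_label: str = "",
    covariates: tuple[str, ...] | None = None,
) -> ValueModelFit:
    """Fit the marginal-value regression on sampled-cell rows.

    Rows with non-positive marginal value are dropped (log undefined) with a
    count; a constant covariate or otherwise rank-deficient design is fatal.
    ``covariates`` restricts the model to a subset (used at grains where
    :func:`degenerate_covariates` reports uninformative columns).
    """
    covariates = tuple(covariates if covariates is not None else COVARIATES)
    if not covariates:
        raise ValueError("no covariates to fit")
    data = rows[~rows["unsampled"]].copy()
    pos = data["marginal_value"] > 0
    n_dropped = int((~pos).sum())
    if n_dropped:
        logger.info("fit_value_model: dropped %d non-positive response rows", n_dropped)
    data = data[pos]
    if len(data) <= 10 * len(covariates):
        logger.warning(
            "fit_value_model: only %d rows for %d covariates", len(data), len(covariates)
        )

    y = np.log(data["marginal_value"].to_numpy(float))
    transforms = {}
    X = np.ones((len(data), 1 + len(covariates)))
    for k, name in enumerate(covariates):
        lx = _log_transform(name, data[name].to_numpy(float))
        mean, sd = float(np.mean(lx)), float(np.std(lx, ddof=0))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {name!r} is constant; design rank-deficient")
        transforms[name] = (mean, sd)
        X[:, 1 + k] = (lx - mean) / sd
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    res = sm.OLS(y, X).fit()
    labels = ["intercept"] + list(covariates)
    return ValueModelFit(
        grain_label=grain_label,
        params=pd.Series(res.params, index=labels),
        bse=pd.Series(res.bse, index=labels),
        pvalues=pd.Series(res.pvalues, index=labels),
        r_squared=float(res.rsquared),
        n=len(data),
        n_dropped_nonpositive=n_dropped,
        transforms=transforms,
        covariates=covariates,
    )


@dataclass
class EffectEstimate:
    """Never-sampled vs sampled contrast in log marginal value, one grain."""

    grain_label: str
    effect: float | None
    se: float | None
    pvalue: float | None
    feasible: bool
    n_unsampled: int
    n_sampled: int


def test_unsampled_effect(rows: pd.DataFrame, grain_label: str = "") -> EffectEstimate:
    """Two-group regression of log marginal value on a never-sampled flag.

    Infeasible (no estimate) when the evaluation year contains no checklist
    from a never-before-sampled cell — at coarse grains every cell may have
    a sampling history.
    """
    data = rows[rows["marginal_value"] > 0]
    flag = data["unsampled"].to_numpy(bool)
    n_un, n_sa = int(flag.sum()), int((~flag).sum())
    if n_un == 0 or n_sa == 0:
        return EffectEstimate(grain_label, None, None, None, False, n_un, n_sa)
    y = np.log(data["marginal_value"].to_numpy(float))
    X = np.column_stack([np.ones(len(y)), flag.astype(float)])
    res = sm.OLS(y, X).fit()
    return EffectEstimate(
        grain_label,
        float(res.params[1]),
        float(res.bse[1]),
        float(res.pvalues[1]),
        True,
        n_un,
        n_sa,
    )


def predict_daily_map(
    fit: ValueModelFit,
    day_params: pd.DataFrame,
    day_checklist_cells: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Expected log marginal value for every cell on one date.

    Ever-sampled cells get the model prediction from their covariates (using
    the training transforms); never-sampled cells are imputed with the mean
    of the sampled cells' predictions. Where a cell received several
    checklists that day it holds several predicted values (identical
    covariates, so identical values); one is kept, chosen uniformly at
    random with the supplied generator, and flagged in the provenance.
    """
    day_params = day_params.sort_values("cell_id").reset_index(drop=True)
    sampled = day_params["ever_sampled"].astype(bool).to_numpy()
    if not sampled.any():
        raise ValueError("no sampled cell on the grid; map undefined")
    values = np.full(len(day_params), np.nan)
    values[sampled] = fit.predict(day_params[sampled])
    mean_sampled = float(values[sampled].mean())
    values[~sampled] = mean_sampled
    provenance = np.where(sampled, "modelled", "mean-imputed")

    if day_checklist_cells is not None and len(day_checklist_cells):
        if rng is None:
            raise ValueError("an RNG is required to resolve multi-checklist cells")
        cells, counts = np.unique(
            np.asarray(day_checklist_cells, dtype=int), return_counts=True
        )
        pos = {int(c): i for i, c in enumerate(day_params["cell_id"].to_numpy())}
        for c, k in zip(cells, counts):
            if k > 1 and int(c) in pos:
                i = pos[int(c)]
                # k identical per-checklist predictions; keep one at random
                choice = int(rng.integers(k))
                values[i] = values[i]  # identical by construction
                provenance[i] = f"modelled-multi[{choice + 1}/{k}]"

    return pd.DataFrame(
        {
            "cell_id": day_params["cell_id"].to_numpy(),
            "day": day_params["day"].to_numpy(),
            "expected_log_value": values,
            "provenance": provenance,
        }
    )
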