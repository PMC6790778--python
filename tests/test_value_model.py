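import numpy as np
import pandas as pd
import pytest

import samplingvalue as sv
from samplingvalue.value_model import COVARIATES, _log_transform


def synth_rows(
    n=2000, seed=0, coefs=None, sigma=0.3, intercept=1.5, frac_unsampled=0.0,
    unsampled_shift=0.0,
):
    """Regression rows with a planted linear model on the log-z scale."""
    rng = np.random.default_rng(seed)
    coefs = dict(zip(COVARIATES, coefs if coefs is not None else
                     [0.4, 0.8, 0.2, -0.1, 0.3]))
    raw = {
        "median_interval": np.exp(rng.normal(2.0, 1.0, n)),
        "n_unique_days": np.exp(rng.normal(3.0, 1.2, n)),
        "days_since_last": np.exp(rng.normal(2.5, 1.0, n)),
        "dist_nearest_sampled": np.exp(rng.normal(1.5, 0.8, n)),
        "neighbor_median_interval": np.exp(rng.normal(2.0, 1.0, n)),
    }
    eta = np.full(n, float(intercept))
    for name in COVARIATES:
        z = _log_transform(name, raw[name])
        z = (z - z.mean()) / z.std()
        eta += coefs[name] * z
    unsampled = rng.random(n) < frac_unsampled
    eta = eta + unsampled_shift * unsampled
    log_mv = eta + (sigma * rng.standard_normal(n) if sigma else 0.0)
    rows = pd.DataFrame(raw)
    rows["marginal_value"] = np.exp(log_mv)
    rows["unsampled"] = unsampled
    rows["sampling_duration"] = raw["median_interval"] * np.exp(
        rng.normal(0, 0.05, n)
    )  # deliberately collinear with the interval
    rows["checklist_id"] = [f"L{i}" for i in range(n)]
    rows["cell_id"] = rng.integers(0, 50, n)
    rows["day"] = rng.integers(1200, 1500, n)
    return rows, coefs


def test_join_produces_one_row_per_checklist(small_pipeline):
    lev = small_pipeline["leverage"]
    retained = small_pipeline["retained"]
    import samplingvalue.grid_params as gp
    import datetime as dt

    origin = dt.date(2010, 1, 1)
    lon = retained["longitude"].to_numpy(float)
    lat = retained["latitude"].to_numpy(float)
    x, y = gp.project_lonlat(lon, lat, (lon.min(), lat.min()))
    grid = gp.make_grid((x.min(), y.min(), x.max() + 1e-9, y.max() + 1e-9), 25.0)
    cells = gp.assign_cells(x, y, grid)
    days = np.array([gp.day_number(d, origin) for d in retained["date"]])
    hist = gp.SamplingHistory.from_assignments(cells, days)
    year = max(d.year for d in retained["date"])
    in_eval = np.array([d.year == year for d in retained["date"]])
    eval_days = sorted(set(days[in_eval]))
    panel = gp.daily_parameters_panel(grid, hist, eval_days)
    eval_rows = pd.DataFrame(
        {
            "checklist_id": retained.loc[in_eval, "checklist_id"].to_numpy(),
            "cell_id": cells[in_eval],
            "day": days[in_eval],
        }
    )
    rows = sv.join_training_table(lev.marginal_value, panel, eval_rows)
    assert len(rows) == in_eval.sum()
    assert {"marginal_value", "unsampled"} <= set(rows.columns)

    with pytest.raises(ValueError, match="no evaluation-year"):
        sv.join_training_table(lev.marginal_value, panel, eval_rows.iloc[:0])
    broken = eval_rows.copy()
    broken.loc[broken.index[0], "day"] = 10 ** 6
    with pytest.raises(ValueError, match="missing grid-day"):
        sv.join_training_table(lev.marginal_value, panel, broken)


def test_collinearity_screen_flags_duration():
    rows, _ = synth_rows(n=500, seed=1)
    report, retained = sv.collinearity_screen(rows)
    assert "sampling_duration" not in retained
    assert set(retained) == set(COVARIATES)
    # the planted duration ~ median_interval pair is reported with high |r|
    pairs = set(
        map(frozenset, report[["covariate_a", "covariate_b"]].itertuples(index=False))
    )
    assert frozenset({"sampling_duration", "median_interval"}) in pairs


def test_collinearity_screen_orthogonal_covariates_clean():
    rows, _ = synth_rows(n=2000, seed=2)
    rows["sampling_duration"] = np.exp(
        np.random.default_rng(3).normal(2, 1, len(rows))
    )  # independent duration
    report, _ = sv.collinearity_screen(rows)
    assert len(report) == 0


def test_noiseless_fit_recovers_exactly():
    rows, coefs = synth_rows(n=400, sigma=0.0, seed=4)
    fit = sv.fit_value_model(rows)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    for name, truth in coefs.items():
        assert fit.params[name] == pytest.approx(truth, abs=1e-8)


def test_noisy_fit_within_three_se():
    rows, coefs = synth_rows(n=2000, sigma=0.3, seed=5)
    fit = sv.fit_value_model(rows)
    for name, truth in coefs.items():
        assert abs(fit.params[name] - truth) < 3 * fit.bse[name]


def test_constant_covariate_is_fatal():
    rows, _ = synth_rows(n=300, seed=6)
    rows["dist_nearest_sampled"] = 7.0
    with pytest.raises(ValueError, match="rank-deficient"):
        sv.fit_value_model(rows)


def test_nonpositive_responses_dropped_with_count():
    rows, _ = synth_rows(n=300, seed=7)
    rows.loc[rows.index[:5], "marginal_value"] = 0.0
    fit = sv.fit_value_model(rows)
    assert fit.n_dropped_nonpositive == 5
    assert fit.n == 295


def test_effect_sizes_invariant_to_column_order():
    rows, _ = synth_rows(n=800, seed=8)
    fit1 = sv.fit_value_model(rows)
    shuffled = rows[list(reversed(rows.columns))]
    fit2 = sv.fit_value_model(shuffled)
    pd.testing.assert_series_equal(fit1.params, fit2.params)


def test_prediction_reproduces_training_fit():
    rows, _ = synth_rows(n=500, seed=9)
    fit = sv.fit_value_model(rows)
    data = rows[~rows["unsampled"] & (rows["marginal_value"] > 0)]
    yhat = fit.predict(data)
    resid = np.log(data["marginal_value"].to_numpy()) - yhat
    # OLS residuals are orthogonal to the design: mean residual ~ 0
    assert abs(resid.mean()) < 1e-10
    y = np.log(data["marginal_value"].to_numpy())
    assert 1 - resid.var() / y.var() == pytest.approx(fit.r_squared, abs=1e-10)


def test_unsampled_effect_recovery_and_feasibility():
    delta = 0.6
    rows, _ = synth_rows(n=1000, seed=10, frac_unsampled=0.3, unsampled_shift=delta)
    est = sv.test_unsampled_effect(rows, "10km")
    assert est.feasible
    assert abs(est.effect - delta) < 3 * est.se
    none = sv.test_unsampled_effect(rows[~rows["unsampled"]], "50km")
    assert not none.feasible and none.effect is None


def test_unsampled_effect_null_calibration():
    rejections = 0
    reps = 200
    for seed in range(reps):
        rows, _ = synth_rows(
            n=150, seed=1000 + seed, frac_unsampled=0.3, unsampled_shift=0.0
        )
        est = sv.test_unsampled_effect(rows)
        rejections += est.pvalue < 0.05
    assert 0.02 <= rejections / reps <= 0.09


def _map_inputs(seed=0):
    rows, _ = synth_rows(n=800, seed=seed)
    fit = sv.fit_value_model(rows)
    rng = np.random.default_rng(seed)
    day_params = pd.DataFrame(
        {
            "cell_id": np.arange(30),
            "day": 1400,
            "ever_sampled": np.r_[np.ones(20, bool), np.zeros(10, bool)],
            "median_interval": np.exp(rng.normal(2, 1, 30)),
            "n_unique_days": np.exp(rng.normal(3, 1, 30)),
            "days_since_last": np.exp(rng.normal(2.5, 1, 30)),
            "dist_nearest_sampled": np.exp(rng.normal(1.5, 0.8, 30)),
            "neighbor_median_interval": np.exp(rng.normal(2, 1, 30)),
            "sampling_duration": np.exp(rng.normal(2, 1, 30)),
        }
    )
    observed = np.array([0, 0, 0, 4, 7])  # cell 0 has three same-day checklists
    return fit, day_params, observed


def test_map_imputes_unsampled_cells_with_sampled_mean():
    fit, day_params, observed = _map_inputs()
    rng = np.random.default_rng(1)
    m = sv.predict_daily_map(fit, day_params, observed, rng)
    modelled = m[m["provenance"].str.startswith("modelled")]
    imputed = m[m["provenance"] == "mean-imputed"]
    assert len(imputed) == 10
    np.testing.assert_allclose(
        imputed["expected_log_value"], modelled["expected_log_value"].mean()
    )
    # every cell exactly once
    assert sorted(m["cell_id"]) == list(range(30))


def test_map_prediction_at_training_means_is_intercept():
    fit, day_params, _ = _map_inputs()
    at_means = day_params.iloc[:1].copy()
    for name in COVARIATES:
        mean, _ = fit.transforms[name]
        at_means[name] = np.expm1(mean) if name == "dist_nearest_sampled" else np.exp(mean)
    assert fit.predict(at_means)[0] == pytest.approx(fit.params["intercept"])


def test_map_is_deterministic_given_seed():
    fit, day_params, observed = _map_inputs()
    m1 = sv.predict_daily_map(fit, day_params, observed, np.random.default_rng(7))
    m2 = sv.predict_daily_map(fit, day_params, observed, np.random.default_rng(7))
    pd.testing.assert_frame_equal(m1, m2)
    m3 = sv.predict_daily_map(fit, day_params, observed, np.random.default_rng(8))
    # values identical; only the recorded multi-checklist choice may differ
    np.testing.assert_allclose(m1["expected_log_value"], m3["expected_log_value"])


def test_map_requires_a_sampled_cell():
    fit, day_params, _ = _map_inputs()
    day_params["ever_sampled"] = False
    with pytest.raises(ValueError, match="no sampled cell"):
        sv.predict_daily_map(fit, day_params, None, None)
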