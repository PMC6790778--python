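import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import samplingvalue as sv
from samplingvalue.grid_params import SamplingHistory, daily_parameters


def test_grid_tiling_counts():
    grid = sv.make_grid((0, 0, 20, 20), 5.0)
    assert (grid.nx, grid.ny, grid.n_cells) == (4, 4, 16)
    big = sv.make_grid((0, 0, 20, 20), 100.0)
    assert big.n_cells == 1
    with pytest.raises(ValueError):
        sv.make_grid((0, 0, 20, 20), 0.0)
    with pytest.raises(ValueError):
        sv.make_grid((0, 0, 0, 20), 5.0)


def test_geographic_region_requires_projection():
    with pytest.raises(ValueError, match="projection"):
        sv.make_grid((150.0, -34.0, 151.0, -33.0), 5.0, geographic=True)
    grid = sv.make_grid(
        (150.0, -34.0, 151.0, -33.0), 5.0, geographic=True,
        projection_origin=(150.0, -34.0),
    )
    assert grid.n_cells > 100  # ~1 degree is ~92-111 km across


def test_boundary_cells_are_clipped():
    grid = sv.make_grid((0, 0, 18, 18), 5.0)
    cent = grid.centroids()
    # interior cell centre vs clipped last-column centre (15..18 -> 16.5)
    assert cent[0].tolist() == [2.5, 2.5]
    assert cent[3][0] == pytest.approx(16.5)


def test_assign_cells_conventions():
    grid = sv.make_grid((0, 0, 20, 20), 5.0)
    cent = grid.centroids()
    ids = sv.assign_cells(cent[:, 0], cent[:, 1], grid)
    np.testing.assert_array_equal(ids, grid.cell_ids())  # centroid -> own cell
    # shared edge: half-open convention puts (5, 0) in column 1
    assert sv.assign_cells([5.0], [0.0], grid)[0] == 1
    assert sv.assign_cells([-1.0], [25.0], grid)[0] == -1  # outside dropped


def test_hand_computed_history_example(fixtures):
    """Cell sampled on days {1,3,7} queried at day 10."""
    grid = fixtures["grid_history"]["grid"]
    hist = SamplingHistory(fixtures["grid_history"]["cell_days"])
    params = daily_parameters(grid, hist, 10).set_index("cell_id")
    cell = params.loc[5]
    assert cell["ever_sampled"]
    assert cell["median_interval"] == 3.0        # gaps {2, 4}
    assert cell["days_since_last"] == 3.0
    assert cell["sampling_duration"] == 6.0
    assert cell["n_unique_days"] == 3
    # an unsampled neighbour inherits the sampled cell's interval
    other = params.loc[0]
    assert not other["ever_sampled"]
    assert other["neighbor_median_interval"] == 3.0
    assert other["dist_nearest_sampled"] > 0


def test_yesterday_only_history(fixtures):
    grid = fixtures["grid_history"]["grid"]
    hist = SamplingHistory({5: np.array([9])})
    cell = daily_parameters(grid, hist, 10).set_index("cell_id").loc[5]
    assert cell["days_since_last"] == 1
    assert cell["n_unique_days"] == 1
    assert cell["sampling_duration"] == 0
    assert cell["median_interval"] == 1.0        # single-day floor


def test_nearest_neighbour_excludes_self(fixtures):
    grid = fixtures["grid_history"]["grid"]
    hist = SamplingHistory({5: np.array([1]), 6: np.array([2])})
    params = daily_parameters(grid, hist, 10).set_index("cell_id")
    # two adjacent sampled cells: each one's nearest sampled cell is the other
    assert params.loc[5, "dist_nearest_sampled"] == pytest.approx(5.0)
    assert params.loc[6, "dist_nearest_sampled"] == pytest.approx(5.0)
    # a single sampled cell has no neighbour: distance degenerates to 0
    lone = daily_parameters(grid, SamplingHistory({5: np.array([1])}), 10)
    assert lone.set_index("cell_id").loc[5, "dist_nearest_sampled"] == 0.0


def test_future_samples_do_not_leak(fixtures):
    grid = fixtures["grid_history"]["grid"]
    before = daily_parameters(
        grid, SamplingHistory({5: np.array([1, 3, 7])}), 10
    )
    after = daily_parameters(
        grid, SamplingHistory({5: np.array([1, 3, 7, 12]), 2: np.array([11])}), 10
    )
    pd.testing.assert_frame_equal(before, after)


@settings(max_examples=60, deadline=None)
@given(st.data())
def test_causality_property(fixtures, data):
    """Appending future-dated samples never changes earlier parameters."""
    grid = fixtures["grid_history"]["grid"]
    n_cells = grid.n_cells
    base = data.draw(
        st.dictionaries(
            st.integers(0, n_cells - 1),
            st.lists(st.integers(0, 50), min_size=1, max_size=8),
            min_size=1, max_size=5,
        )
    )
    query_day = data.draw(st.integers(1, 60))
    future_cell = data.draw(st.integers(0, n_cells - 1))
    future_days = data.draw(
        st.lists(st.integers(query_day, query_day + 30), min_size=1, max_size=4)
    )
    hist = SamplingHistory({c: np.array(d) for c, d in base.items()})
    extended = {c: list(d) for c, d in base.items()}
    extended.setdefault(future_cell, []).extend(future_days)
    hist2 = SamplingHistory({c: np.array(d) for c, d in extended.items()})
    pd.testing.assert_frame_equal(
        daily_parameters(grid, hist, query_day),
        daily_parameters(grid, hist2, query_day),
    )


def test_monotone_accumulation(fixtures):
    grid = fixtures["grid_history"]["grid"]
    rng = np.random.default_rng(3)
    hist = SamplingHistory(
        {int(c): rng.integers(0, 40, size=6) for c in rng.choice(16, 5, replace=False)}
    )
    panel = sv.daily_parameters_panel(grid, hist, list(range(1, 45)))
    for _, cell_rows in panel.groupby("cell_id"):
        nud = cell_rows.sort_values("day")["n_unique_days"].to_numpy()
        assert (np.diff(nud) >= 0).all()
        ever = cell_rows.sort_values("day")["ever_sampled"].to_numpy()
        assert not (ever[:-1] & ~ever[1:]).any()  # never reverts
        med = cell_rows["median_interval"].dropna()
        assert (med >= 1).all()
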