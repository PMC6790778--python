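import datetime as dt
import pathlib

import numpy as np
import pandas as pd
import pytest

import samplingvalue as sv

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixtures():
    return sv.make_fixtures()


@pytest.fixture(scope="session")
def small_world_path(tmp_path_factory):
    """A modest synthetic world written as an EBD-style TSV (seed fixed)."""
    cfg = sv.reduced_config(n_checklists=1200, n_species=8, seed=11)
    table, truth = sv.simulate_world(cfg)
    path = tmp_path_factory.mktemp("world") / "world.tsv"
    sv.write_world(table, path)
    return path, truth


@pytest.fixture(scope="session")
def small_pipeline(small_world_path):
    """Checklists, fits and leverage for the small world, shared read-only."""
    path, truth = small_world_path
    obs = sv.read_observations(path)
    checklists = sv.collapse_to_checklists(obs)
    cfg = sv.FilterConfig(species_min_obs_exclusive=30)
    retained, report = sv.filter_checklists(checklists, cfg)
    species = sv.select_species(retained, cfg)
    presence = sv.zero_fill(retained, species)
    design = sv.build_design(retained)
    fits = sv.fit_all_trends(design, presence)
    lev = sv.build_leverage_table(fits)
    return {
        "truth": truth,
        "checklists": checklists,
        "retained": retained,
        "report": report,
        "species": species,
        "presence": presence,
        "design": design,
        "fits": fits,
        "leverage": lev,
    }


def make_checklist_frame(rows):
    """Build a checklist table from (id, county, date, time, dur, dist, area,
    complete, species) tuples."""
    recs = []
    for cid, county, date, time_h, dur, dist, area, complete, species in rows:
        recs.append(
            {
                "checklist_id": cid,
                "latitude": -33.8,
                "longitude": 151.1,
                "county": county,
                "date": date,
                "start_time": time_h,
                "duration_minutes": dur,
                "distance_km": dist,
                "area_ha": area,
                "is_complete": complete,
                "species_observed": frozenset(species),
                "list_length": len(species),
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def basic_checklists():
    sp = [f"s{i}" for i in range(1, 8)]
    return make_checklist_frame(
        [
            ("A", "c1", dt.date(2012, 5, 1), 9.0, 60, 1.0, np.nan, True, sp[:5]),
            ("B", "c1", dt.date(2012, 6, 1), 10.0, 90, np.nan, np.nan, True, sp[:6]),
            ("C", "c2", dt.date(2013, 1, 15), 7.5, 30, 2.0, np.nan, True, sp[1:7]),
        ]
    )
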