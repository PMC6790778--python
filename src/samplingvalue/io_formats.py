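"""Reading and writing checklist tables.

Input is an eBird Basic Dataset (EBD)-style tab-separated file with one row
per species observation. The functions here parse those rows, collapse them
to checklist level (one row per sampling event, with the set of species seen
and the list length), and pivot to a zero-filled presence/absence matrix.
Zero-filling — treating a species missing from a checklist as an absence —
is valid only for *complete* checklists, where the observer affirmed that
every detected species was reported.

Tables are held as pandas DataFrames with fixed internal column names; a
configurable column map decouples the pipeline from EBD header churn and
lets the simulator write the same schema.
"""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("samplingvalue")

#: internal field -> default EBD header
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "checklist_id": "SAMPLING EVENT IDENTIFIER",
    "species_code": "SCIENTIFIC NAME",
    "latitude": "LATITUDE",
    "longitude": "LONGITUDE",
    "county": "COUNTY",
    "date": "OBSERVATION DATE",
    "start_time": "TIME OBSERVATIONS STARTED",
    "duration_minutes": "DURATION MINUTES",
    "distance_km": "EFFORT DISTANCE KM",
    "area_ha": "EFFORT AREA HA",
    "is_complete": "ALL SPECIES REPORTED",
}

MANDATORY_FIELDS = (
    "checklist_id",
    "species_code",
    "latitude",
    "longitude",
    "county",
    "date",
    "is_complete",
)

#: checklist-level metadata that must be identical across a checklist's rows
CHECKLIST_META = (
    "latitude",
    "longitude",
    "county",
    "date",
    "start_time",
    "duration_minutes",
    "distance_km",
    "area_ha",
    "is_complete",
)


def _parse_time(value) -> float:
    """Parse an HH:MM[:SS] clock string to fractional hours; NaN if absent."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if not s:
        return np.nan
    parts = s.split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"unparseable time {value!r}")
    h, m = int(parts[0]), int(parts[1])
    sec = int(parts[2]) if len(parts) == 3 else 0
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= sec < 60):
        raise ValueError(f"unparseable time {value!r}")
    return h + m / 60.0 + sec / 3600.0


def read_observations(
    path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read an EBD-style TSV into a typed observation-row table.

    Parameters
    ----------
    path : str or path-like
        Tab-separated file with a header row.
    column_map : mapping, optional
        Internal field name -> header in the file. Defaults to the EBD
        headers in :data:`DEFAULT_COLUMN_MAP`; missing *optional* fields are
        filled with NA, missing mandatory fields are fatal.

    Returns
    -------
    DataFrame with internal column names, one row per (checklist, species)
    pair after deduplication. Rows with unparseable dates or times are
    dropped and counted.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [cmap[f] for f in MANDATORY_FIELDS if cmap[f] not in raw.columns]
    if missing:
        raise ValueError(f"mandatory column(s) missing from {path}: {missing}")

    df = pd.DataFrame(index=raw.index)
    for field, header in cmap.items():
        if header in raw.columns:
            col = raw[header]
            df[field] = col.where(col.astype(str).str.len() > 0, np.nan)
        else:
            df[field] = np.nan

    n_in = len(df)
    bad = pd.Series(False, index=df.index)

    def _coerce(col, fn):
        nonlocal bad
        out, err = [], pd.Series(False, index=df.index)
        for i, v in df[col].items():
            try:
                out.append(fn(v))
            except (ValueError, TypeError):
                out.append(None)
                err[i] = True
        bad |= err
        return out

    df["date"] = _coerce(
        "date", lambda v: _dt.date.fromisoformat(str(v).strip())
    )
    df["start_time"] = _coerce("start_time", _parse_time)
    for col in ("latitude", "longitude", "duration_minutes", "distance_km", "area_ha"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["is_complete"] = (
        df["is_complete"].astype(str).str.strip().str.lower().isin(["1", "true", "t", "yes"])
    )

    bad |= ~df["latitude"].between(-90, 90) | ~df["longitude"].between(-180, 180)
    df = df[~bad]
    n_rejected = int(bad.sum())

    n_before_dedup = len(df)
    df = df.drop_duplicates(subset=["checklist_id", "species_code"], keep="first")
    df = df.reset_index(drop=True)
    logger.info(
        "read_observations: %d rows in, %d rejected, %d duplicates collapsed, %d retained",
        n_in, n_rejected, n_before_dedup - len(df), len(df),
    )
    return df


def collapse_to_checklists(rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse deduplicated observation rows to one row per checklist.

    The result has one row per ``checklist_id`` carrying the (shared)
    checklist metadata, a frozenset ``species_observed``, and
    ``list_length = |species_observed|``. Conflicting metadata for a single
    checklist id is fatal.
    """
    if rows.duplicated(subset=["checklist_id", "species_code"]).any():
        raise ValueError("observation rows are not deduplicated")

    meta = [c for c in CHECKLIST_META if c in rows.columns]
    grouped = rows.groupby("checklist_id", sort=True)
    nun = grouped[meta].nunique(dropna=False)
    conflicts = nun[(nun > 1).any(axis=1)]
    if len(conflicts):
        cid = conflicts.index[0]
        fields = list(nun.columns[(nun.loc[cid] > 1)])
        raise ValueError(
            f"inconsistent checklist metadata for {cid!r} in fields {fields}"
        )

    out = grouped[meta].first()
    out["species_observed"] = grouped["species_code"].agg(frozenset)
    out["list_length"] = out["species_observed"].map(len)
    out = out.reset_index()
    return out


def zero_fill(checklists: pd.DataFrame, species_set) -> pd.DataFrame:
    """Build the n x m zero-filled presence/absence matrix.

    Rows are checklist ids (input order), columns are sorted species codes;
    entry 1 iff the species is on the checklist. Absences are inferred, which
    presumes complete checklists.
    """
    species = sorted(species_set)
    if not species:
        raise ValueError("species_set is empty")
    if "is_complete" in checklists.columns and not checklists["is_complete"].all():
        raise ValueError("zero_fill requires complete checklists only")
    idx = pd.Index(checklists["checklist_id"], name="checklist_id")
    mat = np.zeros((len(idx), len(species)), dtype=np.int8)
    col_of = {s: j for j, s in enumerate(species)}
    for i, obs in enumerate(checklists["species_observed"]):
        for s in obs:
            j = col_of.get(s)
            if j is not None:
                mat[i, j] = 1
    return pd.DataFrame(mat, index=idx, columns=species)


def write_checklists(checklists: pd.DataFrame, path) -> None:
    """Write a checklist table to CSV (species set serialized as ';'-joined)."""
    out = checklists.copy()
    out["species_observed"] = out["species_observed"].map(
        lambda s: ";".join(sorted(s))
    )
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_checklists(path) -> pd.DataFrame:
    """Read a checklist table written by :func:`write_checklists`."""
    df = pd.read_csv(path)
    df["species_observed"] = df["species_observed"].map(
        lambda s: frozenset() if pd.isna(s) or s == "" else frozenset(str(s).split(";"))
    )
    df["date"] = df["date"].map(_dt.date.fromisoformat)
    df["checklist_id"] = df["checklist_id"].astype(str)
    df["county"] = df["county"].astype(str)
    df["list_length"] = df["species_observed"].map(len)
    return df
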