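"""Checklist and species filters for trend modelling.

Six checklist-level rules, applied in a fixed order so that the audit report
attributes each removal to the first rule it fails:

  complete -> diurnal start time -> duration in (5, 240) min ->
  (distance < 5 km) or (area < 500 ha) -> list length > 4

plus a species-level rule keeping species with more than 50 observations
among the retained checklists (optionally intersected with a terrestrial
allow-list). Checklists shorter than five species are excluded because very
short lists tend to be targeted searches rather than general surveys, and
stationary checklists (no distance or area recorded) pass the travel rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("samplingvalue")

RULE_ORDER = ("complete", "diurnal", "duration", "distance_area", "list_length")


@dataclass
class FilterConfig:
    require_complete: bool = True
    min_duration_minutes: float = 5.0
    max_duration_minutes: float = 240.0
    max_distance_km: float = 5.0
    max_area_ha: float = 500.0
    min_species_exclusive: int = 4          # keep list_length > 4
    diurnal_window: tuple[float, float] = (5.0, 20.0)  # [start, end) local hours
    terrestrial_species: frozenset[str] | None = None
    species_min_obs_exclusive: int = 50     # keep species with > 50 observations

    def __post_init__(self):
        if self.min_duration_minutes >= self.max_duration_minutes:
            raise ValueError("min_duration must be < max_duration")
        if self.diurnal_window[0] >= self.diurnal_window[1]:
            raise ValueError("diurnal window start must precede end")


@dataclass
class FilterReport:
    """Audit of filter attrition; removals counted at the first failing rule."""

    input_total: int = 0
    output_total: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    species_retained: int | None = None
    species_removed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_total)]
        rows += [(f"removed_{r}", self.removed.get(r, 0)) for r in RULE_ORDER]
        rows.append(("output", self.output_total))
        if self.species_retained is not None:
            rows.append(("species_retained", self.species_retained))
            rows.append(("species_removed", self.species_removed))
        return pd.DataFrame(rows, columns=["item", "count"])


def _rule_masks(checklists: pd.DataFrame, config: FilterConfig) -> dict[str, pd.Series]:
    """Per-rule pass masks (True = passes)."""
    c = checklists
    masks = {}
    masks["complete"] = (
        c["is_complete"].astype(bool)
        if config.require_complete
        else pd.Series(True, index=c.index)
    )
    lo, hi = config.diurnal_window
    st = pd.to_numeric(c["start_time"], errors="coerce")
    masks["diurnal"] = (st >= lo) & (st < hi)
    masks["diurnal"] = masks["diurnal"].fillna(False)

    dur = pd.to_numeric(c["duration_minutes"], errors="coerce")
    masks["duration"] = (dur > config.min_duration_minutes) & (
        dur < config.max_duration_minutes
    )
    masks["duration"] = masks["duration"].fillna(False)

    dist = pd.to_numeric(c["distance_km"], errors="coerce")
    area = pd.to_numeric(c["area_ha"], errors="coerce")
    stationary = dist.isna() & area.isna()
    masks["distance_area"] = (
        stationary
        | (dist < config.max_distance_km).fillna(False)
        | (area < config.max_area_ha).fillna(False)
    )
    masks["list_length"] = c["list_length"] > config.min_species_exclusive
    return masks


def filter_checklists(
    checklists: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply all checklist rules; return retained checklists and the audit."""
    report = FilterReport(input_total=len(checklists))
    masks = _rule_masks(checklists, config)
    still_in = pd.Series(True, index=checklists.index)
    for rule in RULE_ORDER:
        failed_here = still_in & ~masks[rule]
        report.removed[rule] = int(failed_here.sum())
        still_in &= masks[rule]
    retained = checklists[still_in].reset_index(drop=True)
    report.output_total = len(retained)
    logger.info(
        "filter_checklists: %d -> %d (%s)",
        report.input_total,
        report.output_total,
        ", ".join(f"{r}={report.removed[r]}" for r in RULE_ORDER),
    )
    return retained, report


def species_observation_counts(checklists: pd.DataFrame) -> pd.Series:
    """Number of retained checklists recording each species."""
    counts: dict[str, int] = {}
    for obs in checklists["species_observed"]:
        for s in obs:
            counts[s] = counts.get(s, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def select_species(
    checklists: pd.DataFrame,
    config: FilterConfig,
    report: FilterReport | None = None,
) -> list[str]:
    """Species with more than ``species_min_obs_exclusive`` observations.

    If a terrestrial allow-list is configured, only its members qualify;
    without one the taxonomic rule is skipped with a warning. The returned
    order is sorted species code (deterministic).
    """
    counts = species_observation_counts(checklists)
    keep = counts[counts > config.species_min_obs_exclusive]
    if config.terrestrial_species is not None:
        keep = keep[keep.index.isin(config.terrestrial_species)]
    else:
        logger.warning("no terrestrial allow-list given; taxonomic rule skipped")
    selected = sorted(keep.index)
    if report is not None:
        report.species_retained = len(selected)
        report.species_removed = len(counts) - len(selected)
    if not selected:
        raise ValueError(
            "no species passed the observation-count filter; no models fittable"
        )
    return selected
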