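"""Flower density and richness from quadrat / transect surveys.

Per-species density is floral units per m²: the mean of the ten 1 m²
quadrat counts for species recorded in the quadrats, or the whole-transect
total divided by the 100 m² transect area for rare species counted along
the full transect.  Daily patch-level density sums the species densities;
daily richness counts the species actually flowering (density > 0) that
day.  Monthly covariates are unweighted means over the sampled days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import FlowerSurveyRecord, month_of

__all__ = [
    "FloralAvailability",
    "TRANSECT_AREA_M2",
    "species_density",
    "daily_availability",
    "monthly_availability",
    "availability_table",
    "monthly_table",
]

TRANSECT_AREA_M2 = 100.0


@dataclass(frozen=True)
class FloralAvailability:
    """Flower density (floral units / m²) and flowering-species richness for one patch/day."""

    patch_id: str
    date: object
    flower_density: float
    flower_richness: int

    def __post_init__(self) -> None:
        if (self.flower_density == 0) != (self.flower_richness == 0):
            raise ValueError("density is 0 exactly when richness is 0")


def species_density(record: FlowerSurveyRecord) -> float:
    """Floral units per m² for one species on one patch/day."""
    if record.quadrat_counts is not None:
        return sum(record.quadrat_counts) / len(record.quadrat_counts)
    return record.transect_total / TRANSECT_AREA_M2


def daily_availability(
    records: Sequence[FlowerSurveyRecord],
    patch_id: str | None = None,
    date: object | None = None,
) -> FloralAvailability:
    """Patch/day flower density (sum over species) and richness (species with density > 0).

    An empty record list is a surveyed day with nothing in flower: density
    0, richness 0 (the patch/date context must then be passed explicitly).
    All records must share one patch and date.
    """
    if not records:
        if patch_id is None or date is None:
            raise ValueError("empty survey needs explicit patch_id and date")
        return FloralAvailability(patch_id, date, 0.0, 0)
    keys = {(r.patch_id, r.date) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple patch/days: {sorted(keys)}")
    densities = [species_density(r) for r in records]
    density = sum(densities)
    richness = sum(1 for d in densities if d > 0)
    (patch_id, date), = keys
    return FloralAvailability(patch_id, date, density, richness)


def availability_table(records: Iterable[FlowerSurveyRecord]) -> pd.DataFrame:
    """Daily availability for every surveyed patch/day.

    Returns a DataFrame with columns patch, date, month, flower_density,
    flower_richness, sorted by patch then date.
    """
    rows = []
    by_day: dict[tuple, list[FlowerSurveyRecord]] = {}
    for r in records:
        by_day.setdefault((r.patch_id, r.date), []).append(r)
    for (patch_id, date), recs in sorted(by_day.items()):
        av = daily_availability(recs)
        rows.append(
            {
                "patch": patch_id,
                "date": date,
                "month": month_of(date),
                "flower_density": av.flower_density,
                "flower_richness": av.flower_richness,
            }
        )
    return pd.DataFrame(
        rows, columns=["patch", "date", "month", "flower_density", "flower_richness"]
    )


def monthly_availability(
    table: pd.DataFrame, patch_id: str, month: str
) -> tuple[float, float]:
    """(mean density, mean richness) over the patch's sampled days in a month.

    Returns (nan, nan) when the patch has no surveyed day that month.
    """
    sub = table[(table["patch"] == patch_id) & (table["month"] == month)]
    if sub.empty:
        return (math.nan, math.nan)
    return (float(sub["flower_density"].mean()), float(sub["flower_richness"].mean()))


def monthly_table(table: pd.DataFrame) -> pd.DataFrame:
    """Monthly roll-up: mean daily density and richness per patch x month."""
    if table.empty:
        return pd.DataFrame(columns=["patch", "month", "flower_density", "flower_richness"])
    out = (
        table.groupby(["patch", "month"], as_index=False)[["flower_density", "flower_richness"]]
        .mean()
        .sort_values(["patch", "month"])
        .reset_index(drop=True)
    )
    return out
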