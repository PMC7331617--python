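"""Data model and tabular IO for the bee-walk study.

Three plain CSV tables drive the whole pipeline:

* visits — one row per observed pollinator–plant visit event
  (``patch,date,pollinator,plant,visits``), with pre-aggregated counts
  allowed;
* flowers — quadrat / whole-transect floral-unit surveys
  (``patch,date,plant,quadrat_counts,transect_total``), quadrat counts as a
  semicolon-joined list of the ten 1 m² square counts;
* patches — patch geometry and landscape attributes
  (``patch,size_ha,perimeter_m,corridor,centroid_x,centroid_y`` plus
  optional ``cover_<class>`` fraction columns).

Dates are ISO (YYYY-MM-DD).  Months are derived from the calendar date;
the study design covers June–August, so records outside that window are
kept but flagged (an optional remap, e.g. early-September → August, can be
supplied).  Species aliasing (notably lumping *B. lucorum* and
*B. terrestris*, which cannot be told apart in the field, into one
analysis taxon) is applied at read time from a user-editable mapping.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .networks import QuantNetwork

__all__ = [
    "VisitRecord",
    "FlowerSurveyRecord",
    "PatchGeometry",
    "SpeciesAliasMap",
    "DEFAULT_ALIASES",
    "FormatError",
    "read_visits",
    "write_visits",
    "read_flowers",
    "write_flowers",
    "read_patches",
    "write_patches",
    "build_daily_network",
]

log = logging.getLogger(__name__)

STUDY_MONTHS = ("June", "July", "August")

_MONTH_NAMES = {
    1: "January", 2: "February", 3: "March", 4: "April", 5: "May", 6: "June",
    7: "July", 8: "August", 9: "September", 10: "October", 11: "November",
    12: "December",
}


class FormatError(ValueError):
    """Raised for malformed input tables (missing columns, bad rows)."""


def month_of(date: dt.date, remap: Mapping[str, str] | None = None) -> str:
    """Calendar month name of a date, optionally remapped (e.g. September->August)."""
    name = _MONTH_NAMES[date.month]
    if remap and name in remap:
        return remap[name]
    return name


@dataclass(frozen=True, order=True)
class VisitRecord:
    """A single observed pollinator–plant visit event on a bee walk."""

    patch_id: str
    date: dt.date
    pollinator: str
    plant: str
    visits: int

    def __post_init__(self) -> None:
        if self.visits < 1:
            raise ValueError(f"visits must be >= 1, got {self.visits}")

    @property
    def month(self) -> str:
        return month_of(self.date)

    @property
    def in_study_window(self) -> bool:
        return self.month in STUDY_MONTHS


@dataclass(frozen=True)
class FlowerSurveyRecord:
    """Floral-unit survey for one plant species on one patch/day.

    Exactly one of ``quadrat_counts`` (the ten 1 m² square counts, for
    species appearing in the squares) or ``transect_total`` (floral units
    over the whole 100 m² transect, for rare species) is present.
    """

    patch_id: str
    date: dt.date
    plant: str
    quadrat_counts: tuple[int, ...] | None = None
    transect_total: int | None = None

    def __post_init__(self) -> None:
        if (self.quadrat_counts is None) == (self.transect_total is None):
            raise ValueError(
                "exactly one of quadrat_counts / transect_total must be present"
            )
        if self.quadrat_counts is not None:
            if len(self.quadrat_counts) != 10:
                raise ValueError("quadrat_counts must list the 10 square counts")
            if any(c < 0 for c in self.quadrat_counts):
                raise ValueError("quadrat counts must be non-negative")
        if self.transect_total is not None and self.transect_total < 0:
            raise ValueError("transect_total must be non-negative")

    @property
    def month(self) -> str:
        return month_of(self.date)


@dataclass(frozen=True)
class PatchGeometry:
    """Forest-patch geometry and optional landscape context."""

    patch_id: str
    size: float            # hectares
    perimeter: float       # metres
    corridor_connected: bool = False
    centroid: tuple[float, float] | None = None   # metres
    cover_fractions: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"patch size must be > 0 ha, got {self.size}")
        if self.perimeter <= 0:
            raise ValueError(f"patch perimeter must be > 0 m, got {self.perimeter}")
        if self.cover_fractions is not None:
            total = sum(self.cover_fractions.values())
            if total > 1 + 1e-6:
                raise ValueError(f"cover fractions sum to {total} > 1")
            if any(f < 0 for f in self.cover_fractions.values()):
                raise ValueError("cover fractions must be non-negative")


# Field identification cannot separate B. lucorum from B. terrestris, so the
# two are analysed as one taxon; shipped as the default aliasing example.
DEFAULT_ALIASES: dict[str, str] = {
    "Bombus lucorum": "Bombus lucorum/terrestris",
    "Bombus terrestris": "Bombus lucorum/terrestris",
    "B. lucorum": "B. lucorum/terrestris",
    "B. terrestris": "B. lucorum/terrestris",
}


@dataclass(frozen=True)
class SpeciesAliasMap:
    """Raw species label -> canonical analysis taxon.

    Labels without an explicit entry map to themselves, so the mapping is
    total over any label set.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def canonical(self, label: str) -> str:
        return self.mapping.get(label, label)

    @classmethod
    def from_yaml(cls, path) -> "SpeciesAliasMap":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"alias file {path} must map raw label -> canonical label")
        return cls({str(k): str(v) for k, v in raw.items()})


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_date(value, path, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise FormatError(f"{path}, line {line}: unparseable date {value!r}") from exc


def read_visits(
    path,
    aliases: SpeciesAliasMap | None = None,
    month_remap: Mapping[str, str] | None = None,
) -> list[VisitRecord]:
    """Read the visitation table, apply species aliases, derive months.

    Records are returned in deterministic (patch, date, pollinator, plant)
    order.  Rows with ``visits < 1`` or unparseable dates raise a
    :class:`FormatError` naming the offending line.  Dates outside the
    June–August study window are kept and logged.
    """
    aliases = aliases or SpeciesAliasMap()
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["patch", "date", "pollinator", "plant", "visits"], path)
    records: list[VisitRecord] = []
    for row in df.itertuples():
        line = row.Index + 2  # header is line 1
        date = _parse_date(row.date, path, line)
        try:
            visits = int(row.visits)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {line}: bad visit count {row.visits!r}") from exc
        if visits < 1:
            raise FormatError(f"{path}, line {line}: visits must be >= 1, got {visits}")
        rec = VisitRecord(
            patch_id=str(row.patch),
            date=date,
            pollinator=aliases.canonical(str(row.pollinator)),
            plant=str(row.plant),
            visits=visits,
        )
        if month_of(date, month_remap) not in STUDY_MONTHS:
            log.warning("%s line %d: date %s outside June-August window", path, line, date)
        records.append(rec)
    records.sort()
    return records


def write_visits(records: Iterable[VisitRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "patch": r.patch_id,
                "date": r.date.isoformat(),
                "pollinator": r.pollinator,
                "plant": r.plant,
                "visits": r.visits,
            }
            for r in sorted(records)
        ]
    )
    if df.empty:
        df = pd.DataFrame(columns=["patch", "date", "pollinator", "plant", "visits"])
    df.to_csv(path, index=False)


def read_flowers(path) -> list[FlowerSurveyRecord]:
    """Read the flower-survey table (quadrat or whole-transect counts per row)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["patch", "date", "plant", "quadrat_counts", "transect_total"], path)
    records: list[FlowerSurveyRecord] = []
    for row in df.itertuples():
        line = row.Index + 2
        date = _parse_date(row.date, path, line)
        has_quadrats = isinstance(row.quadrat_counts, str) and row.quadrat_counts.strip()
        has_transect = isinstance(row.transect_total, str) and row.transect_total.strip()
        if bool(has_quadrats) == bool(has_transect):
            raise FormatError(
                f"{path}, line {line}: exactly one of quadrat_counts / transect_total required"
            )
        try:
            quadrats = (
                tuple(int(v) for v in row.quadrat_counts.split(";")) if has_quadrats else None
            )
            transect = int(row.transect_total) if has_transect else None
        except ValueError as exc:
            raise FormatError(f"{path}, line {line}: bad count field") from exc
        try:
            records.append(
                FlowerSurveyRecord(
                    patch_id=str(row.patch), date=date, plant=str(row.plant),
                    quadrat_counts=quadrats, transect_total=transect,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}, line {line}: {exc}") from exc
    records.sort(key=lambda r: (r.patch_id, r.date, r.plant))
    return records


def write_flowers(records: Iterable[FlowerSurveyRecord], path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: (r.patch_id, r.date, r.plant)):
        rows.append(
            {
                "patch": r.patch_id,
                "date": r.date.isoformat(),
                "plant": r.plant,
                "quadrat_counts": ";".join(map(str, r.quadrat_counts))
                if r.quadrat_counts is not None
                else "",
                "transect_total": "" if r.transect_total is None else str(r.transect_total),
            }
        )
    df = pd.DataFrame(rows, columns=["patch", "date", "plant", "quadrat_counts", "transect_total"])
    df.to_csv(path, index=False)


def read_patches(path) -> list[PatchGeometry]:
    """Read the patch geometry table; ``cover_<class>`` columns become fractions."""
    df = pd.read_csv(path)
    _require_columns(df, ["patch", "size_ha", "perimeter_m", "corridor"], path)
    cover_cols = [c for c in df.columns if c.startswith("cover_")]
    has_centroid = "centroid_x" in df.columns and "centroid_y" in df.columns
    out: list[PatchGeometry] = []
    for row in df.itertuples():
        line = row.Index + 2
        centroid = None
        if has_centroid and pd.notna(row.centroid_x) and pd.notna(row.centroid_y):
            centroid = (float(row.centroid_x), float(row.centroid_y))
        cover = None
        if cover_cols:
            cover = {
                c[len("cover_"):]: float(getattr(row, c))
                for c in cover_cols
                if pd.notna(getattr(row, c))
            }
        try:
            out.append(
                PatchGeometry(
                    patch_id=str(row.patch),
                    size=float(row.size_ha),
                    perimeter=float(row.perimeter_m),
                    corridor_connected=bool(int(row.corridor)),
                    centroid=centroid,
                    cover_fractions=cover or None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}, line {line}: {exc}") from exc
    out.sort(key=lambda p: p.patch_id)
    return out


def write_patches(patches: Iterable[PatchGeometry], path) -> None:
    patches = list(patches)
    classes = sorted(
        {k for p in patches if p.cover_fractions for k in p.cover_fractions}
    ) if any(p.cover_fractions for p in patches) else []
    rows = []
    for p in sorted(patches, key=lambda p: p.patch_id):
        row = {
            "patch": p.patch_id,
            "size_ha": p.size,
            "perimeter_m": p.perimeter,
            "corridor": int(p.corridor_connected),
            "centroid_x": p.centroid[0] if p.centroid else "",
            "centroid_y": p.centroid[1] if p.centroid else "",
        }
        for cls in classes:
            row[f"cover_{cls}"] = (p.cover_fractions or {}).get(cls, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def build_daily_network(
    visits: Iterable[VisitRecord], patch_id: str, date: dt.date
) -> QuantNetwork:
    """Pollinator x plant visit-count matrix for one patch on one sampling day.

    Duplicate (pollinator, plant) rows are summed into one cell.  A day
    without visits yields the empty-network sentinel rather than an error:
    zero-visit days are real observations and the resampling unit of the
    standardization step.
    """
    day = [v for v in visits if v.patch_id == patch_id and v.date == date]
    if not day:
        return QuantNetwork.empty()
    pollinators = sorted({v.pollinator for v in day})
    plants = sorted({v.plant for v in day})
    mat = pd.DataFrame(0.0, index=pollinators, columns=plants)
    for v in day:
        mat.loc[v.pollinator, v.plant] += v.visits
    return QuantNetwork(mat)
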