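"""Sample-based standardization of visitation data across unequal effort.

Patches were surveyed on different numbers of days, which inflates
apparent abundance and richness where effort was high.  Standardization
identifies the lowest sampling effort (number of sampled days) across
patches, then repeatedly (B replicates, default 1000) draws that many days
without replacement from each better-sampled patch and averages the
resulting totals: standardized abundance is the replicate-mean total visit
count, standardized richness the replicate-mean number of distinct
pollinator taxa, and standardized networks the cell-wise replicate mean of
the summed daily interaction matrices.  The patch at minimum effort keeps
its observed values exactly.

Seeding spawns one independent stream per patch (and per month scope) from
the master seed, so adding or removing a patch never perturbs the draws of
the others, and scalar and network standardization of the same patch/scope
share identical day draws (making the standardized network's grand total
equal the standardized abundance exactly).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import STUDY_MONTHS, VisitRecord, FlowerSurveyRecord, month_of
from .networks import QuantNetwork

__all__ = [
    "SamplingCalendar",
    "StandardizedSummary",
    "min_sampling_days",
    "rarefy_scalars",
    "rarefy_network",
    "standardize_study",
]

log = logging.getLogger(__name__)

DEFAULT_REPLICATES = 1000


@dataclass(frozen=True)
class SamplingCalendar:
    """Ordered sampled dates per patch.

    Built from the survey records: a sampled day is any day with a flower
    survey or a visit record, so zero-visit days count as effort.
    """

    days: Mapping[str, tuple[dt.date, ...]]

    def __post_init__(self) -> None:
        for patch, dates in self.days.items():
            if not dates:
                raise ValueError(f"patch {patch} has an empty day list")
            if len(set(dates)) != len(dates):
                raise ValueError(f"patch {patch} has duplicate sampled dates")

    @classmethod
    def from_records(
        cls,
        visits: Iterable[VisitRecord] = (),
        flowers: Iterable[FlowerSurveyRecord] = (),
    ) -> "SamplingCalendar":
        days: dict[str, set[dt.date]] = {}
        for r in visits:
            days.setdefault(r.patch_id, set()).add(r.date)
        for r in flowers:
            days.setdefault(r.patch_id, set()).add(r.date)
        if not days:
            raise ValueError("no records to build a sampling calendar from")
        return cls({p: tuple(sorted(d)) for p, d in sorted(days.items())})

    def patches(self) -> list[str]:
        return sorted(self.days)

    def month_days(self, patch_id: str, month: str) -> tuple[dt.date, ...]:
        return tuple(d for d in self.days[patch_id] if month_of(d) == month)


@dataclass(frozen=True)
class StandardizedSummary:
    """Standardized abundance and richness for one patch (x month scope)."""

    patch_id: str
    scope: str  # month name, or "season"
    abundance: float
    richness: float
    replicates: int
    seed: int
    n_days: int
    n_min: int


def min_sampling_days(calendar: SamplingCalendar) -> int:
    """Number of sampled days in the least-sampled patch."""
    if not calendar.days:
        raise ValueError("empty sampling calendar")
    return min(len(d) for d in calendar.days.values())


def _stream(seed: int, patch_id: str, scope: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one patch/scope."""
    def h(text: str) -> int:
        return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big") % (2**31)

    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), h(patch_id), h(scope)])
    )


def _replicate_draws(
    n_days: int, n_min: int, B: int, seed: int, patch_id: str, scope: str
) -> np.ndarray:
    """B without-replacement draws of n_min day indices, shape (B, n_min).

    Scalar and network standardization both call this with identical
    arguments, so they subsample exactly the same day sets.
    """
    if B < 1:
        raise ValueError(f"replicates B must be >= 1, got {B}")
    if n_min < 1:
        raise ValueError(f"n_min must be >= 1, got {n_min}")
    if n_min > n_days:
        raise ValueError(f"cannot draw {n_min} days from {n_days}")
    rng = _stream(seed, patch_id, scope)
    # argsort of uniforms = B independent permutations; keep the first n_min
    return np.argsort(rng.random((B, n_days)), axis=1, kind="stable")[:, :n_min]


def _patch_day_arrays(
    visits: Sequence[VisitRecord], patch_id: str, days: Sequence[dt.date]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Per-day totals, species presence, and daily network stack for one patch."""
    patch_visits = [v for v in visits if v.patch_id == patch_id and v.date in set(days)]
    species = sorted({v.pollinator for v in patch_visits})
    plants = sorted({v.plant for v in patch_visits})
    day_index = {d: i for i, d in enumerate(days)}
    sp_index = {s: i for i, s in enumerate(species)}
    pl_index = {p: i for i, p in enumerate(plants)}
    totals = np.zeros(len(days))
    presence = np.zeros((len(days), len(species)), dtype=bool)
    nets = np.zeros((len(days), len(species), len(plants)))
    for v in patch_visits:
        i = day_index[v.date]
        totals[i] += v.visits
        presence[i, sp_index[v.pollinator]] = True
        nets[i, sp_index[v.pollinator], pl_index[v.plant]] += v.visits
    return totals, presence, nets, species, plants


def rarefy_scalars(
    visits: Sequence[VisitRecord],
    calendar: SamplingCalendar,
    n_min: int | None = None,
    B: int = DEFAULT_REPLICATES,
    seed: int = 0,
    per_month: bool = True,
) -> list[StandardizedSummary]:
    """Standardized abundance and richness per patch (x month by default).

    With ``per_month=True`` the minimum effort is computed per month over
    the patches sampled at least once that month, and days are drawn from
    the month-restricted pool; patch x month cells with no sampled day are
    dropped (logged).  With ``per_month=False`` a single season-level
    minimum applies.  A patch already at minimum effort keeps its observed
    totals exactly (no resampling).
    """
    if B < 1:
        raise ValueError(f"replicates B must be >= 1, got {B}")
    if n_min is not None and n_min < 1:
        raise ValueError(f"n_min must be >= 1, got {n_min}")
    out: list[StandardizedSummary] = []
    scopes: list[tuple[str, dict[str, tuple[dt.date, ...]]]]
    if per_month:
        scopes = []
        for month in STUDY_MONTHS:
            pools = {
                p: calendar.month_days(p, month)
                for p in calendar.patches()
                if calendar.month_days(p, month)
            }
            if pools:
                scopes.append((month, pools))
            skipped = [p for p in calendar.patches() if not calendar.month_days(p, month)]
            for p in skipped:
                log.info("patch %s has no sampled day in %s; cell dropped", p, month)
    else:
        scopes = [("season", {p: calendar.days[p] for p in calendar.patches()})]

    for scope, pools in scopes:
        scope_min = n_min if n_min is not None else min(len(d) for d in pools.values())
        for patch_id, days in sorted(pools.items()):
            totals, presence, _, _, _ = _patch_day_arrays(visits, patch_id, days)
            if len(days) == scope_min:
                abundance = float(totals.sum())
                richness = float(presence.any(axis=0).sum())
            else:
                draws = _replicate_draws(len(days), scope_min, B, seed, patch_id, scope)
                abundance = float(totals[draws].sum(axis=1).mean())
                richness = float(presence[draws].any(axis=1).sum(axis=1).mean())
            out.append(
                StandardizedSummary(
                    patch_id=patch_id, scope=scope, abundance=abundance,
                    richness=richness, replicates=B, seed=seed,
                    n_days=len(days), n_min=scope_min,
                )
            )
    return out


def rarefy_network(
    visits: Sequence[VisitRecord],
    calendar: SamplingCalendar,
    patch_id: str,
    n_min: int | None = None,
    B: int = DEFAULT_REPLICATES,
    seed: int = 0,
    scope: str = "season",
) -> QuantNetwork:
    """Standardized interaction network for one patch (cell-wise replicate mean).

    Each replicate sums the daily pollinator x plant matrices of ``n_min``
    randomly drawn days; cells are averaged over replicates, giving a
    real-valued network.  Taxa absent from every replicate are dropped.
    Shares the day draws of :func:`rarefy_scalars` for the same
    patch/scope, so the grand total equals the standardized abundance.
    """
    if scope == "season":
        days = calendar.days[patch_id]
        pool_min = min(len(d) for d in calendar.days.values())
    else:
        days = calendar.month_days(patch_id, scope)
        pools = [
            calendar.month_days(p, scope)
            for p in calendar.patches()
            if calendar.month_days(p, scope)
        ]
        pool_min = min(len(d) for d in pools) if pools else 0
    if not days:
        return QuantNetwork.empty()
    n_min = n_min if n_min is not None else pool_min
    _, _, nets, species, plants = _patch_day_arrays(visits, patch_id, days)
    if not species:
        return QuantNetwork.empty()
    if len(days) == n_min:
        mean_net = nets.sum(axis=0)
    else:
        draws = _replicate_draws(len(days), n_min, B, seed, patch_id, scope)
        mean_net = nets[draws].sum(axis=1).mean(axis=0)
    return QuantNetwork(
        pd.DataFrame(mean_net, index=species, columns=plants)
    ).drop_empty_margins()


def standardize_study(
    visits: Sequence[VisitRecord],
    calendar: SamplingCalendar,
    B: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, QuantNetwork]]:
    """Full standardization: per patch x month scalars + per-patch networks.

    Returns the standardized summary table (patch, month, abundance,
    richness, B, seed) and one season-scope standardized network per patch.
    """
    summaries = rarefy_scalars(visits, calendar, B=B, seed=seed, per_month=True)
    table = pd.DataFrame(
        [
            {
                "patch": s.patch_id, "month": s.scope, "abundance": s.abundance,
                "richness": s.richness, "replicates": s.replicates, "seed": s.seed,
                "n_days": s.n_days, "n_min": s.n_min,
            }
            for s in summaries
        ]
    )
    networks = {
        p: rarefy_network(visits, calendar, p, B=B, seed=seed, scope="season")
        for p in calendar.patches()
    }
    return table, networks
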