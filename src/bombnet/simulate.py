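"""Synthetic bee-walk study generator with recorded ground truth.

Emulates the structure of a one-summer, 24-patch fragmentation study:

* a landscape of forest patches with centroids, sizes, perimeters,
  corridor flags and buffer land-cover shares arranged along a
  fragmentation gradient (isolated, complex-shaped patches at one end,
  forest-embedded patches at the other);
* an uneven sampling calendar (patches sampled on ~15.6 +/- 2.9 days,
  truncated at 5, across June-August);
* a flowering community whose per-species densities respond to patch
  shape complexity (+) and surrounding forest (-), surveyed through ten
  1 m² quadrats (rare species through whole-transect counts);
* species-specific bumblebee visitation: per patch/day/species visit
  totals are Poisson with a log-linear predictor in patch isolation,
  percent forest, flower density x month, a month main effect and a
  patch random intercept — exactly the model family fitted downstream —
  allocated to flowering plants by species diet vectors drawn once per
  study from a symmetric Dirichlet whose concentration dials diet breadth
  (low = specialist, high = generalist).

Every generating coefficient, diet vector and patch intercept is recorded
in :class:`SimGroundTruth` so recovery tests can compare estimates with
the truth.  Defaults are calibrated to the study scale: 24 patches, ten
bumblebee taxa with realistic rank abundances, and a seasonal total of
roughly 850 visits.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    FlowerSurveyRecord,
    PatchGeometry,
    VisitRecord,
    write_flowers,
    write_patches,
    write_visits,
)

__all__ = [
    "SimSpecies",
    "SimConfig",
    "SimGroundTruth",
    "SimStudy",
    "simulate_landscape",
    "simulate_calendar",
    "simulate_flora",
    "simulate_visits",
    "simulate_study",
    "emit_study",
]

SEASON_START = dt.date(2007, 6, 1)
SEASON_END = dt.date(2007, 8, 31)

# Rank-abundance skeleton of a southern-Norway bumblebee community: the two
# generalists dominate, one forest specialist (hypnorum) tracks forest cover.
_DEFAULT_SPECIES = (
    ("Bombus pascuorum", 279, 0.0),
    ("Bombus lucorum/terrestris", 255, -0.3),
    ("Bombus wurflenii", 74, 0.1),
    ("Bombus lapidarius", 67, 0.2),
    ("Bombus hortorum", 56, -0.1),
    ("Bombus hypnorum", 54, 0.4),
    ("Bombus pratorum", 47, 0.1),
    ("Bombus sylvarum", 11, -0.2),
    ("Bombus jonellus", 9, 0.3),
)

_DEFAULT_PLANTS = tuple(f"Plant_{i:02d}" for i in range(1, 16))


@dataclass(frozen=True)
class SimSpecies:
    """Generating parameters of one bumblebee taxon."""

    name: str
    baseline: float      # log expected visits per patch-day at covariate means
    beta_forest: float   # habitat preference: effect of %forest (z-scored)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic bee-walk season.

    Effect sizes are on z-scored covariates, so they are standardized
    coefficients in the log-linear visitation model.
    """

    n_patches: int = 24
    # sampling calendar: days per patch ~ Normal(15.62, 2.93), truncated >= 5
    sampling_days_mean: float = 15.62
    sampling_days_sd: float = 2.93
    sampling_days_min: int = 5
    # landscape
    region_size_m: float = 1200.0     # side of the square the centroids fall in
    n_corridor: int = 4               # corridor-connected patches (isolation 0)
    k_neighbours: int = 5
    gradient_strength: float = 1.0    # 0 = independent covariates
    # flora
    plants: tuple[str, ...] = _DEFAULT_PLANTS
    flora_shape_effect: float = 0.3   # log-density response to shape complexity
    flora_forest_effect: float = 0.3  # log-density decline with %forest
    # visitation model
    # baseline = log(per patch-day rate) calibrated so the season total lands
    # near the study's ~860 visits once month, flower and random-effect terms
    # (which lift the mean via Jensen's inequality) are folded in
    species: tuple[SimSpecies, ...] = tuple(
        SimSpecies(name, math.log(count / 374.0) - 0.11, bf)
        for name, count, bf in _DEFAULT_SPECIES
    )
    beta_isolation: float = -0.2
    beta_flower_density: Mapping[str, float] = field(
        default_factory=lambda: {"June": 0.15, "July": 0.35, "August": 0.15}
    )
    beta_month: Mapping[str, float] = field(
        default_factory=lambda: {"June": 0.0, "July": 0.4, "August": -0.3}
    )
    patch_sd: float = 0.3             # random-intercept SD
    diet_concentration: float = 1.0   # symmetric Dirichlet over plants
    # standardization constants for the flower-density term of the
    # generating model, applied on the log1p scale (heavy-tailed daily
    # densities would otherwise blow up the Poisson rate)
    fd_center: float = 1.5
    fd_scale: float = 0.6

    def __post_init__(self) -> None:
        if self.n_patches < 2:
            raise ValueError("need at least 2 patches")
        if self.diet_concentration <= 0:
            raise ValueError("Dirichlet concentration must be > 0")
        if self.sampling_days_min < 1:
            raise ValueError("sampling_days_min must be >= 1")
        for b in self.beta_flower_density.values():
            if not math.isfinite(b):
                raise ValueError("rate parameters must be finite")


@dataclass
class SimGroundTruth:
    """Everything needed to recompute any expected value of the simulation."""

    config: SimConfig
    seed: int
    patch_intercepts: dict[str, float]
    diets: pd.DataFrame            # species x plant diet probabilities
    covariates: pd.DataFrame       # realized landscape covariates (incl. z-scores)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) and k == "plants" else v)
                for k, v in dataclasses.asdict(self.config).items()
                if k != "species"
            },
            "species": [dataclasses.asdict(s) for s in self.config.species],
            "patch_intercepts": self.patch_intercepts,
            "diets": self.diets.to_dict(),
            "covariates": self.covariates.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


@dataclass
class SimStudy:
    """A complete synthetic study: inputs plus ground truth."""

    patches: list[PatchGeometry]
    covariates: pd.DataFrame
    calendar: dict[str, tuple[dt.date, ...]]
    flowers: list[FlowerSurveyRecord]
    visits: list[VisitRecord]
    truth: SimGroundTruth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_landscape(
    config: SimConfig, seed: int
) -> tuple[list[PatchGeometry], pd.DataFrame]:
    """Patch geometries plus realized covariate table.

    Isolation is genuinely geometric (mean distance to the k nearest
    simulated centroids, zeroed for corridor patches), and the other
    fragmentation covariates are tied to it with strength
    ``gradient_strength``: isolated patches tend to have complex shapes
    and little surrounding forest.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 1]))
    n = config.n_patches
    ids = [f"P{i + 1:02d}" for i in range(n)]
    xy = rng.uniform(0, config.region_size_m, size=(n, 2))
    diff = xy[:, None, :] - xy[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dmat, np.inf)
    k = min(config.k_neighbours, n - 1)
    iso_geo = np.sort(dmat, axis=1)[:, :k].mean(axis=1)
    corridor = np.zeros(n, dtype=bool)
    if config.n_corridor > 0:
        corridor[rng.choice(n, size=min(config.n_corridor, n), replace=False)] = True
    isolation = np.where(corridor, 0.0, iso_geo)

    g = config.gradient_strength
    frag = _zscore(isolation)  # fragmentation gradient axis
    log_sc = math.log(350.0) + 0.35 * g * frag + rng.normal(0, 0.25, n)
    shape_complexity = np.exp(log_sc)                   # m per ha
    size = np.exp(rng.normal(math.log(3.0), 0.8, n))    # ha
    perimeter = shape_complexity * size                 # m
    pct_forest = np.clip(55.0 - 20.0 * g * frag + rng.normal(0, 10.0, n), 2.0, 98.0)
    pct_crop = np.clip(95.0 - pct_forest - np.abs(rng.normal(5.0, 3.0, n)), 0.0, None)

    patches = [
        PatchGeometry(
            patch_id=ids[i],
            size=float(size[i]),
            perimeter=float(perimeter[i]),
            corridor_connected=bool(corridor[i]),
            centroid=(float(xy[i, 0]), float(xy[i, 1])),
            cover_fractions={
                "forest": float(pct_forest[i] / 100.0),
                "cropland": float(pct_crop[i] / 100.0),
            },
        )
        for i in range(n)
    ]
    cov = pd.DataFrame(
        {
            "patch": ids,
            "size_ha": size,
            "perimeter_m": perimeter,
            "shape_complexity": shape_complexity,
            "isolation_m": isolation,
            "pct_forest_500m": pct_forest,
            "pct_cropland_500m": pct_crop,
            "iso_z": _zscore(isolation),
            "forest_z": _zscore(pct_forest),
            "shape_z": _zscore(shape_complexity),
        }
    )
    return patches, cov


def simulate_calendar(config: SimConfig, seed: int) -> dict[str, tuple[dt.date, ...]]:
    """Uneven sampling calendar: per-patch day counts ~ truncated normal."""
    rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 2]))
    season = [
        SEASON_START + dt.timedelta(days=i)
        for i in range((SEASON_END - SEASON_START).days + 1)
    ]
    out: dict[str, tuple[dt.date, ...]] = {}
    for i in range(config.n_patches):
        while True:
            n_days = int(round(rng.normal(config.sampling_days_mean, config.sampling_days_sd)))
            if n_days >= config.sampling_days_min:
                break
        n_days = min(n_days, len(season))
        chosen = rng.choice(len(season), size=n_days, replace=False)
        out[f"P{i + 1:02d}"] = tuple(sorted(season[j] for j in chosen))
    return out


def simulate_flora(
    config: SimConfig,
    covariates: pd.DataFrame,
    calendar: Mapping[str, Sequence[dt.date]],
    seed: int,
) -> list[FlowerSurveyRecord]:
    """Quadrat/transect flower surveys for every sampled patch/day.

    Per-species log densities respond to shape complexity (+) and percent
    forest (-) and follow a triangular June-August phenology.  Species
    expected to show up in the ten quadrats get Poisson quadrat counts via
    multinomial thinning of the 10 m² total; sparse species are counted
    along the whole 100 m² transect.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 3]))
    n_plants = len(config.plants)
    base = rng.normal(math.log(0.25), 0.6, n_plants)     # per-m2 density scale
    peak_month = rng.choice([6, 7, 8], size=n_plants)
    cov = covariates.set_index("patch")
    records: list[FlowerSurveyRecord] = []
    for patch, days in sorted(calendar.items()):
        shape_z = float(cov.loc[patch, "shape_z"])
        forest_z = float(cov.loc[patch, "forest_z"])
        for date in days:
            for s, plant in enumerate(config.plants):
                season_term = -0.5 * abs(date.month - peak_month[s])
                log_density = (
                    base[s]
                    + config.flora_shape_effect * shape_z
                    - config.flora_forest_effect * forest_z
                    + season_term
                    + rng.normal(0, 0.4)
                )
                density = float(np.exp(log_density))
                if density >= 0.05:
                    total10 = rng.poisson(10.0 * density)
                    quadrats = rng.multinomial(total10, np.full(10, 0.1))
                    records.append(
                        FlowerSurveyRecord(
                            patch_id=patch, date=date, plant=plant,
                            quadrat_counts=tuple(int(c) for c in quadrats),
                        )
                    )
                else:
                    total = int(rng.poisson(100.0 * density))
                    if total > 0:
                        records.append(
                            FlowerSurveyRecord(
                                patch_id=patch, date=date, plant=plant,
                                transect_total=total,
                            )
                        )
    return records


def _daily_flower_densities(
    flowers: Sequence[FlowerSurveyRecord],
) -> dict[tuple[str, dt.date], dict[str, float]]:
    from .flowers import species_density

    out: dict[tuple[str, dt.date], dict[str, float]] = {}
    for r in flowers:
        out.setdefault((r.patch_id, r.date), {})[r.plant] = species_density(r)
    return out


def simulate_visits(
    config: SimConfig,
    covariates: pd.DataFrame,
    flowers: Sequence[FlowerSurveyRecord],
    calendar: Mapping[str, Sequence[dt.date]],
    seed: int,
) -> tuple[list[VisitRecord], SimGroundTruth]:
    """Species-specific Poisson visitation allocated to flowering plants.

    Per patch/day/species visit totals follow
    ``Poisson(exp(b0_s + b_iso * iso_z + b_forest_s * forest_z
    + b_fd[month] * fd_z + b_month[month] + u_patch))`` where ``fd_z`` is
    that day's realized flower density, log1p-transformed and standardized
    by the configured constants.  Totals are spread over the plants flowering that day by a
    multinomial with the species' Dirichlet diet vector restricted to
    those plants and renormalized; a day with nothing in flower yields
    zero visits.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 4]))
    cov = covariates.set_index("patch")
    species_names = [s.name for s in config.species]
    diets = pd.DataFrame(
        rng.dirichlet(np.full(len(config.plants), config.diet_concentration),
                      size=len(species_names)),
        index=species_names,
        columns=list(config.plants),
    )
    u = {p: float(rng.normal(0, config.patch_sd)) for p in sorted(calendar)}
    density_by_day = _daily_flower_densities(flowers)
    month_name = {6: "June", 7: "July", 8: "August"}

    visits: list[VisitRecord] = []
    for patch, days in sorted(calendar.items()):
        iso_z = float(cov.loc[patch, "iso_z"])
        forest_z = float(cov.loc[patch, "forest_z"])
        for date in days:
            month = month_name.get(date.month)
            if month is None:
                continue
            densities = density_by_day.get((patch, date), {})
            flowering = [p for p, d in densities.items() if d > 0]
            fd = sum(densities.values())
            fd_z = (math.log1p(fd) - config.fd_center) / config.fd_scale
            for sp in config.species:
                eta = (
                    sp.baseline
                    + config.beta_isolation * iso_z
                    + sp.beta_forest * forest_z
                    + config.beta_flower_density[month] * fd_z
                    + config.beta_month[month]
                    + u[patch]
                )
                total = int(rng.poisson(np.exp(eta)))
                if total == 0 or not flowering:
                    continue
                probs = diets.loc[sp.name, flowering].to_numpy(dtype=float)
                if probs.sum() <= 0:
                    probs = np.full(len(flowering), 1.0 / len(flowering))
                else:
                    probs = probs / probs.sum()
                counts = rng.multinomial(total, probs)
                for plant, c in zip(flowering, counts):
                    if c > 0:
                        visits.append(
                            VisitRecord(
                                patch_id=patch, date=date, pollinator=sp.name,
                                plant=plant, visits=int(c),
                            )
                        )
    visits.sort()
    truth = SimGroundTruth(
        config=config, seed=seed, patch_intercepts=u, diets=diets,
        covariates=covariates.copy(),
    )
    return visits, truth


def simulate_study(config: SimConfig | None = None, seed: int = 0) -> SimStudy:
    """Run the full generator: landscape -> calendar -> flora -> visitation."""
    config = config or SimConfig()
    patches, covariates = simulate_landscape(config, seed)
    calendar = simulate_calendar(config, seed)
    flowers = simulate_flora(config, covariates, calendar, seed)
    visits, truth = simulate_visits(config, covariates, flowers, calendar, seed)
    return SimStudy(
        patches=patches, covariates=covariates, calendar=calendar,
        flowers=flowers, visits=visits, truth=truth,
    )


def emit_study(study: SimStudy, outdir) -> dict[str, Path]:
    """Write the three pipeline input CSVs plus the ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": outdir / "visits.csv",
        "flowers": outdir / "flowers.csv",
        "patches": outdir / "patches.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_visits(study.visits, paths["visits"])
    write_flowers(study.flowers, paths["flowers"])
    write_patches(study.patches, paths["patches"])
    study.truth.to_json(paths["ground_truth"])
    return paths
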