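"""Stage orchestration: chain the analysis from raw tables to model selection.

Each stage reads and writes plain CSV artifacts so any intermediate can be
inspected, diffed, or recomputed in isolation:

``simulate``     -> visits.csv, flowers.csv, patches.csv, ground_truth.json
``flowers``      -> flower_daily.csv, flower_monthly.csv
``landscape``    -> landscape.csv
``standardize``  -> standardized_summary.csv, networks/<patch>.csv
``networks``     -> network_metrics.csv, pac/<patch>.csv
``models``       -> model_selection.csv, model_terms.csv

``run_all`` chains them.  Model responses follow the field conventions:
standardized abundance and richness are Poisson with a patch random
intercept and month forced into every candidate (rounded to integers,
since replicate-averaged counts are not integral); H2' and interspecific
competition are Gamma (log link) with at most two / one predictors;
intraspecific competition is Gaussian.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import flowers as fl
from . import io
from . import landscape as ls
from . import models as md
from . import networks as nw
from . import standardize as st
from .simulate import SimConfig, emit_study, simulate_study

__all__ = ["RunConfig", "run_all", "stage_flowers", "stage_landscape",
           "stage_standardize", "stage_networks", "stage_models", "stage_simulate"]

log = logging.getLogger(__name__)

PREDICTORS = [
    "size_ha", "shape_complexity", "isolation_m",
    "pct_forest_500m", "flower_density", "flower_richness",
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds and defaults; every field is CLI-overridable."""

    replicates: int = st.DEFAULT_REPLICATES
    seed: int = 0
    vif_threshold: float = 3.0
    focal_threshold: float = 0.5
    k_neighbours: int = ls.DEFAULT_K_NEIGHBOURS
    buffer_radius_m: float = ls.DEFAULT_BUFFER_RADIUS_M
    inter_aggregation: str = "mean"
    inter_direction: str = "on_others"
    abundance_max_terms: int | None = 2
    h2_max_terms: int = 2
    competition_max_terms: int = 1


def _zscore_cols(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        sd = out[c].std(ddof=0)
        out[c + "_z"] = (out[c] - out[c].mean()) / sd if sd > 0 else 0.0
    return out


def stage_simulate(outdir: Path, config: SimConfig | None = None, seed: int = 0) -> dict:
    study = simulate_study(config, seed=seed)
    return emit_study(study, outdir)


def stage_flowers(flowers_csv, outdir: Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = io.read_flowers(flowers_csv)
    daily = fl.availability_table(records)
    monthly = fl.monthly_table(daily)
    daily_path = outdir / "flower_daily.csv"
    monthly_path = outdir / "flower_monthly.csv"
    daily.to_csv(daily_path, index=False)
    monthly.to_csv(monthly_path, index=False)
    return {"flower_daily": daily_path, "flower_monthly": monthly_path}


def stage_landscape(patches_csv, outdir: Path, cfg: RunConfig = RunConfig(),
                    distances_csv=None) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patches = io.read_patches(patches_csv)
    distances = (
        pd.read_csv(distances_csv, index_col=0) if distances_csv is not None else None
    )
    table = ls.covariate_table(patches, k=cfg.k_neighbours, distances=distances)
    path = outdir / "landscape.csv"
    table.to_csv(path, index=False)
    return {"landscape": path}


def stage_standardize(visits_csv, flowers_csv, outdir: Path,
                      cfg: RunConfig = RunConfig()) -> dict[str, Path]:
    outdir = Path(outdir)
    (outdir / "networks").mkdir(parents=True, exist_ok=True)
    visits = io.read_visits(visits_csv, aliases=io.SpeciesAliasMap(io.DEFAULT_ALIASES))
    flower_recs = io.read_flowers(flowers_csv)
    calendar = st.SamplingCalendar.from_records(visits, flower_recs)
    table, networks = st.standardize_study(
        visits, calendar, B=cfg.replicates, seed=cfg.seed
    )
    summary_path = outdir / "standardized_summary.csv"
    table.to_csv(summary_path, index=False)
    paths = {"standardized_summary": summary_path}
    for patch, net in networks.items():
        p = outdir / "networks" / f"{patch}.csv"
        net.to_csv(p)
        paths[f"network_{patch}"] = p
    return paths


def stage_networks(network_dir, outdir: Path, cfg: RunConfig = RunConfig()) -> dict[str, Path]:
    outdir = Path(outdir)
    (outdir / "pac").mkdir(parents=True, exist_ok=True)
    networks = {
        p.stem: nw.QuantNetwork.read_csv(p)
        for p in sorted(Path(network_dir).glob("*.csv"))
    }
    focal = nw.focal_species_filter(networks, threshold=cfg.focal_threshold)
    rows = []
    paths: dict[str, Path] = {}
    n_degenerate = 0
    for patch, net in networks.items():
        row: dict = {"patch": patch, "h2prime": nw.h2prime(net)}
        if np.isnan(row["h2prime"]):
            n_degenerate += 1
        if not net.is_empty and len(net.drop_empty_margins().pollinators) >= 1:
            pac = nw.muller_pac(net)
            p = outdir / "pac" / f"{patch}.csv"
            pac.d.to_csv(p, index_label="pollinator")
            paths[f"pac_{patch}"] = p
            for taxon in focal:
                row[f"inter__{taxon}"] = nw.interspecific_index(
                    pac, taxon, aggregation=cfg.inter_aggregation,
                    direction=cfg.inter_direction,
                )
                row[f"intra__{taxon}"] = nw.intraspecific_index(pac, taxon)
        rows.append(row)
    if n_degenerate:
        log.info("%d degenerate networks excluded from H2' (sentinel NaN)", n_degenerate)
    metrics = pd.DataFrame(rows)
    path = outdir / "network_metrics.csv"
    metrics.to_csv(path, index=False)
    paths["network_metrics"] = path
    return paths


def _safe_name(taxon: str) -> str:
    return taxon.replace(" ", "_").replace("/", "_").replace(".", "")


def stage_models(summary_csv, landscape_csv, flower_monthly_csv, metrics_csv,
                 outdir: Path, cfg: RunConfig = RunConfig()) -> dict[str, Path]:
    """VIF screening + AICc dredge for every response of the study design."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = pd.read_csv(summary_csv)
    land = pd.read_csv(landscape_csv)
    monthly = pd.read_csv(flower_monthly_csv)
    metrics = pd.read_csv(metrics_csv)

    # patch x month table for abundance/richness GLMMs
    pm = summary.merge(land, on="patch").merge(monthly, on=["patch", "month"], how="left")
    pm = pm.dropna(subset=["flower_density"])
    # patch-level table for the network indices (season-mean flower covariates)
    season_fl = monthly.groupby("patch", as_index=False)[
        ["flower_density", "flower_richness"]
    ].mean()
    pl = metrics.merge(land, on="patch").merge(season_fl, on="patch", how="left")

    retained, vif_trace = md.vif_screen(
        pl[PREDICTORS].dropna(), threshold=cfg.vif_threshold
    )
    vif_trace.to_csv(outdir / "vif_trace.csv", index=False)
    zcols = [p + "_z" for p in retained]
    pm = _zscore_cols(pm, retained)
    pl = _zscore_cols(pl, retained)

    selection_rows = []
    term_rows = []

    def _run(name, data, response, family, predictors, interactions=(),
             forced=(), max_terms=None, group=None):
        try:
            sel = md.dredge(data, response, family, predictors,
                            interactions=interactions, forced=forced,
                            max_terms=max_terms, group=group)
        except (RuntimeError, ValueError) as exc:
            log.warning("model stage: %s skipped (%s)", name, exc)
            return
        best = sel.best
        selection_rows.append(
            {"response": name, "family": family,
             "best_terms": " + ".join(best.spec.terms) or "1",
             "aicc": md.aicc(best),
             "n_alternatives": len(sel.alternatives)}
        )
        # per-variable LRT against the best model without that variable
        for term in best.spec.terms:
            if term in forced:
                continue
            reduced_terms = tuple(
                t for t in best.spec.terms
                if t != term and not (":" in t and term in t.split(":"))
            )
            try:
                reduced = md.fit_model(
                    dataclasses.replace(best.spec, terms=reduced_terms), data
                )
                chi2, dfree, p = md.lrt(reduced, best)
            except (ValueError, NotImplementedError) as exc:
                log.warning("LRT for %s / %s failed: %s", name, term, exc)
                continue
            term_rows.append({"response": name, "variable": term,
                              "chi2": chi2, "df": dfree, "p": p})

    pm_fit = pm.copy()
    pm_fit["abundance_int"] = pm_fit["abundance"].round().astype(int)
    pm_fit["richness_int"] = pm_fit["richness"].round().astype(int)
    inter_terms = [f"{z}:month" for z in zcols]
    _run("abundance", pm_fit, "abundance_int", "poisson", zcols,
         interactions=inter_terms, forced=("month",),
         max_terms=cfg.abundance_max_terms, group="patch")
    _run("richness", pm_fit, "richness_int", "poisson", zcols,
         interactions=inter_terms, forced=("month",),
         max_terms=cfg.abundance_max_terms, group="patch")

    h2 = pl.dropna(subset=["h2prime"])
    _run("h2prime", h2, "h2prime", "gamma", zcols, max_terms=cfg.h2_max_terms)

    for col in [c for c in pl.columns if c.startswith("inter__")]:
        taxon = col.split("__", 1)[1]
        data = pl.dropna(subset=[col]).rename(columns={col: "response_value"})
        _run(f"interspecific[{taxon}]", data, "response_value", "gamma",
             zcols, max_terms=cfg.competition_max_terms)
    for col in [c for c in pl.columns if c.startswith("intra__")]:
        taxon = col.split("__", 1)[1]
        data = pl.dropna(subset=[col]).rename(columns={col: "response_value"})
        _run(f"intraspecific[{taxon}]", data, "response_value", "gaussian",
             zcols, max_terms=cfg.competition_max_terms)

    sel_path = outdir / "model_selection.csv"
    pd.DataFrame(selection_rows).to_csv(sel_path, index=False)
    term_path = outdir / "model_terms.csv"
    pd.DataFrame(term_rows, columns=["response", "variable", "chi2", "df", "p"]).to_csv(
        term_path, index=False
    )
    return {"model_selection": sel_path, "model_terms": term_path,
            "vif_trace": outdir / "vif_trace.csv"}


def run_all(outdir, cfg: RunConfig = RunConfig(),
            sim_config: SimConfig | None = None,
            inputs: dict | None = None) -> dict[str, Path]:
    """Full chain; simulates inputs unless existing CSV paths are given."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    if inputs is None:
        artifacts.update(stage_simulate(outdir / "inputs", sim_config, seed=cfg.seed))
        inputs = {k: artifacts[k] for k in ("visits", "flowers", "patches")}
    for key in ("visits", "flowers", "patches"):
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input file not found: {inputs[key]}")
    artifacts.update(stage_flowers(inputs["flowers"], outdir))
    artifacts.update(stage_landscape(inputs["patches"], outdir, cfg))
    artifacts.update(stage_standardize(inputs["visits"], inputs["flowers"], outdir, cfg))
    artifacts.update(stage_networks(outdir / "networks", outdir, cfg))
    artifacts.update(
        stage_models(artifacts["standardized_summary"], artifacts["landscape"],
                     artifacts["flower_monthly"], artifacts["network_metrics"],
                     outdir, cfg)
    )
    return artifacts
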