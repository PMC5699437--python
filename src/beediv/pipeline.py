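"""End-to-end orchestration: simulate → impute → diversity → fit →
project → mismatch, with seeded stage RNGs and a run manifest.

A single master seed is fanned out to independent per-stage child seeds,
so re-running any stage from its persisted inputs reproduces its outputs
exactly. Every run writes a ``manifest.json`` recording the seed, the
stage seeds, the package version and the SHA-256 hash of every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import synthetic
from ._util import child_seeds
from .diversity import effort_correct, site_diversity
from .mismatch import mismatch_extremes, ols_residual_map, second_stage_residuals
from .models import (
    ModelSpec,
    backward_select_fixed,
    bootstrap_ci,
    fit_lmm,
    gvif,
    marginal_r2,
    morans_i,
    prepare_model_frame,
    select_random_effects,
    type2_anova,
)
from .projection import baseline_map, country_summary, predict_map, relative_map
from .rasters import RasterStack, read_stack, write_ascii_grid, write_stack
from .traits_phylo import (
    graft_missing_species,
    impute_traits,
    phylo_eigenvectors,
    read_trees,
    sample_trees,
    write_trees,
)

logger = logging.getLogger("beediv")

STAGES = ("simulate", "impute", "diversity", "fit", "project", "mismatch")


@dataclass
class RunConfig:
    """Pipeline configuration; all sizes refer to the synthetic system."""

    seed: int = 0
    outdir: str = "beediv_run"
    stages: tuple[str, ...] = STAGES
    # synthetic sizes
    n_species: int = 60
    n_studies: int = 10
    sites_per_study: int = 30
    raster_shape: tuple[int, int] = (30, 40)
    n_countries: int = 5
    frac_partial: float = 0.117
    frac_total: float = 0.041
    frac_missing_from_tree: float = 0.10
    n_trees_grafted: int = 25
    n_trees_sampled: int = 8
    # modelling
    alpha: float = 0.05
    n_boot: int = 0  # parametric bootstrap repeats (0 = skip)
    select_random: bool = True
    # external inputs (used when the simulate stage is switched off)
    sites_csv: str | None = None
    communities_csv: str | None = None
    traits_csv: str | None = None
    tree_newick: str | None = None
    raster_dir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "raster_shape" in raw:
            raw["raster_shape"] = tuple(raw["raster_shape"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate(config: RunConfig) -> None:
    if "simulate" not in config.stages:
        needed = {
            "sites_csv": config.sites_csv,
            "communities_csv": config.communities_csv,
            "traits_csv": config.traits_csv,
            "tree_newick": config.tree_newick,
        }
        missing = [k for k, v in needed.items() if not v]
        if missing:
            raise ValueError(
                f"simulate stage disabled but input path(s) missing: {missing}"
            )
        for k, v in needed.items():
            if v and not Path(v).exists():
                raise FileNotFoundError(f"{k}: {v}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    _validate(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, child_seeds(config.seed, len(STAGES))))
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": dataclasses.asdict(config),
        "artifacts": {},
    }
    art = manifest["artifacts"]

    def save_df(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        art[name] = _sha256(p)
        return p

    state: dict = {}
    try:
        if "simulate" in config.stages:
            _stage_simulate(config, seeds["simulate"], out, state, art)
        else:
            _load_inputs(config, state)
        if "impute" in config.stages:
            _stage_impute(config, seeds["impute"], out, state, art)
        if "diversity" in config.stages:
            _stage_diversity(config, seeds["diversity"], out, state, art, save_df)
        if "fit" in config.stages:
            _stage_fit(config, seeds["fit"], out, state, art, save_df)
        if "project" in config.stages:
            _stage_project(config, out, state, art, save_df)
        if "mismatch" in config.stages:
            _stage_mismatch(config, out, state, art)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage context: {exc}") from exc

    p = out / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config, seed, out, state, art):
    logger.info("stage simulate (seed %d)", seed)
    s_tree, s_traits, s_sites, s_comm, s_rast, s_mask = child_seeds(seed, 6)
    tree, pool = synthetic.simulate_tree(config.n_species, seed=s_tree)
    traits = synthetic.simulate_traits(tree, seed=s_traits)
    sites = synthetic.simulate_sites(
        config.n_studies, config.sites_per_study, seed=s_sites
    )
    truth = synthetic.default_ground_truth()
    comm = synthetic.simulate_communities(sites, pool, tree, traits, truth, seed=s_comm)
    stack = synthetic.simulate_rasters(config.raster_shape, config.n_countries, seed=s_rast)
    masked, mask = synthetic.mask_traits(
        traits, config.frac_partial, config.frac_total, seed=s_mask
    )
    for name, df in [("pool.csv", pool), ("sites.csv", sites), ("communities.csv", comm)]:
        p = out / name
        df.to_csv(p, index=False)
        art[name] = _sha256(p)
    for name, df in [("traits_true.csv", traits), ("traits_masked.csv", masked)]:
        p = out / name
        df.to_csv(p)
        art[name] = _sha256(p)
    tree.write(path=str(out / "tree.nwk"), schema="newick")
    art["tree.nwk"] = _sha256(out / "tree.nwk")
    for p in write_stack(stack, out / "rasters"):
        art[f"rasters/{p.name}"] = _sha256(p)
    state.update(
        tree=tree, pool=pool, traits=masked, traits_true=traits, trait_mask=mask,
        sites=sites, comm=comm, stack=stack, truth=truth,
    )


def _load_inputs(config, state):
    state["sites"] = pd.read_csv(config.sites_csv)
    state["comm"] = pd.read_csv(config.communities_csv)
    state["traits"] = pd.read_csv(config.traits_csv, index_col="species_id")
    state["tree"] = dendropy.Tree.get(path=config.tree_newick, schema="newick")
    species = sorted({lf.taxon.label for lf in state["tree"].leaf_node_iter()} | set(state["traits"].index))
    state["pool"] = pd.DataFrame(
        {"species_id": species, "genus": "G000", "family": "F000"}
    )
    if config.raster_dir:
        state["stack"] = read_stack(config.raster_dir)


def _stage_impute(config, seed, out, state, art):
    logger.info("stage impute (seed %d)", seed)
    s_graft, s_sample, s_imp = child_seeds(seed, 3)
    tree, pool = state["tree"], state["pool"]
    # emulate an incomplete phylogeny: prune a fraction of species, then
    # graft them back at taxonomically constrained random positions
    rng = np.random.default_rng(s_graft)
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    n_drop = int(round(config.frac_missing_from_tree * len(labels)))
    incomplete = dendropy.Tree.get(data=tree.as_string(schema="newick"), schema="newick")
    if n_drop:
        dropped = list(rng.choice(labels, size=n_drop, replace=False))
        incomplete.prune_taxa_with_labels(dropped)
    grafted = graft_missing_species(incomplete, pool, config.n_trees_grafted, seed=s_graft)
    trees = sample_trees(grafted, min(config.n_trees_sampled, len(grafted)), seed=s_sample)
    write_trees(trees, out / "trees_sampled.nwk")
    art["trees_sampled.nwk"] = _sha256(out / "trees_sampled.nwk")

    eig = phylo_eigenvectors(tree)
    imputed, report = impute_traits(state["traits"], eig, seed=s_imp)
    imputed.to_csv(out / "traits_imputed.csv")
    art["traits_imputed.csv"] = _sha256(out / "traits_imputed.csv")
    with open(out / "imputation_report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)
    art["imputation_report.json"] = _sha256(out / "imputation_report.json")
    state.update(trees=trees, traits_imputed=imputed, imputation_report=report)


def _stage_diversity(config, seed, out, state, art, save_df):
    logger.info("stage diversity")
    comm = effort_correct(state["comm"], state["sites"])
    traits = state.get("traits_imputed", state.get("traits_true", state["traits"]))
    trees = state.get("trees") or [state["tree"]]
    div = site_diversity(comm, traits=traits, trees=trees)
    save_df(div, "diversity.csv")
    state["div"] = div


def _stage_fit(config, seed, out, state, art, save_df):
    logger.info("stage fit (seed %d)", seed)
    data, centring = prepare_model_frame(state["sites"], state["div"])
    fits = {}
    for facet, response in [("sd", "ln_E_sd"), ("fd", "E_fd"), ("pd", "E_pd")]:
        spec = ModelSpec(response)
        if config.select_random:
            spec, _ = select_random_effects(data, spec, centring=centring)
        ml_fit, drop_log = backward_select_fixed(data, spec, alpha=config.alpha, centring=centring)
        final = fit_lmm(data, ml_fit.spec, "REML", centring)
        final.to_json(out / f"model_{facet}.json")
        art[f"model_{facet}.json"] = _sha256(out / f"model_{facet}.json")
        anova = type2_anova(data, final.spec, centring)
        save_df(anova, f"anova_{facet}.csv")
        diag = {
            "marginal_r2": marginal_r2(final),
            "drop_log": drop_log,
            "gvif": gvif(data, ModelSpec(response)).to_dict("records"),
            "morans_i": morans_i(
                np.asarray(final.result.resid),
                data[["x", "y"]].to_numpy(),
                n_perm=199,
                seed=seed,
            ),
        }
        if config.n_boot > 0:
            ci = bootstrap_ci(data, final.spec, n_boot=config.n_boot, seed=seed, centring=centring)
            ci.insert(0, "coefficient", ci.index)
            save_df(ci.reset_index(drop=True), f"bootstrap_ci_{facet}.csv")
        with open(out / f"diagnostics_{facet}.json", "w") as fh:
            json.dump(diag, fh, indent=2, default=float)
        art[f"diagnostics_{facet}.json"] = _sha256(out / f"diagnostics_{facet}.json")
        fits[facet] = final
    state["fits"] = fits
    state["model_frame"] = data
    state["centring"] = centring


def _stage_project(config, out, state, art, save_df):
    logger.info("stage project")
    stack: RasterStack = state["stack"]
    rel = {}
    for facet, log_response in [("sd", True), ("fd", False), ("pd", False)]:
        fit = state["fits"][facet]
        pred = predict_map(fit, stack, log_response=log_response)
        base = baseline_map(fit, stack, log_response=log_response)
        rel[facet] = relative_map(pred, base)
        p = out / f"relative_{facet}.asc"
        write_ascii_grid(p, rel[facet], stack.cellsize, stack.origin, stack.nodata)
        art[p.name] = _sha256(p)
    summary = country_summary(rel, stack.layers["country_id"])
    save_df(summary, "country_summary.csv")
    state["relative_maps"] = rel
    state["country_summary"] = summary


def _stage_mismatch(config, out, state, art):
    logger.info("stage mismatch")
    rel = state["relative_maps"]
    stack: RasterStack = state["stack"]
    fd_res = ols_residual_map(rel["fd"], rel["sd"])
    pd_res = ols_residual_map(rel["pd"], rel["sd"])
    second = second_stage_residuals(pd_res, fd_res)
    summary = {}
    for name, rm in [("fd_vs_sd", fd_res), ("pd_vs_sd", pd_res), ("pd_vs_fd_second_stage", second)]:
        p = out / f"residuals_{name}.asc"
        write_ascii_grid(p, rm.grid, stack.cellsize, stack.origin, stack.nodata)
        art[p.name] = _sha256(p)
        lo, hi = mismatch_extremes(rm)
        summary[name] = {
            "slope": rm.slope,
            "intercept": rm.intercept,
            "n_cells": rm.n_cells,
            "min_pp": lo,
            "max_pp": hi,
        }
    with open(out / "mismatch_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    art["mismatch_summary.json"] = _sha256(out / "mismatch_summary.json")
    state["mismatch_summary"] = summary
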