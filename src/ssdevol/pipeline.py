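"""End-to-end analysis orchestration with configuration and a run manifest.

The pipeline chains every stage of the SSD analysis: trait loading/validation
(or synthetic generation), SDI and regime coding, phylogenetic RMA by clade,
stochastic character mapping of the social / diet / combined regimes,
five-model OU comparison across the mapped trees, parametric bootstrap of the
best model, RJ-MCMC shift detection, and ancestral-state / transition-count
summaries.  Outputs are plain TSV/CSV/JSON tables plus a ``manifest.json``
recording configuration, seeds, stage runtimes, and any failure point.

All randomness flows from one master seed through ``numpy.random.SeedSequence``
spawns, so a rerun with the same configuration is numerically identical.
"""

from __future__ import annotations

import difflib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tree import read_tree, prune_to_taxa, normalize_label, write_simmap
from .traits import load_trait_table
from .rma import rma_by_clade, results_table
from .markov import fit_mk, sample_simmaps, summarize_maps
from .ou import compare_models, parametric_bootstrap, bm_ancestral_states
from .rjmcmc import ShiftModel, summarize_posterior
from .simulate import SimulationRecipe, paper_like_recipe, generate_dataset

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.errors))


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the production analysis scale."""

    tree_path: str = None
    table_path: str = None
    recipe: dict = None  # synthetic-data recipe; None + no paths -> paper-like
    clades: dict = None  # species -> clade label (optional; global RMA always runs)
    n_maps: int = 500
    bootstrap_reps: int = 1000
    rjmcmc_gens: int = 200_000
    rjmcmc_thin: int = 100
    rjmcmc_chains: int = 2
    pp_threshold: float = 0.5
    burn_in: float = 0.30
    alpha_level: float = 0.05
    mk_structure: str = "ER"
    seed: int = 0
    outdir: str = "results"
    stages: tuple = ("data", "rma", "map", "oufit", "bootstrap", "shifts", "report")

    def stage_seed(self, index: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed).spawn(16)[index]


_POSITIVE_INT = {"n_maps", "bootstrap_reps", "rjmcmc_gens", "rjmcmc_thin",
                 "rjmcmc_chains"}
_UNIT_FLOAT = {"pp_threshold", "burn_in", "alpha_level"}


def validate_config(source) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file, path, or dict.

    Unknown keys are rejected with a closest-match suggestion; all invalid
    values are listed at once.  An empty input yields pure defaults.
    """
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, dict) or source is None:
        raw = dict(source or {})
    else:
        text = Path(source).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])
    known = set(RunConfig.__dataclass_fields__)
    errors = []
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
    for key in _POSITIVE_INT & set(raw):
        v = raw[key]
        if not isinstance(v, int) or v < 1:
            errors.append(f"{key} must be a positive integer, got {v!r}")
    for key in _UNIT_FLOAT & set(raw):
        v = raw[key]
        if not isinstance(v, (int, float)) or not (0.0 <= float(v) < 1.0):
            errors.append(f"{key} must be in [0, 1), got {v!r}")
    if "seed" in raw and not isinstance(raw["seed"], int):
        errors.append(f"seed must be an integer, got {raw['seed']!r}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(**{k: v for k, v in raw.items() if k in known})


def _load_or_simulate(config: RunConfig, outdir: Path):
    """Stage 1: produce (tree, table, sdi, simulated_flag)."""
    if config.tree_path and config.table_path:
        tree = read_tree(config.tree_path)
        table = load_trait_table(config.table_path)
        # exact match after underscore/space normalization
        relabel = {normalize_label(lab): lab for lab in tree.tip_labels}
        keep, dropped_rows = [], []
        for sp in table.species:
            (keep if normalize_label(sp) in relabel else dropped_rows).append(sp)
        if not keep:
            raise ValueError("no species shared between tree and table")
        tree_names = [relabel[normalize_label(sp)] for sp in keep]
        tree, dropped_tips = prune_to_taxa(tree, tree_names)
        if dropped_rows:
            warnings.warn(f"{len(dropped_rows)} table rows not in tree: dropped")
        df = table.df[table.df["species"].isin(keep)].copy()
        df["species"] = df["species"].map(lambda s: relabel[normalize_label(s)])
        table = load_trait_table(df)
        drops = {"table_rows": dropped_rows, "tree_tips": dropped_tips}
        simulated = False
    else:
        recipe = (SimulationRecipe.from_dict(config.recipe)
                  if config.recipe else paper_like_recipe())
        seed = config.stage_seed(0)
        tree, smap, table, _ = generate_dataset(recipe, seed=seed)
        (outdir / "simulated_tree.nwk").write_text(tree.to_newick() + "\n")
        (outdir / "simulated_true_history.smap").write_text(write_simmap(smap) + "\n")
        drops = {"table_rows": [], "tree_tips": []}
        simulated = True
    sdi = table.sdi_vector(order=tree.tip_labels)
    return tree, table, sdi, drops, simulated


def run_pipeline(config: RunConfig = None, **overrides) -> dict:
    """Run the configured stages; returns the report bundle as a dict.

    Any stage failure preserves the outputs written so far; the manifest
    records the failure point.
    """
    config = validate_config(config)
    if overrides:
        cfg = asdict(config)
        cfg.update(overrides)
        config = validate_config(cfg)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "ssdevol",
        "version": __version__,
        "config": {k: (v if not isinstance(v, tuple) else list(v))
                   for k, v in asdict(config).items()},
        "stages": [],
        "failure": None,
    }
    report: dict = {}
    state: dict = {}

    def _write_manifest():
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage_fns = {
        "data": _stage_data,
        "rma": _stage_rma,
        "map": _stage_map,
        "oufit": _stage_oufit,
        "bootstrap": _stage_bootstrap,
        "shifts": _stage_shifts,
        "report": _stage_report,
    }
    for name in config.stages:
        if name not in stage_fns:
            raise ConfigError([f"unknown stage {name!r}"])
        t0 = time.perf_counter()
        try:
            stage_fns[name](config, outdir, state, report)
        except Exception as exc:
            manifest["failure"] = {"stage": name, "error": str(exc)}
            manifest["stages"].append({"stage": name, "status": "failed",
                                       "seconds": time.perf_counter() - t0})
            _write_manifest()
            raise
        manifest["stages"].append({"stage": name, "status": "ok",
                                   "seconds": round(time.perf_counter() - t0, 3)})
    _write_manifest()
    return report


# -- stages -------------------------------------------------------------------


def _stage_data(config, outdir, state, report):
    tree, table, sdi, drops, simulated = _load_or_simulate(config, outdir)
    state.update(tree=tree, table=table, sdi=sdi)
    table.to_csv(outdir / "analysis_table.csv")
    report["n_species"] = len(table)
    report["simulated"] = simulated
    report["dropped"] = drops
    report["sdi_mean"] = float(np.mean(sdi))
    report["sdi_range"] = [float(np.min(sdi)), float(np.max(sdi))]


def _stage_rma(config, outdir, state, report):
    tree, table = state["tree"], state["table"]
    if config.clades:
        results = rma_by_clade(tree, table, config.clades)
    else:
        from .rma import PhyloRMA
        results = [PhyloRMA.from_table(tree, table).fit()]
    tab = results_table(results)
    tab.to_csv(outdir / "rma_table.tsv", sep="\t", index=False)
    g = results[0]
    report["rma"] = {
        "slope": g.slope, "se": g.se, "lambda": g.lam, "r2": g.r2,
        "T": g.T, "df": g.df, "P": g.pvalue, "rensch": g.rensch, "n": g.n,
    }
    state["rma_results"] = results


_CHARACTERS = (("social", "social_system"), ("diet", "diet"),
               ("social_diet", "combined_regime"))


def _stage_map(config, outdir, state, report):
    tree, table = state["tree"], state["table"]
    maps_by_char = {}
    mk_fits = {}
    seed_root = config.stage_seed(1)
    children = seed_root.spawn(len(_CHARACTERS))
    report["map"] = {}
    for (char, column), child in zip(_CHARACTERS, children):
        tip_states = table.states(column, order=tree.tip_labels)
        fit = fit_mk(tree, tip_states, structure=config.mk_structure)
        maps = sample_simmaps(tree, fit.model, tip_states, config.n_maps,
                              rng=np.random.default_rng(child))
        summ = summarize_maps(maps)
        summ.node_frequencies_tsv(outdir / f"ancestral_states_{char}.tsv")
        summ.counts_tsv(outdir / f"transition_counts_{char}.tsv")
        maps_by_char[char] = maps
        mk_fits[char] = fit
        root_freq = summ.node_frequencies.loc[tree.root]
        report["map"][char] = {
            "lnL": fit.loglik,
            "rates": [float(r) for r in fit.rates],
            "root_state_frequencies": {s: float(root_freq[s]) for s in summ.node_frequencies.columns},
            "mean_total_transitions": float(summ.mean_counts.values.sum()),
            "mean_counts": {
                a: {b: float(summ.mean_counts.loc[a, b])
                    for b in summ.mean_counts.columns if a != b}
                for a in summ.mean_counts.index
            },
        }
        state[f"map_summary_{char}"] = summ
    state["maps_by_char"] = maps_by_char
    state["mk_fits"] = mk_fits


def _stage_oufit(config, outdir, state, report):
    sdi, tree = state["sdi"], state["tree"]
    maps = state["maps_by_char"]
    comp = compare_models(
        {f"OUM_{char}": maps[char] for char, _ in _CHARACTERS},
        sdi, tree=tree,
    )
    comp.to_tsv(outdir / "model_comparison.tsv")
    state["comparison"] = comp
    best_fit = comp.fits[comp.best_model]
    report["oufit"] = {
        "best_model": comp.best_model,
        "mean_AICcW": {m: float(comp.mean_weights[m]) for m in comp.models},
        "mean_AICc": {m: float(comp.mean_aicc[m]) for m in comp.models},
        "best_half_life_myr": best_fit.half_life,
        "best_theta": best_fit.theta_dict(),
    }
    anc = bm_ancestral_states(tree, sdi)
    anc.rename_axis("node_id").to_csv(outdir / "sdi_ancestral_states.tsv", sep="\t")


def _stage_bootstrap(config, outdir, state, report):
    comp = state["comparison"]
    fit = comp.fits[comp.best_model]
    seed = int(config.stage_seed(2).generate_state(1)[0] % (2**31))
    ci = parametric_bootstrap(fit, n_reps=config.bootstrap_reps, seed=seed)
    payload = ci.to_dict()
    payload["model"] = comp.best_model
    (outdir / "bootstrap_ci.json").write_text(json.dumps(payload, indent=2))
    report["bootstrap"] = payload


def _stage_shifts(config, outdir, state, report):
    tree, sdi = state["tree"], state["sdi"]
    seed = int(config.stage_seed(3).generate_state(1)[0] % (2**31))
    run = ShiftModel(tree, sdi).run(
        n_gens=config.rjmcmc_gens, thin=config.rjmcmc_thin,
        n_chains=config.rjmcmc_chains, seed=seed,
    )
    post = summarize_posterior(run, burn_in=config.burn_in,
                               pp_threshold=config.pp_threshold)
    post.to_tsv(outdir / "shifts.tsv")
    rj_manifest = {
        "seed": seed,
        "generations": config.rjmcmc_gens,
        "thin": config.rjmcmc_thin,
        "chains": config.rjmcmc_chains,
        "burn_in": config.burn_in,
        "rhat": post.rhat,
        "ess": post.ess,
        "mean_K": post.mean_k,
        "n_shifts_reported": int(len(post.shifts)),
    }
    (outdir / "rjmcmc_manifest.json").write_text(json.dumps(rj_manifest, indent=2))
    report["shifts"] = rj_manifest
    state["shift_posterior"] = post


def _stage_report(config, outdir, state, report):
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
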