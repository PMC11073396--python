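"""End-to-end orchestration: simulate (or load) a study, then run alpha,
beta-partition, assembly-null and succession-statistic stages into one
output directory with a machine-readable summary.

Every stochastic stage receives its own seed derived from one master seed
via numpy's SeedSequence spawning, so a single integer reproduces a whole
run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import nullmodels, stats
from .io_core import (
    AbundanceTable,
    SampleMetadata,
    read_abundance_table,
    read_env_table,
    read_metadata,
    read_tree,
    write_abundance_table,
    write_env_table,
    write_metadata,
)
from .synthetic import DesignConfig, RegimeConfig, generate_study

logger = logging.getLogger(__name__)

STAGE_NAMES = ("simulate", "alpha", "beta", "assembly", "timedecay",
               "permanova", "mantel", "convergence")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one deterministic sub-seed per stage from a master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGE_NAMES))
    return {name: int(ss.generate_state(1)[0] % (2**31 - 1))
            for name, ss in zip(STAGE_NAMES, children)}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full analysis described by ``config``; returns the summary.

    Config keys: either ``simulate`` (design/regime blocks) or ``inputs``
    (paths to table/metadata/tree/env); ``seed`` (master); optional
    ``null`` (n_null etc.), ``thresholds`` and stage toggles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    seeds = stage_seeds(int(config.get("seed", 0)))
    summary: dict = {"seed": int(config.get("seed", 0))}

    try:
        if "simulate" in config:
            sim = config["simulate"]
            design = DesignConfig(**{**sim.get("design", {}),
                                     "seed": seeds["simulate"]})
            regime = RegimeConfig(**sim.get("regime", {}))
            table, metadata, tree, env, truth = generate_study(design, regime)
            write_abundance_table(table, out / "abundance.tsv")
            write_metadata(metadata, out / "metadata.tsv")
            write_env_table(env, out / "environment.tsv")
            tree.write(str(out / "tree.nwk"))
            (out / "ground_truth.json").write_text(
                json.dumps(dataclasses.asdict(truth), indent=2))
        elif "inputs" in config:
            paths = config["inputs"]
            table = read_abundance_table(paths["table"])
            metadata = read_metadata(paths["metadata"])
            tree = read_tree(paths["tree"])
            env = read_env_table(paths["env"]) if "env" in paths else None
        else:
            raise StageError("simulate", "config needs 'simulate' or 'inputs'")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e

    meta_frame = metadata.frame
    plast = metadata.plastisphere()
    summary["n_samples"] = table.n_samples
    summary["n_plastisphere_samples"] = int(
        (meta_frame["fraction"] == "plastisphere").sum())
    summary["n_water_samples"] = int(
        (meta_frame["fraction"] != "plastisphere").sum())

    def _stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as e:  # noqa: BLE001
                raise StageError(name, str(e)) from e
        return deco

    plast_table = table.select_samples(plast.sample_ids).drop_empty()
    if config.get("rarefy", False):
        depth = config["rarefy"] if isinstance(config["rarefy"], int) else None
        plast_table = beta_mod.rarefy(plast_table, depth=depth,
                                      seed=seeds["beta"])

    @_stage("alpha")
    def _():
        adf = alpha_mod.alpha_table(table, tree)
        adf.to_csv(out / "alpha.tsv", sep="\t", index=False)
        traj = alpha_mod.alpha_trajectories(adf, metadata)
        traj.to_csv(out / "alpha_trajectories.tsv", sep="\t", index=False)
        summary["mean_richness"] = float(adf["richness"].mean())
        summary["mean_faith_pd"] = float(adf["faith_pd"].mean())

    @_stage("beta")
    def _():
        ratio = beta_mod.beta_ratio_by_group(plast_table, plast)
        ratio.to_csv(out / "beta_ratio.tsv", sep="\t", index=False)
        summary["beta_ratio_dominance"] = {
            f"{r.lake}/d{r.day}": r.dominance for r in ratio.itertuples()
        }
        summary["mean_beta_ratio"] = float(ratio["mean_beta_ratio"].mean())

    null_cfg = nullmodels.NullConfig(
        seed=seeds["assembly"], **config.get("null", {}))

    if config.get("run_assembly", True):
        @_stage("assembly")
        def _():
            # whole-lake pools (water included); plastisphere pairs classified
            res = nullmodels.assembly_analysis(
                table, tree, metadata, null_cfg,
                pair_filter={"fraction": "plastisphere"})
            res.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
            frac = nullmodels.process_fractions(res, plast)
            frac.to_csv(out / "assembly_fractions.tsv", sep="\t", index=False)
            modal = (res.dropna(subset=["process"])["process"]
                     .value_counts().idxmax())
            summary["modal_process"] = modal
            summary["deterministic_share"] = float(frac["deterministic"].mean())

    @_stage("timedecay")
    def _():
        sor = beta_mod.sorensen_matrix(plast_table)
        sim = 1.0 - sor.data
        np.fill_diagonal(sim, 0.0)
        import skbio
        sim_dm = skbio.DistanceMatrix(sim, ids=sor.ids)
        fits = stats.time_decay(sim_dm, plast)
        stats.time_decay_table(fits).to_csv(out / "time_decay.tsv", sep="\t",
                                            index=False)
        summary["time_decay_slopes"] = {f.group: f.slope for f in fits}

    @_stage("permanova")
    def _():
        bc = beta_mod.bray_curtis_matrix(plast_table)
        terms = config.get("permanova_terms")
        if terms is None:
            # default Table-1-style terms, keeping only multi-level factors
            multi = [c for c in ("day", "lake", "polymer")
                     if plast.frame[c].nunique() > 1]
            terms = multi + (["day:lake"] if {"day", "lake"} <= set(multi) else [])
        tab = stats.permanova(bc, plast, terms,
                              n_permutations=int(config.get(
                                  "permanova_permutations", 999)),
                              seed=seeds["permanova"])
        tab.to_csv(out / "permanova.tsv", sep="\t", index=False)
        summary["permanova"] = {
            r.term: {"R2": r.R2, "p": None if np.isnan(r.p) else r.p}
            for r in tab.itertuples()
        }

    if env is not None:
        @_stage("mantel")
        def _():
            bc = beta_mod.bray_curtis_matrix(plast_table)
            from .io_core import ENV_VARIABLES
            envd = stats.env_distance(env, ENV_VARIABLES, plast,
                                      list(bc.ids))
            res = stats.mantel(bc, envd, seed=seeds["mantel"])
            summary["mantel_env"] = {"r": res.r, "p": res.p_value}

    @_stage("convergence")
    def _():
        bc = beta_mod.bray_curtis_matrix(plast_table)
        fits = stats.convergence_trend(bc, plast)
        stats.convergence_table(fits).to_csv(out / "convergence.tsv", sep="\t",
                                             index=False)
        summary["convergence_slopes"] = {f.group: f.slope for f in fits}
        summary["all_lakes_convergent"] = bool(all(f.convergent for f in fits))

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
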