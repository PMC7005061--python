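"""End-to-end pipeline: simulate -> process -> convert -> ordinate -> fit ->
cross-validate -> group -> phylogenetic signal -> report.

Each stage reads/writes delimited text tables in the run directory, so any
stage can be rerun in isolation; a manifest records the config, seed,
per-stage timing and a SHA-256 digest of every output file. One global seed
fans out to per-stage substreams (see ``SimulationConfig.rng``), making the
whole run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biascorr import MODEL_PREDICTORS, bias_report, fit_vwwd_model, loso_crossval, predict_vwwd
from .compartments import SMALL_BRANCH, STUMP
from .fieldcalc import process_tables
from .grouping import blomberg_k_pvalue, oneway_anova, tukey_hsd, variance_partition
from .profiles import (
    build_profile_matrix,
    gradient_percent,
    run_pca,
    supplementary_correlations,
)
from .synthgen import SimulationConfig, generate_dataset, write_dataset
from .vwwd import agb_estimates_table

logger = logging.getLogger("woodgrad")

__all__ = ["run_pipeline", "load_config"]


def load_config(path) -> dict:
    """Read a YAML/JSON config file into a plain dict."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _bias_summary(rep) -> dict:
    return {
        "B": rep.B,
        "sd_b": rep.sd_b,
        "agb_rmse": rep.agb_rmse,
        "MAGB_obs": rep.MAGB_obs,
        "CV": rep.CV,
    }


def run_pipeline(config: dict | None = None, out_dir="woodgrad_run", seed: int = 0) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    ``config`` keys: any ``SimulationConfig`` field under ``simulation``,
    plus ``pca_mode`` (row_mean_ratio|row_center), ``models`` (list of
    m1..m6), ``crossval_model``, ``physig_n_rand``, ``physig_tail``.
    """
    config = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
        "files": {},
        "warnings": [],
    }
    written: list[Path] = []

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)

        def done():
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s finished", name)

        return done

    # -- simulate ----------------------------------------------------------
    end = stage("simulate")
    sim_kwargs = dict(config.get("simulation", {}))
    sim_kwargs["seed"] = seed
    sim = SimulationConfig(**sim_kwargs)
    dataset = generate_dataset(sim)
    written += [Path(p) for p in write_dataset(dataset, out)]
    end()

    # -- process -----------------------------------------------------------
    end = stage("process")
    comp_df, trees_df = process_tables(
        dataset["samples"], dataset["logs"], dataset["trees"]
    )
    trees_df = trees_df.merge(
        dataset["species"][["species_id", "WD_GWD", "guild"]], on="species_id"
    )
    comp_df.to_csv(out / "compartments.csv", index=False)
    trees_df.to_csv(out / "trees_processed.csv", index=False)
    written += [out / "compartments.csv", out / "trees_processed.csv"]
    end()

    # -- convert: AGB bias per WD source ----------------------------------
    end = stage("convert")
    bias = {}
    est_frames = []
    for source in ("WD_GWD", "WD_Stu", "VWWD"):
        est = agb_estimates_table(trees_df, source, species=dataset["species"])
        rep = bias_report(est["AGB_est"], est["AGB_obs"])
        est["b_i"] = rep.b_i
        bias[source] = _bias_summary(rep)
        est_frames.append(est)
    pd.concat(est_frames, ignore_index=True).to_csv(out / "agb_estimates.csv", index=False)
    written.append(out / "agb_estimates.csv")
    end()

    # -- ordination --------------------------------------------------------
    end = stage("pca")
    mode = config.get("pca_mode", "row_mean_ratio")
    ordination = run_pca(build_profile_matrix(comp_df, mode=mode))
    ordination.scores.to_csv(out / "scores.csv")
    ordination.loadings.to_csv(out / "loadings.csv")
    pd.DataFrame(
        {"axis": ordination.scores.columns, "eigenvalue": ordination.eigenvalues}
    ).to_csv(out / "eigenvalues.csv", index=False)
    suppl = supplementary_correlations(ordination, trees_df)
    suppl.to_csv(out / "table1.csv", index=False)
    written += [out / "scores.csv", out / "loadings.csv", out / "eigenvalues.csv",
                out / "table1.csv"]
    n_imputed = int(ordination.imputed.sum()) if ordination.imputed is not None else 0
    if n_imputed:
        manifest["warnings"].append(
            {"stage": "pca", "kind": "imputed_stem_base", "count": n_imputed}
        )
    end()

    # -- gradient statistics ----------------------------------------------
    wide = comp_df.pivot_table(
        index="tree_id", columns="compartment", values="WD_c", observed=True
    )
    grad = pd.Series(
        [gradient_percent(sb, stu) for sb, stu in zip(wide[SMALL_BRANCH], wide[STUMP])],
        index=wide.index,
        name="gradient_pct",
    )
    sp_of_tree = trees_df.set_index("tree_id")["species_id"]
    species_grad = grad.groupby(sp_of_tree.reindex(grad.index)).mean()

    # -- model fits --------------------------------------------------------
    end = stage("fit")
    model_ids = config.get("models", list(MODEL_PREDICTORS))
    models_json = {}
    for mid in model_ids:
        fit = fit_vwwd_model(trees_df, mid)
        models_json[mid] = {
            "coefficients": fit.coefficients,
            "std_errors": fit.std_errors,
            "r2": fit.r2,
            "r2_adj": fit.r2_adj,
            "model_rse": fit.model_rse,
            "aic": fit.aic,
            "n": fit.n,
            "bias": _bias_summary(fit.bias) if fit.bias else None,
        }
        pred = predict_vwwd(fit, trees_df)
        est = agb_estimates_table(trees_df, "VWWD_model", wd_values=pred)
        bias[f"VWWD_{mid}"] = _bias_summary(bias_report(est["AGB_est"], est["AGB_obs"]))
    (out / "models.json").write_text(json.dumps(models_json, indent=2))
    written.append(out / "models.json")
    end()

    # -- cross-validation --------------------------------------------------
    end = stage("crossval")
    n_sites = trees_df["site"].nunique()
    if n_sites >= 2:
        cv = loso_crossval(trees_df, config.get("crossval_model", "m1"))
        cv.to_csv(out / "crossval.csv", index=False)
        written.append(out / "crossval.csv")
        crossval_summary = cv.to_dict(orient="records")
    else:
        logger.warning("crossval skipped: only %d site(s) in the data", n_sites)
        manifest["warnings"].append(
            {"stage": "crossval", "kind": "skipped", "reason": f"{n_sites} site(s)"}
        )
        crossval_summary = None
    end()

    # -- guild / site / species grouping ----------------------------------
    end = stage("group")
    pc1 = ordination.scores["pc1"]
    tmeta = trees_df.set_index("tree_id").reindex(pc1.index)
    anova = oneway_anova(pc1.to_numpy(), tmeta["guild"].to_numpy())
    tukey = tukey_hsd(pc1.to_numpy(), tmeta["guild"].to_numpy())
    tukey.to_csv(out / "tukey.csv", index=False)
    written.append(out / "tukey.csv")
    try:
        vp = variance_partition(
            pc1.to_numpy(), tmeta["species_id"].to_numpy(), tmeta["site"].to_numpy()
        )
        vp_json = {
            "variance_fractions": vp.variance_fractions,
            "n": vp.n,
            "terms": vp.terms.to_dict(orient="records"),
        }
    except ValueError as exc:
        logger.warning("variance partition skipped: %s", exc)
        manifest["warnings"].append(
            {"stage": "group", "kind": "variance_partition_skipped", "reason": str(exc)}
        )
        vp_json = None
    anova_json = {
        "guild_anova": {
            "F": anova.F, "p": anova.p,
            "df_between": anova.df_between, "df_within": anova.df_within,
        },
        "tukey_letters": tukey.attrs["letters"],
        "variance_partition": vp_json,
    }
    (out / "anova.json").write_text(json.dumps(anova_json, indent=2))
    written.append(out / "anova.json")
    end()

    # -- phylogenetic signal ----------------------------------------------
    end = stage("physig")
    species_pc1 = pc1.groupby(sp_of_tree.reindex(pc1.index)).mean()
    physig_json = None
    if dataset["phylogeny"] and species_pc1.size >= 3:
        import dendropy

        # prune the phylogeny to species that actually have sampled trees
        phylo = dendropy.Tree.get(data=dataset["phylogeny"], schema="newick")
        phylo.retain_taxa_with_labels(list(species_pc1.index))
        sig = blomberg_k_pvalue(
            species_pc1.to_dict(),
            phylo,
            n_rand=int(config.get("physig_n_rand", 999)),
            seed=seed,
            tail=config.get("physig_tail", "lower"),
        )
        physig_json = {
            "K": sig.K, "p": sig.p,
            "n_randomizations": sig.n_randomizations, "tail": sig.tail,
        }
        (out / "physignal.json").write_text(json.dumps(physig_json, indent=2))
        written.append(out / "physignal.json")
    end()

    # -- report ------------------------------------------------------------
    end = stage("report")
    r_pc1 = suppl.set_index("variable")
    report = {
        "n_trees": int(len(trees_df)),
        "n_species": int(trees_df["species_id"].nunique()),
        "n_sites": int(n_sites),
        "gradients": {
            "frac_decreasing_trees_pct": float(100.0 * (grad < 0).mean()),
            "mean_gradient_pct": float(grad.mean()),
            "frac_decreasing_species_pct": float(100.0 * (species_grad < 0).mean()),
            "mean_species_gradient_pct": float(species_grad.mean()),
        },
        "pca": {
            "eigenvalues": ordination.eigenvalues.tolist(),
            "r_pc1_WD_Stu": float(r_pc1.loc["WD_Stu", "r_axis1"]),
            "r_pc1_WD_GWD": float(r_pc1.loc["WD_GWD", "r_axis1"]),
        },
        "bias_by_wd_source": bias,
        "models": models_json,
        "crossval": crossval_summary,
        "grouping": anova_json,
        "phylo_signal": physig_json,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    written.append(out / "report.json")
    end()

    for path in written:
        manifest["files"][path.name] = _digest(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["report"] = report
    return manifest
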