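"""End-to-end orchestration of the colony analysis stages.

A single config dict (usually loaded from YAML) drives every stage:
synthetic data generation, phenotype statistics, role differential
expression at both fold-change thresholds, the rank/effort
residualization decomposition, the co-expression network, orthology,
the cross-lineage comparison and term enrichment.  All randomness flows
from one master seed, expanded deterministically per stage; every run
writes a manifest with per-stage seeds and output digests so reruns are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("colonysig")

from . import collinearity, crossspecies, enrichment, io, network, orthology, pca, phenotypes, simulate
from .de import DesignSpec, run_de

__all__ = ["DEFAULT_CONFIG", "PipelineError", "load_config", "run_pipeline", "stage_seeds"]

STAGES = ["simulate", "phenotypes", "de", "decompose", "network",
          "orthology", "compare", "enrich"]

DEFAULT_CONFIG = {
    "simulate": {
        "n_nests": 28,
        "size_range": [3, 5],
        "n_genes": 1500,
        "n_role": 100,
        "n_effort": 100,
        "n_modules": 5,
        "module_size": 40,
        "role_log2fc": 2.0,
        "effort_log2_slope": 3.0,
        "sequenced_subset": True,
    },
    "de": {"theta": 0.0, "theta_strict": 0.5849625007211562, "contrast": "role"},
    "decompose": {"exclude_reproductives": True, "rank_col": "rank_post"},
    "network": {"power": 6.0, "min_module_size": 20, "merge_threshold": 0.75,
                "traits": ["foraging_effort", "rank_pre", "rank_post", "age_days"]},
    "compare": {"tau_target": 0.046, "n_perm": 100},
    "enrich": {"alpha": 0.01, "namespace": "biological_process"},
    "pca": {"k": 1000},
}


class PipelineError(RuntimeError):
    """A stage-named configuration or execution failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path=None) -> dict:
    """Load a YAML config merged over the bundled demo defaults."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for stage, opts in user.items():
            if stage not in config:
                raise PipelineError(stage, "unknown config section")
            if not isinstance(opts, dict):
                raise PipelineError(stage, "config section must be a mapping")
            config[stage].update(opts)
    _validate(config)
    return config


def _validate(config: dict) -> None:
    sim = config["simulate"]
    if sim["n_nests"] < 0:
        raise PipelineError("simulate", "n_nests must be >= 0")
    lo, hi = sim["size_range"]
    if not (2 <= lo <= hi <= 10):
        raise PipelineError("simulate", "size_range must lie within [2, 10]")
    planted = sim["n_role"] + sim["n_effort"] + sim["n_modules"] * sim["module_size"]
    if sim["n_genes"] < planted:
        raise PipelineError("simulate", f"n_genes < planted genes ({planted})")
    for key in ("theta", "theta_strict"):
        if config["de"][key] < 0:
            raise PipelineError("de", f"{key} must be >= 0")
    if not 0 < config["network"]["merge_threshold"] < 1:
        raise PipelineError("network", "merge_threshold must lie in (0, 1)")
    if config["pca"]["k"] > sim["n_genes"]:
        raise PipelineError("pca", "k exceeds the simulated gene count")


def stage_seeds(master_seed: int) -> dict:
    """Expand one master seed into independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {stage: int(child.generate_state(1)[0] % (2**31))
            for stage, child in zip(STAGES, children)}


def run_pipeline(config: dict | str | Path | None = None, outdir="results",
                 seed: int = 0) -> dict:
    """Execute all stages in order and write the run manifest.

    Returns the manifest dict.  Fails with a stage-named
    :class:`PipelineError` before any compute if the config is invalid.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        _validate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    outputs: dict = {}

    # -- simulate -----------------------------------------------------------
    sim = config["simulate"]
    designs = simulate.generate_colonies(sim["n_nests"], tuple(sim["size_range"]),
                                         seed=seeds["simulate"])
    truth = simulate.make_truth(
        n_genes=sim["n_genes"], n_role=sim["n_role"], n_effort=sim["n_effort"],
        n_modules=sim["n_modules"], module_size=sim["module_size"],
        role_log2fc=sim["role_log2fc"], effort_log2_slope=sim["effort_log2_slope"],
        seed=seeds["simulate"] + 1,
    )
    meta = simulate.generate_phenotypes(designs, truth, seed=seeds["simulate"] + 2)
    if sim.get("sequenced_subset", True):
        meta = simulate.sequenced_subset(meta, seed=seeds["simulate"] + 3)
    else:
        meta = meta.assign(sequenced=True)
    seq_meta = meta[meta["sequenced"]]
    if seq_meta.empty or seq_meta["role"].nunique() < 2:
        raise PipelineError("simulate", "sequenced sample set lacks both roles")
    counts = simulate.generate_counts(seq_meta, truth, seed=seeds["simulate"] + 4)
    logger.info("simulate: %d genes x %d sequenced samples (%d individuals total)",
                counts.shape[0], counts.shape[1], len(meta))
    io.write_counts_tsv(counts, outdir / "counts.tsv")
    io.write_metadata(meta, outdir / "metadata.csv")
    truth.to_json(outdir / "truth.json")
    outputs["simulate"] = [outdir / "counts.tsv", outdir / "metadata.csv", outdir / "truth.json"]

    # -- phenotypes ---------------------------------------------------------
    fit = phenotypes.rank_effort_regression(meta)
    promoted = meta[meta["promoted"] & meta["effort_post"].notna()]
    unman = meta[~meta["promoted"] & ~meta["removed_at_manipulation"] & meta["effort_post"].notna()]
    w_p, p_p, mc_p, sd_p = phenotypes.promotion_change_test(promoted["effort_pre"],
                                                            promoted["effort_post"])
    w_u, p_u, mc_u, sd_u = phenotypes.promotion_change_test(unman["effort_pre"],
                                                            unman["effort_post"])
    pheno = pd.DataFrame([
        {"statistic": "rank_effort_slope", "value": fit.slope, "se": fit.slope_se,
         "p": fit.p, "extra": fit.r_squared},
        {"statistic": "promoted_change_W", "value": w_p, "se": sd_p, "p": p_p, "extra": mc_p},
        {"statistic": "unmanipulated_change_W", "value": w_u, "se": sd_u, "p": p_u, "extra": mc_u},
    ])
    pheno.to_csv(outdir / "phenotype_stats.tsv", sep="\t", index=False)
    outputs["phenotypes"] = [outdir / "phenotype_stats.tsv"]

    # -- differential expression + PCA -------------------------------------
    de_cfg = config["de"]
    design = DesignSpec({"role": "categorical"}, contrast="role",
                        reference={"role": "non_reproductive"})
    res0 = run_de(counts, seq_meta, design, theta=de_cfg["theta"])
    res1 = run_de(counts, seq_meta, design, theta=de_cfg["theta_strict"])
    logger.info("de: %d/%d genes kept by group-mean filter; %d DEGs (theta=%g), "
                "%d DEGs (theta=%g)", len(res0.table), counts.shape[0],
                res0.n_significant, de_cfg["theta"],
                res1.n_significant, de_cfg["theta_strict"])
    res0.to_tsv(outdir / "de_role.tsv")
    res1.to_tsv(outdir / "de_role_strict.tsv")
    expr_log = network.variance_stabilize(counts)
    k = min(config["pca"]["k"], expr_log.shape[0])
    scores, explained = pca.pca_top_variable(expr_log, k=k, n_components=5)
    scores.assign(**{"explained_PC1": explained.iloc[0]}).to_csv(
        outdir / "pca_scores.tsv", sep="\t", index_label="sample")
    outputs["de"] = [outdir / "de_role.tsv", outdir / "de_role_strict.tsv",
                     outdir / "pca_scores.tsv"]

    # -- residualization decomposition --------------------------------------
    dec = config["decompose"]
    res_rank, res_effort = collinearity.decomposed_de(
        counts, seq_meta, theta=0.0, rank_col=dec["rank_col"],
        exclude_reproductives=dec["exclude_reproductives"])
    res_rank.to_tsv(outdir / "decompose_rank_residual.tsv")
    res_effort.to_tsv(outdir / "decompose_effort_residual.tsv")
    outputs["decompose"] = [outdir / "decompose_rank_residual.tsv",
                            outdir / "decompose_effort_residual.tsv"]

    # -- co-expression network (non-reproductives) --------------------------
    net_cfg = config["network"]
    nonrep = seq_meta[seq_meta["role"] == "non_reproductive"]
    traits = nonrep[[c for c in net_cfg["traits"] if c in nonrep.columns]]
    model = network.CoexpressionNetwork.from_counts(
        counts[nonrep.index], traits=traits, power=net_cfg["power"],
        min_module_size=net_cfg["min_module_size"],
        merge_threshold=net_cfg["merge_threshold"])
    net = model.fit()
    logger.info("network: %d genes after <10-reads filter (of %d), %d modules "
                "(initial %d) over %d non-reproductives", len(net.assignments),
                counts.shape[0], len(net.modules), net.n_initial_modules, len(nonrep))
    net.assignments.rename("module").to_csv(outdir / "network_modules.tsv", sep="\t",
                                            index_label="gene")
    net.eigengenes.to_csv(outdir / "network_eigengenes.tsv", sep="\t", index_label="sample")
    if net.module_trait is not None:
        net.module_trait.to_tsv(outdir / "module_trait.tsv")
        outputs["network"] = [outdir / "network_modules.tsv", outdir / "network_eigengenes.tsv",
                              outdir / "module_trait.tsv"]
    else:
        outputs["network"] = [outdir / "network_modules.tsv", outdir / "network_eigengenes.tsv"]

    # -- orthology ----------------------------------------------------------
    hits_ab, hits_ba, _ = simulate.toy_hit_tables(list(counts.index), seed=seeds["orthology"])
    ortho = orthology.reciprocal_best_hits(hits_ab, hits_ba)
    ortho.to_tsv(outdir / "ortholog_map.tsv")
    outputs["orthology"] = [outdir / "ortholog_map.tsv"]

    # -- cross-species comparison -------------------------------------------
    cmp_cfg = config["compare"]
    fc_A = res0.table["log2_effect"]
    mapped = [a for a in ortho.pairs["gene_A"] if a in fc_A.index]
    second = simulate.generate_second_species(fc_A.loc[mapped], cmp_cfg["tau_target"],
                                              seed=seeds["compare"])
    fc_B = pd.Series(second["fc_B"].to_numpy(), index=[ortho.as_dict()[a] for a in mapped])
    join = crossspecies.join_fold_changes(fc_A, fc_B, ortho)
    join.to_csv(outdir / "fold_change_join.tsv", sep="\t", index=False)
    null = crossspecies.permutation_null(join["fc_A"], join["fc_B"],
                                         n_perm=cmp_cfg["n_perm"], seed=seeds["compare"] + 1)
    with open(outdir / "correlation_report.json", "w") as fh:
        json.dump({"tau": null.tau_observed, "null_mean_tau": null.null_mean,
                   "empirical_p": null.empirical_p, "n_perm": cmp_cfg["n_perm"],
                   "seed": seeds["compare"], "n_orthologs": len(join)}, fh, indent=2)
    universe = set(join["gene_A"])
    sig0 = set(res0.significant())
    up_A = [g for g in sig0 & universe if res0.table.loc[g, "log2_effect"] < 0]
    dn_B = list(join.loc[join["fc_B"] < np.quantile(join["fc_B"], 0.1), "gene_A"])
    up_rep_A = [g for g in sig0 & universe if res0.table.loc[g, "log2_effect"] > 0]
    up_rep_B = list(join.loc[join["fc_B"] > np.quantile(join["fc_B"], 0.9), "gene_A"])
    overlap = crossspecies.overlap_fisher(None, None, universe, family=[
        ("nonreproductive_biased", up_A, dn_B),
        ("reproductive_biased", up_rep_A, up_rep_B),
    ])
    overlap.to_csv(outdir / "overlap_tests.tsv", sep="\t")
    outputs["compare"] = [outdir / "fold_change_join.tsv", outdir / "correlation_report.json",
                          outdir / "overlap_tests.tsv"]

    # -- enrichment ----------------------------------------------------------
    enr_cfg = config["enrich"]
    parents, namespace = simulate.toy_ontology(n_branches=4, depth=3)
    dag = enrichment.OntologyDAG.from_edges(parents, namespace)
    sig = list(sig0)
    annots = simulate.toy_annotations(list(counts.index), sig, "GO:B1D3", parents,
                                      seed=seeds["enrich"])
    closed = enrichment.propagate_annotations(dag, annots)
    results = enrichment.elim_enrichment(dag, closed, sig, list(counts.index),
                                         alpha=enr_cfg["alpha"],
                                         namespace=enr_cfg["namespace"])
    enrichment.enrichment_table(results).to_csv(outdir / "enrichment_bp.tsv", sep="\t",
                                                index=False)
    outputs["enrich"] = [outdir / "enrichment_bp.tsv"]

    manifest = io.write_manifest(outdir / "manifest.json", config, seeds, outputs)
    return manifest
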