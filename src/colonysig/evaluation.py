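"""Planted-truth evaluation harnesses.

Each function regenerates synthetic study data at the design's scale
(28 nests, the 19-reproductive / 64-non-reproductive sequencing split,
8460 orthologs), runs the corresponding analysis stage, and scores the
result against the planted truth.  They back both the acceptance-style
tests and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import network as net
from .collinearity import decomposed_de
from .crossspecies import overlap_fisher, permutation_null
from .de import DesignSpec, run_de
from .enrichment import OntologyDAG, elim_enrichment, propagate_annotations
from .simulate import EffortModel, generate_counts, make_truth, toy_annotations, toy_ontology

__all__ = [
    "elim_vs_classic",
    "fisher_worked_example",
    "module_trait_power",
    "network_recovery",
    "null_fdr",
    "permutation_calibration",
    "residualization_pattern",
    "role_effect_recovery",
    "study_split_metadata",
]

ROLE_DESIGN = DesignSpec({"role": "categorical"}, "role", {"role": "non_reproductive"})


def study_split_metadata(n_repro: int = 19, n_nonrep: int = 64, seed: int = 0,
                         rank_effort_r: float | None = None) -> pd.DataFrame:
    """Metadata for the sequenced study split: ``n_repro`` rank-1
    reproductives vs ``n_nonrep`` queue members of ranks 2-5 with
    queue-model foraging efforts.

    With ``rank_effort_r`` set, non-reproductive effort is drawn so its
    correlation with rank is the given value (used by the
    collinearity harness); otherwise the effort model's own rank
    dependence applies.
    """
    rng = np.random.default_rng(seed)
    ranks = np.concatenate([np.ones(n_repro, dtype=int), rng.integers(2, 6, n_nonrep)])
    model = EffortModel()
    if rank_effort_r is None:
        t = model.intercept + model.slope * ranks + rng.normal(0, model.noise_sd, ranks.size)
        t[ranks == 1] = np.abs(rng.normal(0, model.rank1_sd, int((ranks == 1).sum())))
        effort = np.sin(np.clip(t, 0, np.pi / 2)) ** 2
    else:
        effort = np.zeros(ranks.size)
        nr = ranks > 1
        z = (ranks[nr] - ranks[nr].mean()) / ranks[nr].std()
        mix = rank_effort_r * z + np.sqrt(1 - rank_effort_r**2) * rng.normal(size=int(nr.sum()))
        effort[nr] = np.clip(0.5 + 0.2 * mix, 0.01, 0.99)
        effort[~nr] = np.abs(rng.normal(0, 0.01, int((~nr).sum())))
    return pd.DataFrame({
        "nest_id": "N01",
        "rank_pre": ranks,
        "rank_post": ranks,
        "role": np.where(ranks == 1, "reproductive", "non_reproductive"),
        "age_days": np.where(ranks == 1, np.nan, 40.0 - 4 * ranks),
        "foraging_effort": effort,
        "promoted": False,
    }, index=pd.Index([f"w{i:03d}" for i in range(len(ranks))], name="individual_id"))


def fisher_worked_example() -> pd.DataFrame:
    """The study's printed cross-lineage overlap: 101 shared genes from
    non-reproductive-biased lists of 542 and 824 inside the 8460-
    ortholog universe, BH-corrected together with the paired
    reproductive-biased test (57 of 469 and 1038)."""
    universe = [f"o{i}" for i in range(8460)]
    nonrep_A = universe[:542]
    nonrep_B = universe[441:1265]        # overlap 101
    rep_A = universe[2000:2469]          # 469
    rep_B = universe[2412:3450]          # overlap 57, length 1038
    return overlap_fisher(None, None, universe, family=[
        ("nonreproductive_biased", nonrep_A, nonrep_B),
        ("reproductive_biased", rep_A, rep_B),
    ])


def null_fdr(n_genes: int = 5000, n_per_group: int = 40, n_seeds: int = 20,
             seed: int = 0, alpha: float = 0.05) -> dict:
    """Mean false-discovery proportion of the role contrast under a
    fully null simulation (no planted effects)."""
    fdps, rejections = [], []
    for k in range(n_seeds):
        truth = make_truth(n_genes=n_genes, n_role=0, n_effort=0, n_modules=0,
                           module_size=0, seed=seed + 1000 + k)
        meta = study_split_metadata(n_per_group, n_per_group, seed=seed + k)
        counts = generate_counts(meta, truth, seed=seed + 2000 + k)
        res = run_de(counts, meta, ROLE_DESIGN)
        n_sig = len(res.significant(alpha))
        rejections.append(n_sig)
        fdps.append(1.0 if n_sig > 0 else 0.0)  # every rejection is false
    return {"mean_fdp": float(np.mean(fdps)), "rejections": rejections,
            "n_seeds": n_seeds, "n_genes": n_genes}


def role_effect_recovery(seed: int = 0, n_genes: int = 2000, n_role: int = 100,
                         role_log2fc: float = 2.0) -> dict:
    """Recall of planted role-biased genes at the 19-vs-64 split for the
    point null and both fold-change thresholds."""
    truth = make_truth(n_genes=n_genes, n_role=n_role, n_effort=0, n_modules=0,
                       module_size=0, role_log2fc=role_log2fc, seed=seed + 1)
    meta = study_split_metadata(19, 64, seed=seed)
    counts = generate_counts(meta, truth, seed=seed + 2)
    planted = set(truth.role_effects)
    sig = {}
    for key, theta in [("theta0", 0.0), ("theta_log2_1.5", np.log2(1.5)), ("theta_1.5", 1.5)]:
        res = run_de(counts, meta, ROLE_DESIGN, theta=theta)
        sig[key] = set(res.significant())
    return {
        "recall_theta0": len(sig["theta0"] & planted) / len(planted),
        "n_sig_theta0": len(sig["theta0"]),
        "n_sig_theta_log2_1.5": len(sig["theta_log2_1.5"]),
        "n_sig_theta_1.5": len(sig["theta_1.5"]),
        "monotone": sig["theta_1.5"] <= sig["theta_log2_1.5"] <= sig["theta0"],
    }


def residualization_pattern(seed: int = 0, n_genes: int = 1000, n_effort: int = 80,
                            rank_effort_r: float = 0.85) -> dict:
    """The rank-vs-effort decomposition when expression depends only on
    effort and rank is collinear with it (r ~ .85): the rank-residual
    arm should find ~nothing, the effort-residual arm most planted
    genes (the study's 0-vs-18 asymmetry)."""
    truth = make_truth(n_genes=n_genes, n_role=0, n_effort=n_effort, n_modules=0,
                       module_size=0, effort_log2_slope=3.0, seed=seed + 1)
    meta = study_split_metadata(0, 64, seed=seed, rank_effort_r=rank_effort_r)
    counts = generate_counts(meta, truth, seed=seed + 2)
    res_rank, res_effort = decomposed_de(counts, meta, exclude_reproductives=False)
    planted = set(truth.effort_slopes)
    return {
        "n_planted": len(planted),
        "n_rank_residual_sig": len(res_rank.significant()),
        "effort_residual_recall": len(set(res_effort.significant()) & planted) / len(planted),
    }


def network_recovery(seed: int = 0, n_genes: int = 1000, n_modules: int = 5,
                     module_size: int = 40, n_samples: int = 64) -> dict:
    """Planted-module recovery on generator counts: adjusted Rand index
    of detected vs planted assignments, and the post-merge eigengene
    correlation ceiling."""
    truth = make_truth(n_genes=n_genes, n_role=0, n_effort=0, n_modules=n_modules,
                       module_size=module_size, seed=seed + 1)
    meta = study_split_metadata(0, n_samples, seed=seed)
    counts = generate_counts(meta, truth, seed=seed + 2)
    expr = net.variance_stabilize(net.network_gene_filter(counts))
    result = net.CoexpressionNetwork(expr, power=6.0, min_module_size=20).fit()
    truth_labels = pd.Series(
        [truth.module_of.get(g, net.BACKGROUND) for g in expr.index], index=expr.index)
    ari = adjusted_rand_score(truth_labels, result.assignments.loc[expr.index])
    if result.eigengenes.shape[1] >= 2:
        cor = result.eigengenes.corr().to_numpy()
        np.fill_diagonal(cor, -1.0)
        max_cor = float(cor.max())
    else:
        max_cor = 0.0
    return {"ari": float(ari), "max_merged_eigengene_cor": max_cor,
            "n_modules_found": result.eigengenes.shape[1]}


def module_trait_power(n_sims: int = 50, n_samples: int = 64, seed: int = 0,
                       r_threshold: float = 0.4) -> dict:
    """Fraction of simulations in which the planted effort-coupled
    module's eigengene reaches |r| >= ``r_threshold`` with foraging
    effort at the study's n = 64."""
    hits, rs = 0, []
    for k in range(n_sims):
        truth = make_truth(n_genes=300, n_role=0, n_effort=0, n_modules=2,
                           module_size=40, seed=seed + 3000 + k)
        meta = study_split_metadata(0, n_samples, seed=seed + 4000 + k)
        counts = generate_counts(meta, truth, seed=seed + 5000 + k)
        expr = net.variance_stabilize(counts)
        genes = [g for g, m in truth.module_of.items() if m == truth.effort_module]
        eig = net.module_eigengene(expr, genes)
        r, _ = stats.pearsonr(eig, meta["foraging_effort"])
        rs.append(float(r))
        hits += abs(r) >= r_threshold
    return {"hit_rate": hits / n_sims, "mean_abs_r": float(np.mean(np.abs(rs))),
            "n_sims": n_sims}


def permutation_calibration(seed: int = 0, n: int = 8460, n_perm: int = 100) -> dict:
    """Permutation null for independent fold-change vectors at the
    study's ortholog count."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    res = permutation_null(x, y, n_perm=n_perm, seed=seed + 1)
    return {"mean_abs_null_tau": float(np.mean(np.abs(res.null_taus))),
            "null_mean_tau": res.null_mean, "empirical_p": res.empirical_p,
            "tau_observed": res.tau_observed}


def elim_vs_classic(seed: int = 0) -> dict:
    """Constructed leaf-only enrichment: elim reports the leaf and
    suppresses its ancestors, which classic reports."""
    parents, ns = toy_ontology(n_branches=3, depth=3)
    dag = OntologyDAG.from_edges(parents, ns)
    genes = [f"g{i}" for i in range(120)]
    direct = {g: ({"GO:B1D3"} if i < 25 else {f"GO:B{2 + i % 2}D1"})
              for i, g in enumerate(genes)}
    closed = propagate_annotations(dag, direct)
    sig = genes[:20]
    classic = {r.term for r in elim_enrichment(dag, closed, sig, genes, algorithm="classic")}
    elim = {r.term for r in elim_enrichment(dag, closed, sig, genes)}
    ancestors = {"GO:B1D2", "GO:B1D1"}
    return {
        "n_classic": len(classic), "n_elim": len(elim),
        "leaf_reported": "GO:B1D3" in elim,
        "ancestors_in_classic": len(ancestors & classic),
        "ancestors_in_elim": len(ancestors & elim),
    }
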