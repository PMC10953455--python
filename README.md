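# colonysig

Within-colony brain-transcriptome analysis for facultatively social
insects with age-ranked reproductive queues.

In a hover-wasp-style society, each small nest (3–5 females) has a
single egg-layer (rank 1) and a strict queue of non-reproductive
helpers behind her.  Helpers lower in the queue invest more in risky
foraging, so queue rank and foraging effort are strongly collinear —
which makes "is a gene tracking rank or tracking effort?" a genuinely
hard inferential problem.  `colonysig` packages the full analysis
chain for this kind of study, exercisable end-to-end on synthetic
colonies with known planted truth:

- **Synthetic colony data** — nest designs, age-ranked phenotypes
  (foraging effort on the arcsine-square-root scale, promotion by
  removal of the rank-2/3 individual, ovary and insemination status),
  negative-binomial counts with planted role-biased, effort-correlated
  and co-expression-module signals, and a second-lineage fold-change
  table with a target Kendall correlation.
- **Differential expression** — group-mean count filtering,
  median-of-ratios size factors, gene-wise NB2 GLMs (batched IRLS,
  Cox–Reid profile dispersions with empirical-Bayes moderation), and
  Wald tests of H0: effect = 0 or the composite null H0: |log2 FC| ≤ θ
  applied *during* testing, with Benjamini–Hochberg correction.
- **Collinearity decomposition** — additive models pairing one
  covariate with the OLS residuals of the other (effort +
  resid(rank~effort), and the mirror), isolating rank effects net of
  effort and vice versa.
- **Co-expression networks** — signed-hybrid adjacency (corᵝ for
  positive correlations, 0 otherwise; β = 6 by default), topological
  overlap, average-linkage module detection, eigengene merging above
  r = 0.75, module–trait correlation and module membership (kME).
- **Orthology and cross-lineage comparison** — reciprocal best hits
  from 12-column tabular alignment files, GO annotation transfer,
  Kendall fold-change correlation with a 100-permutation null, and
  Fisher's exact overlap tests in a declared ortholog universe.
- **GO enrichment** — OBO/GAF input, true-path propagation, and
  one-sided Fisher tests per term with either the classic or the elim
  (ancestor-decorrelating) algorithm.

## The models at the core

Counts for gene *g* in sample *s* are NB2 with log link:

    K_gs ~ NB(mean = mu_gs, var = mu_gs + alpha_g mu_gs^2)
    log mu_gs = log s_s + x_s' beta_g

with size factors *s_s* (median-of-ratios) entering as offsets.
Dispersions α_g are Cox–Reid adjusted profile-ML estimates, shrunk
toward a robust mean–dispersion trend with an empirical-Bayes weight;
the Wald statistic for the contrast of interest is referred to a *t*
distribution with the residual degrees of freedom.  For a fold-change
threshold θ > 0 the statistic is max(0, |β̂| − θ)/SE, a composite-null
test that is conservative by construction relative to θ = 0.

The co-expression model is the weighted-network construction:
a_ij = cor(i,j)^β if cor > 0 else 0, TOM similarity, modules from the
dendrogram of 1 − TOM, each summarized by its eigengene (first PC of
the standardized module expression).

## Worked example

```python
import numpy as np
import colonysig as cs

designs = cs.generate_colonies(n_nests=28, size_range=(3, 5), seed=1)
truth = cs.make_truth(n_genes=2000, n_role=100, n_effort=100,
                      n_modules=5, module_size=40, seed=2)
meta = cs.generate_phenotypes(designs, truth, seed=3)
meta = cs.sequenced_subset(meta, seed=4)          # the 19-vs-64 split
seq = meta[meta["sequenced"]]
counts = cs.generate_counts(seq, truth, seed=5)

fit = cs.rank_effort_regression(meta)
print(f"effort ~ rank: slope = {fit.slope:.3f} +/- {fit.slope_se:.3f}, "
      f"R^2 = {fit.r_squared:.3f}")

design = cs.DesignSpec({"role": "categorical"}, contrast="role",
                       reference={"role": "non_reproductive"})
res = cs.run_de(counts, seq, design, theta=0.0)
print(res.summary())
```

prints

```
effort ~ rank: slope = 0.325 +/- 0.017, R^2 = 0.774
Negative-binomial differential expression
  contrast:        C(role, Treatment(reference='non_reproductive'))[T.reproductive]
  genes tested:    2000
  theta (log2):    0
  DEGs (p_adj<0.05): 249  (up 106 / down 143)
```

The phenotype regression recovers the planted queue structure
(transformed effort rises by ~0.33 per rank step, explaining ~77% of
variance), and the role contrast at θ = 0 calls 249 genes — all 100
planted role-biased genes plus effort-correlated genes that covary
with role.  Repeating the fit at θ = log2(1.5) shrinks the list to
163: the threshold is part of the test, not a post-hoc filter.

The whole pipeline (simulation → phenotypes → DE → decomposition →
network → orthology → cross-lineage comparison → enrichment) runs from
one command and writes a manifest with per-stage seeds and output
digests:

```sh
colonysig all --seed 1 --outdir results/demo
```

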