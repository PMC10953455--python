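# Methods

This note records the models implemented in `colonysig`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would want to
know about.

## Study system being emulated

The package targets the analysis of brain gene expression in small
social-insect colonies organised as strictly age-ranked reproductive
queues: one inseminated egg-layer (rank 1) per nest and 2–4
non-reproductive helpers who forage, with foraging effort (the
proportion of ~30-minute daytime censuses an individual was off the
nest) increasing down the queue.  The experimental design removes the
rank-2 or rank-3 individual from each nest, promoting everyone below
her by one position, with brood removed in proportion R/N to keep the
per-capita workload constant (pupae, which need no feeding, are never
removed).  The scientific questions are (i) how strongly reproductive
role structures brain transcription, (ii) whether rank or foraging
effort better explains expression among non-reproductives — the two
are collinear, which is the crux — and (iii) whether role-biased genes
overlap across independent origins of sociality.

## Synthetic colony generator

`generate_colonies` draws 28 nests of 3–5 wasps by default, one
reproductive each, with the removed rank assigned 2 or 3 in a 15:7
ratio (the deployed design).  Phenotypes come from a linear model of
arcsine-square-root-transformed effort on integer rank:

    t = -0.34 + 0.34 * rank + N(0, 0.27),  effort = sin(clip(t, 0, pi/2))^2

The slope 0.34 is the emulated queue's regression slope; the intercept
pins rank-1 effort near zero (reproductives rarely leave the nest and
get a separate half-normal draw with SD 0.05); the noise SD 0.27 was
set once so that the regression at n ≈ 83 recovers R² ≈ 0.72, the
reported fit.  Within-rank variance is deliberately high; an optional
mixture component makes rank-3 effort bimodal (off by default — the
field observation motivating it is qualitative only).  Rank-1 females carry
round(N(12.63, 2.29)) mature eggs and are inseminated; helpers have
none and are not.

Promotion is simulated on the change scale: promoted individuals'
post-manipulation effort shifts by N(-0.1016, 0.2025) and unmanipulated
helpers drift by N(+0.0035, 0.1268), the two reported aggregate
changes, clipped so effort stays in [0, 1].  (Redrawing promoted
effort from the new rank's distribution and *additionally* shifting it
by -0.10 would double-count the reduction — the per-rank effort step
alone is ~0.2 on the raw scale mid-queue — so the direct change draw
is used.)  Unmanipulated rank-1 females are redrawn from the
reproductive near-zero distribution rather than drifted, since the
additive drift clipped at 0 would bias their change upward.

Counts are NB2 (gamma–Poisson) with log2 mean

    log2 baseline_g + log2 sf_s + role_g * [s reproductive]
      + slope_g * effort_s + loading_g * F_{module(g), s}

Baselines are log-normal (median 100, log-SD 1); dispersions are
log-normal around 0.08 (log-SD 0.25); library-size factors are
log-normal(0, 0.2).  Planted sets are mutually disjoint: role-biased
genes at ±2 log2 units, effort-correlated genes at ±3 log2 units per
unit effort (an ~8-fold swing across the queue — what a strongly
foraging-coupled gene looks like), and five 40-gene modules with
loadings U(0.5, 1.0) per latent-factor SD.  One module's latent factor
is 0.8·z(effort) + 0.6·noise, giving the effort-coupled module whose
eigengene–trait correlation the network analysis should find.  The
second-species fold-change generator couples ranks through a Gaussian
copula with ρ = sin(πτ/2), so the measured Kendall τ hits its target
to within sampling error (~0.008 at n = 8460).

What the generator does **not** emulate: within-nest relatedness,
nest-level random effects on expression, census-interval
irregularities, sequencing depth heterogeneity beyond a global size
factor, batch effects, and correlated planted sets (role/effort/module
genes are disjoint by construction, whereas real role-biased and
foraging-biased sets overlap heavily).  Passing tests therefore show
that each method recovers the signal it is designed for under a
faithful but idealised data-generating process — not that the same
power would be reached on real colonies.

## Differential expression engine

Filtering keeps a gene when its mean count within at least one sample
group (grouped by original rank) is ≥ 1 — "one count per sample" read
as a rate, not a per-sample minimum.  Size factors are median-of-ratios
against a geometric-mean reference (falling back to positive-count
genes when no gene is everywhere positive), rescaled to geometric mean
one.

All genes share one design matrix, so NB2 IRLS is batched: per
iteration one einsum forms every gene's p×p normal equations and a
batched solve updates the coefficients (clipped steps, η clipped to
±30).  Dispersion is estimated per gene by golden-section search on
the Cox–Reid adjusted profile likelihood (floor 1e-8), then moderated
toward a robust mean–dispersion trend a₀ + a₁/mean by an
empirical-Bayes weight

    w = sampling_var / (sampling_var + prior_var),
    sampling_var = trigamma((n - p)/2),
    prior_var = max(MAD²(log residuals) - sampling_var, 0.25²),

i.e. shrinkage is strong only when the per-gene estimate is noisy
relative to the genuine gene-to-gene spread.  The contrast's Wald
statistic is referred to a t distribution with n − p degrees of
freedom at the model level, so that noise in the estimated dispersion
propagates into the tails; with a *known* dispersion the reference is
normal (and the standalone `wald_test` defaults to the normal
reference).  These two calibration choices were adopted after a null
simulation (5000 genes, 40 vs 40, no effects) showed ~3–20× inflated
tail p-values for plain ML dispersions with normal tails; with them
the same simulation's tails are calibrated and BH keeps the familywise
error at its nominal level.  This is a deliberately lighter-weight
moderation than full empirical-Bayes machinery (no per-gene prior df
estimation, no outlier refitting); it is documented as an
approximation and tested against a statsmodels NB2 MLE oracle.

The fold-change threshold test uses the composite null H0: |β| ≤ θ
with statistic max(0, |β̂| − θ)/SE and two-sided-style p = 2(1 − F(stat))
capped at one.  θ is stored in log2 units.  A "1.5-fold-change threshold" admits two
conventional readings (1.5 in log2 units, or log2 of fold change 1.5),
so both are supported:
θ = log2(1.5) ≈ 0.585 is the default and θ = 1.5 is selectable;
significant sets are provably nested as θ grows.  Genes are "DEGs" at
BH-adjusted p < .05.  Rank enters continuous designs as an integer
covariate; QC-failed samples are handled as metadata exclusions.

## Collinearity decomposition

Because rank and effort correlate at r ≈ 0.85 in this design, their
separate effects are estimated from two additive NB-GLMs: effort plus
the OLS residuals of rank on effort (the residual coefficient is the
rank effect net of effort), and the mirror.  Residualization is done
once globally over the included samples (no nest stratification — the
emulated design fits none), on post-manipulation rank by
default, and reproductives are excluded by default so the
decomposition acts on within-queue variation.  The residual covariate
is exactly uncorrelated with its partner by construction, which is
asserted in tests.

## Co-expression network

Network input is the stricter second-round filter (< 10 reads in
> 90% of samples removed) followed by a variance-stabilizing
transform: log2(normalized + 1) by default, with a closed-form NB
asinh transform available.  Adjacency is signed-hybrid at β = 6;
`pick_soft_threshold` offers scale-free-fit selection (smallest power
with R² ≥ 0.8 and negative slope, else the argmax with a warning) for
users who prefer data-driven powers.  Modules come from average-linkage
clustering of 1 − TOM with a fixed cut at dissimilarity 0.995 on the
absolute [0, 1] scale, pruning branches below `min_module_size`
(default 20; the smallest module reported for the emulated study was 32 genes)
into the grey background.  A fixed-height cut is used in place of
dynamic tree cutting — no cut parameters are prescribed for the
emulated analysis, and the package's accuracy surface is
planted-module recovery (ARI), not exact module counts.  The absolute cut (rather than a cut relative to the merge-
height range) is used because a range-relative cut always splits the
dendrogram's top merge, misbehaving when all genes belong to one
module.

Eigengenes are the first right singular vector of the standardized
module matrix, sign-aligned to the mean module profile.  Merging
repeatedly fuses the most-correlated eigengene pair above 0.75 and
recomputes, so the fixed point has no pair above the threshold (module
count strictly decreases, guaranteeing termination).  Module–trait
tables use Pearson correlation with pairwise missing-data dropping and
BH across all module × trait cells (traits: foraging effort, pre- and
post-manipulation rank, age).  Module/gene-set overlaps use the exact
two-sided hypergeometric convention (sum of point probabilities ≤ the
observed one).

## Orthology, cross-lineage comparison, enrichment

Best hits maximize bitscore with e-value as tie-breaker (bitscore is
length-normalized; e-value depends on database size); queries still
tied are dropped as ambiguous, which keeps the map deterministic.
Reciprocal best hits form a partial bijection, checked on
construction.  Annotation transfer copies the partner's term set
verbatim; unpaired genes get the empty set.

The cross-lineage comparison joins per-ortholog log2 fold changes,
measures Kendall τ-b (exact p by enumeration for n ≤ 8, asymptotic
otherwise), and calibrates it against 100 permutations of one species'
fold changes with the plus-one empirical p rule, so p is never zero.
Overlap tests are one-sided Fisher enrichment by default, always
against an explicitly passed ortholog universe, with BH applied across
the family of tests declared in a single call (the paired
direction-specific tests are one family).

Enrichment propagates annotations by the true-path rule and tests
terms with one-sided Fisher tests at raw p < .01, namespace-restricted
(biological_process reported by default).  Two algorithms are
provided and tagged in every result: classic (independent per-term
tests) and elim (children-first traversal; a significant term's
significant genes are removed from its ancestors before they are
tested).  elim stands in for the weight01 decorrelation
scheme common in GO tooling because it is precisely specifiable and
testable; term lists are treated as qualitative, and no accuracy check
depends on matching particular term counts, which in any case vary
with annotation releases.

## Problem sizes and reproducibility

Harness sizes mirror the deposited design where it is known: 28 nests,
the 19-reproductive/64-non-reproductive sequencing split, 8460
orthologs, 100 permutations.  The null-FDR harness uses 5000 genes ×
80 samples × 20 seeds; recovery harnesses use 1000–2000 genes with
40–100 planted genes per class, and the module-trait power harness
runs 50 simulations at n = 64.  Every generator and the pipeline
expand one master seed deterministically (per-stage children of a
`SeedSequence`), all outputs are plain text, and the run manifest
records per-stage seeds and sha256 digests so reruns are
byte-identical.

## Known limitations

- No mixed models: nest identity is carried in the metadata but never
  fitted as a random effect, matching the emulated analyses.
- The dispersion moderation is a two-parameter trend with a single
  global shrinkage weight, not per-gene prior-df estimation; extremely
  mean-dependent dispersion structures will be under-smoothed.
- The permutation null permutes one fold-change vector only, which is
  exchangeable under the no-association null but ignores any shared
  phylogenetic structure between lineages.
- `pick_soft_threshold`'s scale-free R² uses equal-count connectivity
  bins; very small gene sets (< ~100) give unstable fits.
- The CLI's per-stage subcommand re-runs the deterministic pipeline
  from the master seed rather than resuming from intermediates.
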