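# Methods

## The analysis in brief

`traitgrad` studies how functional-trait diversity is organised in plant
communities sampled as plot-based surveys.  Three strands are combined:

1. **Trait-gradient analysis.**  With `t_sp` the (log10) trait value of
   species `s` in plot `p` and `a_sp` its abundance (fraction of quadrats
   occupied), the community mean trait is
   `p̄_p = Σ_s a_sp t_sp / Σ_s a_sp` and the species mean is
   `t̄_s = Σ_p a_sp t_sp / Σ_p a_sp`.  The among-community (β) component of
   a species is the abundance-weighted mean of `p̄_p` over the plots it
   occupies, and the within-community (α) component is the remainder,
   `α_s = t̄_s − β_s`, so `α_s + β_s = t̄_s` holds identically.  The
   intraspecific slope `b_s` is the OLS slope of a species' plant-level
   values against `p̄_p`; `b_s = 1` means individuals track the community
   gradient one-for-one.  A one-sample t-test compares the collection of
   slopes with 1.
2. **Phylogenetic comparative tests.**  Felsenstein's independent
   contrasts, computed after transforming all branch lengths to 1 (the
   transform is accepted when |standardized contrast| and its expected SD
   are uncorrelated), give through-origin correlations with `df = N − 1`.
   Phylogenetic signal is measured by Blomberg's K — the ratio of observed
   to Brownian-expected partitioning of trait variance on the tree — with a
   permutation P-value from shuffling trait values across tips (999 by
   default) and comparing the variance of standardized contrasts.
3. **Ordination.**  Bray–Curtis dissimilarities among plots,
   non-metric multidimensional scaling (best of 20 random starts plus one
   classical-scaling start), species scores as abundance-weighted means of
   plot scores, and a Monte-Carlo stress test whose null shuffles each
   species' abundance vector across plots.

## Numerical and design choices

- **Ages and branch lengths.**  Node ages are in time units before present
  with tips at 0; a branch length is the parent–child age difference.
  Undated internal nodes are aged by even spacing between their nearest
  dated ancestor and nearest dated descendant, processed from the root
  down so each node is assigned once (ties among equally near descendants
  break toward the older age, then the label).  The default root age is
  139 (a monocot–eudicot calibration).
- **Polytomies** are resolved randomly with zero-length branches before
  contrast computation (seeded; recorded in the run log).  Zero-length
  edges are floored at 1e-8 inside the contrast recursion so variances
  stay positive.  Path lengths between original nodes are unchanged, so
  the covariance structure is preserved; the contrast count is always
  tips − 1 on the resolved tree.
- **Blomberg's K** is computed by a pruning-style Gaussian elimination
  that accumulates `x'C⁻¹x`, `1'C⁻¹x` and `1'C⁻¹1` without building or
  inverting the covariance matrix; multifurcating trees are handled
  directly, which keeps K = 1 exact on star phylogenies.  The signal test
  instead expresses the contrast vector as a fixed linear operator on tip
  values, so all tip shuffles reduce to one matrix product.
- **K's tree.**  K and the permutation test default to the same
  equal-branch-length tree used for contrasts, for internal consistency;
  the pipeline's `branch_lengths="dated"` switch uses the dated tree
  instead.
- **Permutation P-values** use the add-one rank formula
  `P = (#{null ≤ observed} + 1)/(n + 1)`, so `P ≥ 1/(n+1)` always.
- **Stress scale.**  NMDS stress is Kruskal stress-1 times 100.  Axis
  signs are arbitrary; they are fixed by correlating axis 1 with a habitat
  indicator (the order habitats appear in the plot table) and remaining
  axes by the sign of the lexicographically first plot.
- **Imputation** fills an unmeasured species-plot cell with the species'
  mean from other plots at the same site; species never measured at a site
  lose those occurrences, species never measured at all are dropped.  All
  actions are logged, and imputed records are excluded from `b_s`
  eligibility and the within-species variance fraction.
- **Variance decompositions** are unweighted sums of squares over
  occurrence-level values (plot partition) and individual plants (species
  partition); an abundance-weighted variant is available but off by
  default, since the survey protocol reports plain percentages.
- **Multiple testing.**  Raw two-sided P-values are reported; a Holm
  adjustment over each correlation family is available behind a flag and
  off by default.
- **Height** enters as a species-level constant (flora value): it takes
  part in the α/β partition and the comparative tests but is excluded from
  `b_s` and the within-species variance fraction, which need individual
  measurements.

## The synthetic-data generator

The generator emulates a two-habitat grassland survey: 76 species on an
ultrametric Yule tree, 27 plots in two habitat blocks split across sites,
abundances as occupied fractions of 10 quadrats, eight log10-scale traits,
and 2% of occurrences left unmeasured.  Species receive:

- an **α component**: Brownian motion on the tree, standardised and scaled
  to `alpha_sd` (tip-shuffled when the α-signal switch is off);
- a **habitat affinity** on [−1, 1]: a rank-rescaled Brownian trait,
  tip-shuffled by default so affinity carries no phylogenetic signal;
- a **commonness** drawn lognormally (`dominance_sd`), so a few dominants
  recur in most plots as in real abundance distributions.

Occupancy is independent Bernoulli per quadrat with probability
`commonness × exp(−(affinity − e_p)²/(2·breadth²))`, where `e_p` is the
plot environment (habitat centre plus jitter).  There is no spatial
autocorrelation within plots, no dispersal limitation, and no
trait–abundance feedback; passing tests on these data show the estimators
behave correctly under the assumed sampling model, not that real
communities satisfy it.

**Intraspecific slopes.**  Plants respond plastically to the standardised
plot environment `u_p`.  The estimated `b_s` is, structurally, the share
of the community-mean gradient carried by that shared plastic response
(the remainder being species turnover).  The generator therefore measures
its own turnover trend `κ` (slope of abundance-weighted plot-mean base
values on `u`) and sets the plastic coefficient to `κ·b/(1 − b)` so the
plastic share is exactly `b_s_true`.  `b_s_true = 1` is the limiting case
in which turnover contributes nothing along the gradient; the generator
realises it by residualising species base values against their mean
gradient position and setting the plastic coefficient to `gradient_sd`
directly.  Recovering the slope *statistically* also requires the gradient
to dominate the plot means: `slope_calibration_config` documents a
configuration (small `alpha_sd`, strong turnover link, three plants per
occurrence, rich plots) in which the t-test of slopes against 1 holds its
nominal level.  Under the survey-realistic defaults the estimate is
attenuated below the generative ratio — composition noise enters the
regressor — which mirrors the downward-biased slope estimates such surveys
themselves produce.

**Default parameter choices** (log10 trait units unless noted):
`alpha_sd = 1` sets within-community species spread; `gradient_sd = 0.3`
and `beta_coef = 0.1` keep among-plot variance at a few percent of the
total, matching surveys where nearly all trait variation is within
communities; `noise_sd = 0.25` puts the within-species variance fraction
near 10%; `niche_breadth = 0.5` against a habitat separation of 1.2 leaves
a minority of species shared between habitats; `detectability = 0.12`
yields realistic plot richness (~15–25 species).

## Scaling of the validation runs

The test suite and the acceptance script verify, at sizes chosen to keep
runs reproducible on a single CPU: the partition identities on 1000 random
tables; contrasts and K against brute-force oracles on trees of 4–8 tips;
K calibration over 200 Brownian simulations on a fixed 64-tip tree; the
permutation test's type-I error over 500 signal-free replicates with 199
shuffles; slope recovery over 200 scenario draws per setting; the
α-signal/habitat-signal contrast over 100 scenario draws (64 species, 24
plots, 199 shuffles); and the Monte-Carlo stress test at 99 runs.

## Known limitations

- NMDS relies on scikit-learn's SMACOF; with few plots the stress surface
  is multimodal and the reported minimum depends on the number of starts
  (a classical-scaling start is always included to stabilise easy cases).
- The permutation signal test assumes exchangeable tips under the null;
  strongly unbalanced sampling of clades is not corrected for.
- The t-test on `b_s` treats species as independent; because every species
  is regressed on the same realised plot means, community-level noise
  induces correlated slope errors and can inflate the test's size when the
  gradient is weakly identified (see the calibration discussion above).
- Contrast-based statistics require complete trait coverage of the pruned
  tree; species missing traits are dropped rather than imputed on the
  phylogeny.
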