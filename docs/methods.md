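# Methods

## Clade agglomeration

A clade is an internal node of the rooted ASV phylogeny with all of its
descendant tips; tips themselves are not emitted as clades (their
abundances are already rows of the ASV table), so a fully bifurcating
rooted tree over n tips defines exactly n − 1 clades. The clade
abundance matrix `ctu` is built by a single postorder accumulation:
each internal node's per-sample vector is the sum of its children's
vectors, which makes the hierarchical-consistency invariant
(`parent = Σ children`, `root = sample total`) hold exactly by
construction. Polytomies contribute one clade each; no implicit
resolution is performed, because only monophyletic groups actually
present in the tree are meaningful units. Clade identifiers are SHA-1
content hashes of the sorted member tip labels, so identifiers are
stable across reruns, tree-file orderings, and machines.

Midpoint rooting places the root halfway along the longest tip-to-tip
path. When several paths tie for the diameter (within 1e-9), the path
whose sorted endpoint-label pair is lexicographically smallest is used —
an arbitrary but deterministic choice made for reproducibility. If the
midpoint coincides with an existing node the tree is rooted at that node
rather than inserting a zero-length edge. Pruning to a tip subset
collapses unary internal nodes and sums their branch lengths, so all
pairwise tip path lengths are preserved.

## Count model and inference

Clade abundances are modelled as NB2: y ~ NB(μ, θ) with log link and
Var(y) = μ + μ²/θ. The GLM is fitted by Fisher-scoring IRLS for β at
fixed θ, alternating with Newton updates of θ in log space on the
profile score, until the log-likelihood changes by less than 1e-10
(relative); θ is bounded to [1e-3, 1e6] with a boundary flag (the upper
bound is the Poisson limit). Standard errors come from the observed
information for β at the optimum, X'WX with
w_i = θμ_i(θ + y_i)/(θ + μ_i)².

The GLMM adds a normal random intercept b_h per host. The marginal
likelihood integrates b_h out by adaptive Gauss–Hermite quadrature:
per host, the conditional mode is found by a (globally convergent,
because the integrand is strictly log-concave) Newton iteration, the
quadrature is centred and scaled at the mode, and 7 nodes are used by
default (1 node = Laplace approximation). The parameters
(β, log θ, log σ_b) are maximized by L-BFGS-B with log σ_b bounded in
[−6, 3]; a fit that lands on the lower bound is reported as σ_b = 0
with a "boundary" flag — the valid degenerate case in which the GLMM
reduces to the GLM. Standard errors come from a central finite-difference
observed information at the optimum, with boundary variance parameters
held fixed. The test suite verifies the fitter against its analytic
reductions (GLM at sigma_b = 0) and against Monte-Carlo parameter
recovery at known sigma_b.

Each battery Wald-tests the single non-intercept slope of its formula
(age, diet, or IL-6) against a normal reference. BH adjustment runs
across the clades of each model family separately — one family for age,
one per age × study cell for diet (four), one per age group for IL-6
(two) — because each family is a separate screening question. The
intercept-sign exclusion is applied after BH: clades with q < 0.05 but
a negative fitted intercept leave the significant set (with the reason
recorded) but stay in the BH family. Clades that are all-zero or
nonzero in fewer than 3 samples of a family's subset are reported as
degenerate and not fitted, since their likelihoods are flat or
unbounded and would pollute the FDR family.

Wald z-tests on NB fits are known to be mildly anti-conservative at
these sample sizes (40–160 observations with θ estimated): under a
fully null simulation the raw per-clade rejection rate at α = 0.05 is
≈ 0.07–0.08 rather than 0.05, and the per-family probability of at
least one BH discovery runs ≈ 0.05–0.12. This is a property of the
Wald/ML machinery itself (shared by the usual glm.nb/glmer.nb
pipelines), not of this implementation; the acceptance checks bound it
by 0.05 + 3 Monte-Carlo SEs.

## Nonparametric screens

Genus screens operate on relative abundances. The rank-sum test uses
exact enumeration when both groups have ≤ 10 observations and no ties,
otherwise the tie-corrected normal approximation; Kruskal–Wallis uses
the standard tie-corrected H. A taxon whose values are identical in all
groups carries no evidence and is assigned p = 1. BH runs across taxa
within a screen (and within each age stratum for the diet screen, which
is restricted to week-6 samples).

## Synthetic-data generator

The generator emulates the statistical structure of the two-study
design the batteries assume:

- **Design**: 2 studies (ZAM1: ZA vs ZS; ZAM2: ZA vs ZD) × 2 ages × 2
  diet arms × 10 hosts = 80 mice, each sampled at wk0 and wk6
  (160 samples).
- **Counts**: per tip t, log μ = log(D·p_t) + planted effects + b_h +
  o_s, y ~ NB(μ, θ) with θ = 2 by default; b_h ~ N(0, σ_b²) with
  σ_b = 0.5 is a host-level intercept shared by all tips, and o_s ~
  N(0, 0.25²) models library-size variation around a mean depth
  D = 130,000 reads.
- **Baselines** p_t are a normalized log-normal with log-SD 2.3
  (≈ 4 orders of magnitude of dynamic range), emulating the dominance
  structure of real gut communities.
- **IL-6** (pg/ml, week 6 only): baseline 40 + 60·(old) + 40·(ZD) +
  N(0, 25²), truncated at 0. The increments implement the observed
  pattern that LPS-induced IL-6 rises with age and with zinc
  deficiency; the specific magnitudes are a choice (no values are
  published) picked to give within-age IL-6 spreads of roughly
  25–45 pg/ml.
- **Planted effects** multiply every member tip of a target clade, so
  clade sums inherit the fold-change exactly and hierarchical
  consistency is preserved. Default planting selects 15 disjoint clades
  of 2–4 tips (5 per battery, log-FC 1.5; the IL-6 version is a slope
  of 1.5 per 100 pg/ml), preferring clades from the rare half of the
  abundance distribution. Each planted clade's baseline mass is clamped
  into [0.1%, 0.2%] and spread evenly over its tips: planted targets
  emulate rare-but-consistently-present taxa, which keeps the
  compositional spillover of the planted fold-changes onto unplanted
  clades negligible after rarefaction and keeps every planted tip above
  the prevalence filter.

What the generator does **not** emulate: sequence-level error and
chimeras, taxonomy misassignment, phylogenetic signal in the baseline
abundances, diet effects that emerge only at week 6 (planted diet
effects apply to both timepoints because diet is a host-level
covariate), and real compositional interactions between abundant taxa.
Passing recovery tests therefore demonstrate that the statistical
machinery detects clade-level NB fold-changes of the planted size under
the design's sample sizes — not that real zinc effects of that size
would be detected in the presence of those unmodelled features.

Because the host intercept multiplies all tips equally, rarefaction
cancels it from the composition; the diet GLMM's random intercept then
mostly absorbs residual per-host variation, and σ_b estimates near 0
on rarefied synthetic data are expected rather than alarming.

## Truth scoring

Sensitivity counts exactly the planted clades recovered in their scoped
family. For the empirical FDR, a discovery is counted false only when
its member tips carry no planted signal for *any* covariate: ancestors
and descendants of a planted clade genuinely share its signal, and the
design's covariate correlations (IL-6 rises with age and deficiency)
make clades planted for one covariate truly associated with the others.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline at
reduced sizes chosen to keep a desk run fast: trees of 60–61 tips
(59–60 clades; the structural-identity check uses the full 361), 40
null replicates and 30 planted-recovery replicates in the suite, and
10–20 replicates in the acceptance script. Monte-Carlo error bounds
scale with the replicate counts actually used
(0.05 + 3·sqrt(0.05·0.95/R) for null FDR).

## Numerical and design choices

- Prevalence threshold 5 = half an experimental unit of 10 mice;
  a feature present in exactly 5 samples is retained.
- Rarefaction depth defaults to the minimum retained sample total
  (no published depth exists to copy); the seed is mandatory, and
  rarefaction is performed once on the ASV table before clade
  construction so tips and clades stay consistent.
- Filtering precedes rarefaction.
- The diet models include both timepoints with the host random
  intercept and no time term, mirroring the printed formula; whether a
  time covariate belongs in the model is an open modelling question we
  resolve in favour of the simpler printed form.
- Diet/age are coded 0/1 with the control (ZA, young) as reference;
  positive slopes mean higher abundance in the old / zinc-modified /
  high-IL-6 direction.
- Significant-clade counts are reported per family and as the pooled
  union across families.
- Ties in midpoint rooting, BH sorting, and group ordering are broken
  lexicographically or by stable sorts throughout; batteries contain no
  internal randomness, so identical inputs give identical outputs.

## Known limitations

- Wald-based inference is mildly anti-conservative at small n (see
  above); a parametric bootstrap would calibrate it but is out of scope.
- The GLMM's finite-difference Hessian can be inaccurate when θ or σ_b
  sits at a bound; such fits are flagged and their Wald tests treated
  as non-converged rather than trusted.
- Rarefaction discards counts; offsets for library size are an
  alternative deliberately not offered, to match the rarefied-counts
  analysis this package reproduces.
- The exclusion of negative-intercept clades is a heuristic inherited
  from the reproduced analysis; it removes mostly very rare clades
  whose baseline log-abundance is genuinely negative on the rarefied
  scale.
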