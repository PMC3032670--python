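# Methods

## Synthetic eQTL system

The generator builds a DAG over `L` genomic loci (head nodes, in-degree 0)
and `N` transcripts in two steps.

**Step 1 — locus-rooted trees.** Transcripts are attached one at a time,
in random order, to a uniformly chosen locus tree; within the tree the new
transcript attaches to a uniformly chosen *current leaf* (the bare locus
counts as the initial leaf, so each tree is a single stalk from its
locus).  Leaf attachment yields deep branching trees.  We also evaluated
uniform attachment over all current tree nodes; it produces much shallower
trees in which fewer than half of the transcripts descend from two or more
loci and the weak tail of parent–child correlations is overrepresented,
both inconsistent with the linkage complexity of real segregant panels
that the generator is meant to emulate (a majority of transcripts linked
to two or more loci).  Leaf attachment reproduces those properties
(roughly 80% multi-locus transcripts at the default configuration) and is
the default and only mode.

**Step 2 — extra edges.** Each of `n_extra_edges` additional
transcript→transcript edges is classified inter-loci with probability 0.9
(endpoints drawn uniformly from different trees) and feed-forward
otherwise (a uniformly chosen transcript to a uniformly chosen proper
descendant in the same tree); duplicates and cycle-creating proposals are
rejected, with a 1,000-attempt cap per edge before the configuration is
reported as over-constrained.  Defaults: 2,200 transcripts, 50 loci, 398
extra edges — 2,598 edges in total.

**Expression model.** Genotypes are i.i.d. Bernoulli(0.5) coded {0, 1}
(independent loci, haploid segregants).  In topological order, each
transcript is `y = Σ a_i x_i + ε` with `ε ~ N(0, 1)`; coefficient
magnitudes are `N(0.75, 0.2)` (strong regime) or `N(0.6, 0.2)` (weak),
signed positive with probability 0.7.  Ten percent of transcripts with
two or more parents (rounded to the nearest count) additionally carry
`Σ k_ij x_i x_j` over all unordered parent pairs, `k ~ N(0.5, 0.1)`.
Values are not re-standardized, so variance grows with depth; this is
what lifts the mean parent–child |Pearson r| to ≈ 0.68 (strong) / 0.55
(weak) even though a single locus explains little of a direct child.

**A caveat on the correlation interval.** We summarize the per-edge |r|
distribution by its mean and empirical 5th/95th percentiles.  The upper
percentile lands near 0.90; the lower near 0.36 in the strong regime.
A lower endpoint as high as 0.45 is not attainable as an empirical
percentile under this generative model: locus-adjacent edges (binary
parent, variance 0.25) and lower-tail coefficient draws necessarily place
more than 5% of edges below |r| = 0.45 at unit noise.  A Gaussian
approximation (mean ± 1.645 sd) would raise the lower endpoint to ≈ 0.42
but push the upper endpoint past 0.95; no interval construction fits both
ends, so we report empirical percentiles and note the discrepancy.

What the generator does *not* emulate: feedback loops, diploid genetics,
linkage between loci, genotyping error, measurement-level normalization
artifacts.  Tests passing on these data show the methods recover the
stated generative process; they do not certify performance on real
expression data, where effect tails, confounding and non-linearity are
harsher.

## Regression potentials and the SCT score

Pair potential: `φ(n_p, n_c) = R²` of the OLS regression (with intercept)
of child on parent — equal to the squared Pearson correlation, symmetric
for continuous pairs, and well-defined against a binary locus parent.
Conditional potential: regress child on parent, take residuals `e`, then
`φ(n_g, n_c | n_p) = R²` of `e ~ n_g`; on a true chain g → p → c it
converges to zero.  Internally the engine uses the closed form
`(r_gc − r_pc r_gp)² / (1 − r_pc²)`, which agrees with the two-step
regression to 1e-10 (tested property).

Backgrounds: for each node, the mean/SD of the pair potential against 500
random partners per role (explanatory / response), drawn without
replacement and exhaustively when the pool is smaller — loci appear only
in the explanatory role.  The observed potential is standardized against
both nodes' backgrounds and scored under a bivariate Gaussian with
covariance ρ = 0.  The conditional potential is scored under `N(0,
σ_cond²)`, with σ_cond the root-mean-square conditional potential of
10,000 freshly simulated linear chains at the dataset's sample size
(mean fixed at the null value 0; the RMS-about-zero convention matches
that assumption).  Densities are floored at 1e-300 before logs.

Transition score: `LLS = c1·log l(φ_cond) − log l(φ_pair)` — high when
the pair potential is unusually strong for those two nodes *and* the
grandparent explains nothing beyond the parent.  Defaults `c1 = 5.0`,
`p = 3.0`, `M = 60` leaves, `I = 1000` iterations over all loci.  Root
transitions have no grandparent; each best-transition query from the root
draws a fresh surrogate conditional potential from `N(0, σ_cond)` (one
draw per query, shared across that query's candidates — the surrogate
then shifts the stochastic-selection weight without perturbing the
argmax).  Stochastic leaf selection weights each member's best transition
by `max(score, 1e-6)^p`; the clip keeps non-positive scores selectable
while preserving order.

Because the score for a fixed (parent, grandparent) pair is independent
of the tree, the engine caches the full descending candidate ranking per
pair and answers queries by walking past excluded members — exactly
equivalent to re-scoring, and what makes `I × |L|` tree growths cheap.

**Prior normalization.** Tallies f(i, j) divide either by `M·|L|·I`
("formal") or by the tree count `|L|·I` ("tree_count"); the two conventions
differ by the constant `M`.  Both are exposed (`sct.build_prior` defaults
to formal).  The pipeline defaults to tree-count, for a scale reason made
explicit here: the Gibbs prior contributes `β·R[i,j]` per edge, and the
useful β range {4..24} assumes full-scale tree coverage (60 of 2,250
nodes per tree, ≈ 2.7%).  At desk scale a tree covers ≈ 40% of the
system, so tree-count R entries are an order of magnitude larger relative
to full scale, and the formal convention (dividing by M) over-corrects in
the opposite direction; on our calibration runs the tree-count scale is
the one whose β grid brackets the useful prior strength.

## LCMS comparator

For a triplet (tx, ty, L): M1 (tx → ty), M2 (ty → tx), M3 (independent),
each a per-sample mixture over the two genotype classes with empirical
class frequencies; Gaussian components with per-class ML parameters; the
M1/M2 conditional factors are pooled OLS regressions.  M3's conditional
term is the conditional bivariate normal **under the independence
constraint**: with the class-conditional partial correlation fixed at
zero it reduces to the per-class marginal l(ty | L).  Realizing it
instead as an unconstrained per-class regression would make M3 nest the
causal models and win on essentially any data, so that reading is
rejected on identifiability grounds.  Bootstrap (default 1,000
resamples; degenerate resamples redrawn up to 10 times) converts
likelihood wins into model probabilities; the two-branch rule converts
probabilities into directed scores (sum over shared anchoring loci, with
independence downweighting when any locus gives p(M3) > 0.5).  Scores are
clipped into [0, 1] for the prior matrix (an optional rescale flag
divides by the maximum positive score first, preserving gradation).
Pairs are enumerated from a univariate linkage table at nominal p < 0.05.

## Bayesian network structure learning

Expression is discretized per transcript by 1-D k-means (k = 3, 10
restarts, per-column seeds derived from the global seed), labels ordered
by centroid (down / steady / up); genotypes keep their two levels.
Families are scored with BDe (structure-equivalent Dirichlet priors,
equivalent sample size 1 — the standard default; Markov-equivalent
structures score identically, a tested property).  Candidate sets: top-10
|Pearson| partners per node with reciprocity closure.  Moves: single-edge
addition / removal / reversal, acyclic, ≤ 3 parents, candidate pairs
only, never into a locus; proposals uniform over the legal move set with
the Hastings factor |η(G)|/|η(G′)|.  Chains initialize with
`min(2000, ⌊0.9·N⌋)` random candidate-legal edges.  Posterior edge
frequencies are mean edge indicators over networks sampled every 200
iterations after burn-in; interval tallies support the distortion
diagnostic (mean |Δ frequency| over all head-node-legal ordered pairs).

Two engines share one semantics: a pure-Python reference (with a
continuous audit mode re-deriving every cached quantity) and a compiled
numba kernel (bitset transitive closure, per-pair candidate-list move
enumeration, packed-key family-score cache) that runs ≈ 6 µs/iteration
at 105 nodes and is validated against exhaustive 3-node posterior
enumeration and against the reference engine.

## eQTL mapping and evaluation

Network mapping: (locus, transcript) linkage iff the transcript is
reachable from the locus; over sampled networks the linkage frequency is
the mean indicator.  Univariate baseline: pooled-variance two-sample t
per (transcript, locus); permutation FDR pools null |t| over transcripts
and loci with one expression-row permutation per replicate,
FDR(τ) = mean null exceedance / observed exceedance, capped at 1, with a
step-down monotone envelope (raw quotient retained).  Precision–recall
curves sweep descending score thresholds (for integer tallies this
touches every occupied level of the decrement-by-1 sweep); AUC is the
trapezoid over recall anchored at recall 0; recall-at-precision takes the
best recall among points at or above the precision level, without
interpolation.

## Scaled experiment configuration

The headline experiments (2,200 transcripts, 150M-iteration chains) are
cluster-scale.  The in-package comparison experiment uses 100 transcripts
/ 5 loci / 18 extra edges, strong regime, 200 segregants; SCT prior with
M = 40 (twice the transcripts-per-locus ratio, inside the recommended
{1.0F..2.5F} band), I = 200, c1 = 5.0, p = 3.0, tree-count normalizer,
β = 16; LCMS with the full 1,000 bootstrap resamples and β = 4 (the grid
optimum at 200 samples, consistent with the published β tables); four
pooled chains of 1M iterations per method, sampled every 200 after a 100k
burn-in per chain.  Pooling several moderately long chains averages over
initialization modes, which at this scale reduces consensus variance more
than doubling a single chain's length.
β grids for both methods and both normalizer conventions were evaluated
once on a dedicated calibration seed, separate from the evaluation seeds,
mirroring the published parameter-optimization protocol.

## Known limitations

* Single-edge moves mix slowly through Markov-equivalence classes; at
  desk scale individual chains can lock into modes, which is why the
  comparison pools two chains and why recall-at-precision on a ~120-edge
  truth set remains a high-variance statistic.
* The LCMS reconstruction follows the printed two-branch rule and mixture
  likelihoods; the original's exact supplemental component forms were not
  available, and the independence-constrained M3 is our resolution of
  that gap.
* The permutation-FDR baseline and the LCMS linkage table share the
  univariate scan's blind spot: deep transcripts with attenuated marginal
  locus effects are invisible to both, which is precisely the regime the
  network-based mapping is designed to reach.
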