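# Methods

This note documents the models, parameter conventions and numerical
choices behind `stagepath`, and what the synthetic benchmark does and does
not establish about real data.

## Biomarker selection (mRMR + IFS)

**Discretization.** mRMR operates on discrete states. Each gene is
ternarized per contrast subset at mean ± *k*·SD with *strict*
inequalities (boundary values map to the middle state) using the
population SD (÷ n). Default *k* = 1. A constant gene becomes an all-zero
state vector and is logged; it can never be selected by relevance.

**Mutual information.** Plug-in estimator on the empirical joint
distribution, in nats. No bias correction is applied; consequently the
MIQ quotient (relevance / mean redundancy) is noisy for uninformative
genes whose relevance and redundancy are both near the finite-sample MI
bias ≈ (|X|−1)(|Y|−1)/2n. Occasional noise-gene interlopers in the middle
of an mRMR ranking are expected behaviour of the quotient scheme, not a
defect; the MID difference scheme (available via `scheme="MID"`) is more
conservative. MIQ remains the default because it is the convention of the
canonical mRMR implementation this stage follows.

**Ties.** Every greedy step resolves ties toward the smaller input gene
index. Exact ties occur when two genes share a contingency table; in that
case floating-point summation order, not the comparison logic, decides
which is "first" — the selected gene always attains the maximal objective
value.

**Nearest-neighbour LOOCV.** Each sample is predicted as the label of its
nearest other sample by Euclidean distance on per-gene standardized
expression (standardization prevents high-variance genes from dominating;
the underlying classifier citation specifies no metric). Distance ties
resolve to the smallest sample index. The IFS curve is computed by growing
the squared-distance matrix one gene at a time, which is algebraically
identical to a from-scratch LOOCV at every prefix (asserted by test).

**IFS optimum.** Smallest prefix length attaining the maximal accuracy
(parsimony). The evaluation range `max_k` defaults to min(500, n_genes);
the optimum on the default synthetic study sits around 10–20 genes, so
tests and the acceptance script evaluate to 40–60 to bound cost.

## Network model

Edge distance is `1000·(1 − score)`; admissible scores span [0.150, 1]
inclusive, so distances span [0, 850]. Confidence ranks use strict
thresholds (>0.400 medium, >0.700 high, >0.900 highest); a score of
exactly 0.700 is therefore *medium*, and the screening length criterion
is likewise strict (< 300). Zero-weight edges (score 1.0) are legal;
shortest paths are computed with Dijkstra (non-negative weights by
construction).

"The" shortest path must be reproducible because its interior nodes feed
the hub counts, so among equal-length paths the implementation picks the
one minimal by (hop count, then lexicographic node sequence). Length
queries during screening use plain Dijkstra; the tie-broken reconstruction
runs only for retained pairs.

## Transition screen

Correlations are tested once per (early, late) pair on the pooled Dukes
B ∪ C columns — the stages between which the transition happens — with a
two-sided p-value from the t distribution on n−2 df. BH adjustment is
applied once across the whole family of tested pairs (not per early
gene). Pairs whose endpoints coincide (a gene in both biomarker sets) are
excluded; constant genes are excluded with a log entry. Both screening
criteria are strict inequalities, and both positively and negatively
correlated pairs qualify; the sign is reported per path.

## Permutation FDR

The null model relabels gene symbols: one random bijection over the union
of network-node and cohort-gene symbols is applied to both structures
simultaneously (joint relabeling keeps the two views of a symbol
consistent; independent bijections are available behind a flag).
Topology, edge scores and expression values are untouched. Per
permutation the shortest-path length and the BH-adjusted correlation FDR
of every screened pair are recomputed over the same pair family as the
actual screen; a path's FDR is the fraction of permutations in which both
permuted statistics are strictly smaller than the actual ones. A permuted
pair that falls off the network or loses connectivity contributes an
infinite length, which never counts as "shorter"; a permuted pair without
expression rows cannot beat on the correlation side.

*Implementation.* A relabeling only moves symbols, so the permuted
statistic of pair (e, l) equals the actual statistic of the
inverse-permuted pair. All-pairs graph distances (scipy csgraph, with a
dense adjacency so zero-weight edges survive) and the gene×gene p-value
matrix are precomputed once; each permutation is then pure indexing plus
one vectorized BH pass. A test asserts exact equality with the literal
relabel-and-recompute construction. The loop is single-threaded and
deterministic under the seed; a `--threads` option is accepted for
interface compatibility and cannot change results.

*Calibration caveat.* This FDR is a **joint** beat probability. Even on
null data it is not Uniform(0,1): with independent length and correlation
statistics it behaves like the product of two near-uniform variables
(Kendall distribution t − t·ln t), further depressed by infinite permuted
lengths and by BH tie-flattening under strict inequality. Interpret it as
a conservative exceedance score, not a uniformly calibrated p-value; small
values (< 0.05) on real paths remain meaningful because genuinely short,
strongly correlated pairs are rarely beaten jointly.

## Hubs and overlap

A transition gene is an *interior* node of a retained path — endpoints
(biomarkers) are not transition genes; `include_endpoints=True` is offered
for sensitivity analysis. Hub rank is the number of paths crossing the
gene (each path counts once; shortest paths are simple). The overlap
statistics use the hypergeometric mean |S₁|·|S₂|/N for the expectation and
the classical 2×2 cross-product odds ratio (a·d)/(b·c), reported to three
significant figures, undefined when b·c = 0.

## Synthetic data generator

The generator emulates a staged expression study at desk scale. Defaults:
stage sizes 44/94/91/61 (the emulated cohort), 500 genes and a 400-node
network (scaled from ~19,600 genes / ~15,200 proteins), background
expression i.i.d. Gaussian per gene with mean ~ N(8, 2) and SD ~ U(0.5,
1.5), confidence scores from a mixture concentrated on 0.15–0.40 with a
thin tail above 0.9 (so the 300 cutoff is selective), 10 early + 10 late
planted markers, 5 planted pairs.

**Marker model.** Each planted marker combines a stage-wide mean shift of
`stage_shift_fraction × effect_size` SDs (default 0.3 × 3 SD) with a
full-`effect_size` elevation in its own disjoint block of the shifted
stage's patients (mutually exclusive subtypes, as seen with mutually
exclusive driver alterations). The stage-wide component is what a
per-gene t-test sees; the subtype component makes markers individually
modest but jointly necessary, so the IFS accuracy curve keeps rising
until the whole panel is selected — the qualitative behaviour of the
emulated study, whose optima lay at hundreds of genes. A uniform
full-effect shift would instead let one or two genes classify perfectly
and the parsimonious IFS optimum would stop there; planted-panel
recovery would be impossible by construction. `stage_shift_fraction` was
fixed once at 0.3, where 20-seed recovery of planted markers and pairs
exceeds 90%.

**Correlation planting.** For each planted pair the late gene's pooled
B ∪ C values are replaced by ρ·standardized(early) + √(1−ρ²)·noise,
rescaled to the gene's own mean and SD — exactly the samples the screen
tests, leaving the C-vs-D contrast intact. Default ρ = 0.9.

**Network planting.** Planted pairs are joined by paths of
`planted_path_edges` edges (default 3, capped at 5) at confidence ≥ 0.95,
giving weighted lengths ≤ 250 < 300; six such edges would reach exactly
300 and fail the strict criterion, hence the cap. A configurable fraction
of non-planted markers (default 0.15) is withheld from the network to
exercise the biomarker-mapping step.

**What passing tests do not show.** The generator draws i.i.d. Gaussian
expression; real microarray cohorts have correlated background genes,
batch structure, heavier tails and probe-level artifacts, none of which
are modelled. Recovery rates measured here are therefore upper bounds on
real-data behaviour, and the null-calibration experiments characterize
the method, not any particular platform.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline at the default
synthetic scale (500 genes × 290 samples, 400-node network), 20-seed
recovery and calibration experiments, and 100–20,000 permutations
depending on context; the permutation default of 20,000 matches the
emulated study. A single integer seed drives every stochastic stage
through spawned substreams, and rerunning any configuration reproduces
all output files byte-identically (asserted by test).
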