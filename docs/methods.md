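# Methods

This note documents the models, defaults and numerical choices behind
`netprio`, and what the synthetic benchmarks do and do not establish.

## Random walk with restart

The interactome is an undirected, optionally weighted gene graph. Its
transition operator is column-stochastic,

    W[v, u] = w(u, v) / deg_w(u),

and the walk iterates `p ← (1−r)·W·p + r·s` with `s` uniform over the
seed genes retained in the network. For `r ∈ (0, 1]` the map is an L1
contraction with factor `1−r`, so the fixed point exists, is unique, and
power iteration converges geometrically. Iteration stops when the L1
change falls below `tol = 1e-10` (at most 1000 iterations, then a
convergence error reporting the last residual). Tests verify the
iterate against the closed form `p = r(I−(1−r)W)⁻¹s` computed by a
direct linear solve to < 1e-8 on random graphs.

**Restart probability.** `r = 0.7` by default, the conventional setting
for PPI-based gene prioritization: large enough that probability mass
stays within a few hops of the seeds, small enough that indirect
(2-3-step) interactions still contribute. All walk parameters are
configuration, surfaced in `RunConfig` and every CLI subcommand.

**Seed handling.** Seeds absent from a given network are dropped with a
logged warning (different interactomes have different coverage); the
restart vector is uniform over the retained seeds. Risk categories are
carried as metadata but not weighted — there is no principled weighting
between, say, high-risk and driver genes, so none is invented.

## Degree-aware adjustment

Raw visitation probabilities are confounded by degree: hubs are visited
often under any seeding. The adjustment compares the seeded walk with a
*reference* walk whose restart vector is uniform over all nodes — the
degree-driven baseline — and scores each gene by the log-likelihood
ratio `score(v) = log(p(v)/p_ref(v))`. Candidates are ranked by
descending adjusted score, ties broken lexicographically; seed genes are
never ranked as candidates; candidates absent from the network are
reported as unrankable rather than silently dropped. Both the raw and
the adjusted ranking are written out, since the two orderings are
informative to compare. On scale-free benchmarks the adjustment lowers
|Spearman(score, degree)| relative to raw probabilities in essentially
every replicate.

## Permutation significance

For each candidate gene, θ counts random seed sets whose walk gives the
gene a larger probability than the real seed set does, and `P = θ /
n_sets` (default 1000 sets, sized to the retained seed count).
Exceedance is strict; because the compared probabilities come from an
iterative solver, values equal up to an absolute `tie_eps = 1e-9` are
treated as ties and never increment θ (probabilities are on the scale of
1e-1 to 1e-4 here, so 1e-9 is far below any meaningful difference but
above solver error). Random sets are drawn uniformly without replacement
from the network's nodes — genes outside the network have zero
visitation under any seeding and cannot contribute to the null — and may
include real seed genes (an `exclude` flag removes them, and a
`degree_matched` flag draws degree-binned sets, both for sensitivity
analysis). Significance is declared at `p < 0.05`, strict, with no
further multiple-testing correction. Under a null with random true
seeds, measured rejection at 0.05 is ≈ 1/20 (the add-one lattice effect
makes it (⌊αn⌋+1)/(n+1) exactly under exchangeability).

## Hot-subnetwork detection

Vertex scores are patient carrier fractions (pooled across families:
total carriers ÷ total sequenced cases) for candidate genes and a
constant for seed genes, defaulting to the maximum candidate fraction —
seeds stay as hot as the hottest candidate without dominating. Unscored
genes carry no heat.

The similarity kernel `F = r(I−(1−r)W)⁻¹` is computed by dense
inversion (column u of F is exactly the single-seed walk from u; columns
sum to one). Dense inversion is intended for networks up to ~5000 nodes;
beyond that the same contract would need an iterative column-by-column
path. The exchanged-heat digraph has `u→v` weighted `F[v,u]·score(u)`.

`component_hierarchy` sweeps δ over all distinct edge weights
(descending), keeping edges `≥ δ` and recording strongly connected
components of size ≥ 2. Components can only merge as δ decreases; this
nesting property is asserted at every level.

`significance` evaluates the largest-SCC size as a function of δ on a
log-uniform grid of ≤ 40 thresholds spanning the positive weights —
diffusion weights decay geometrically with distance, so a log grid
resolves every scale while linear quantiles would concentrate in the
tiny-weight percolated regime. The null permutes score values uniformly
across scored vertices. Two details matter for honesty of the p-value:

- **Reporting resolution.** `selected_delta` maximizes the observed
  excess (observed − mean null largest-component size); clusters are
  reported at that δ, which lands where the hot cluster is fully
  assembled.
- **Calibration.** Comparing observed and null *at the selected δ* is
  anticonservative (the δ was chosen to maximize the excess; measured
  type-I ≈ 20% at nominal 5%). The p-value therefore uses a studentized
  max-T: per-δ excess is scaled by the null standard deviation (+1
  component to bound the denominator), and the observed maximum over the
  sweep is referred to each permutation's own maximum. Measured on
  shuffled-score replicates this rejects at ≈ the nominal rate, while
  recovering a planted 10-gene module among 500 nodes at p ≈ 0.01.

Cross-network consensus for modules is membership of a significant
cluster in ≥ 2 of the supplied networks.

`first_neighbor_module` extracts all (seed, partner) pairs where the
partner is a direct network neighbor and is itself a seed or candidate;
candidate-flagged pairs are counted per pair, so a partner interacting
with two seeds counts twice. On the packaged high-risk-gene fixture this
count is 13.

## Variant filtering

The seven predicates form an unordered conjunction; the attrition report
counts, per predicate *alone*, how many input records it rejects, so the
numbers are order-independent. Documented edge-case conventions:

- A missing population MAF passes (absence from a database implies the
  allele is at least as rare as anything recorded there).
- A missing deleteriousness predictor is a non-vote, never counted as
  damaging; non-missense classes pass the deleteriousness gate
  unconditionally. The vote threshold is configurable (`min_votes=2` by
  default; `min_votes=1` expresses the looser tolerated-calls-with-high-
  CADD behaviour seen in practice).
- A missing ABHet passes the balance bounds (the statistic is only
  defined for heterozygous calls).
- The highly-variable-gene blacklist is user-supplied; there is no
  canonical list.

Input is an annotated TSV, one row per variant × family, `.` for
missing. VCF ingestion is deliberately out of scope: the annotations
needed here (population MAFs, ensemble predictor calls, in-house counts,
per-family carrier tallies) live in heterogeneous INFO conventions.

## Synthetic benchmarks

The generator emulates the *structure* of a familial rare-variant study:

- **Network**: preferential attachment (1000 nodes, attachment 2 by
  default) — connected by construction, heavy-tailed degrees. Chosen
  over duplication-divergence for simplicity; the generator is
  pluggable.
- **Seeds**: 20 genes grown by random BFS, so the "disease module" is
  connected.
- **Candidates**: 15 true candidates within 2 hops of a seed, 50 decoys
  strictly farther, verified by multi-source BFS.
- **Families**: 27 families with 3-5 sequenced cases each (~105
  patients), one passing variant per candidate gene in one family
  (private mutations), plus ~200 background records each designed to
  fail exactly one named filter.

Scale mirrors a realistic single-study desk analysis, so the full test
suite runs in about a minute. Benchmarks at this scale show: held-out
seed genes rank in the top 5% of candidates in ≥ 90% of replicates;
true-vs-decoy AUROC of the adjusted score ≈ 0.94.

What passing these benchmarks does **not** show: robustness to the
incompleteness and ascertainment bias of real interactomes (synthetic
decoys are topologically *clean* negatives), to annotation error in real
variant tables, or to misspecified seed lists. Carrier counts are drawn
directly rather than transmitted through pedigrees, so cosegregation is
emulated, not simulated.

## Determinism

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); the pipeline derives per-stage seeds from
the configured `rng_seed`, and identical configurations produce
byte-identical outputs (verified by checksum in the test suite).
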