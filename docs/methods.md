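# Methods

This note documents the models implemented in `marshweb`, the
numerical choices behind them, what the synthetic generator does and
does not emulate, and the package's known limitations.

## The food-web object and its conventions

A web is a labelled square binary matrix with one fixed orientation:
`A[i, j] = 1` means species *i* (consumer) eats species *j* (resource).
Every downstream module depends on this single convention; the loader
exposes a `transpose` flag for files encoded the other way round, since
deposited matrices do not always state their orientation. Diagonal
entries (cannibalism) are legal, count once in `L_o`, and contribute to
both a species' generality and its vulnerability. Blank body cells in
matrix files are read as 0 because spreadsheet exports routinely omit
zeros. Labels are case-sensitive exact strings.

## Web statistics and degree distributions

`S`, `S²`, `L_o`, `d = L_o/S` and `C = L_o/S²` are exact integer/rational
computations rendered as floats. The degree of a species is
`k = G + V` — feeding links counted regardless of direction, so a
cannibal's self-link appears in both terms. The cumulative distribution
`P(k)` (fraction of species with ≥ k links) is evaluated on the
distinct observed `k` values, which are also the regression
observations for model fitting: the plotted cumulative curve is the
object the three candidate shapes describe.

Fitting is by nonlinear least squares (`scipy.optimize.curve_fit`) with
a log-linear warm start for `γ` and `k_x` initialised at `max(k)`; the
amplitude and all shape parameters are constrained non-negative. The
non-negativity constraint on the truncated power-law's `γ` matters: an
unconstrained fit happily uses a *rising* power `k^{+γ}` against the
exponential cutoff to chase sampling noise in the head of the curve,
which is outside the decaying-distribution family the models are meant
to represent. Models are ranked by

    AICc = n ln(RSS/n) + 2K + 2K(K+1)/(n − K − 1),

where `K` counts shape parameters plus one for the residual variance.
Because the truncated power law nests the exponential, a strict
first-place criterion misclassifies true-exponential data at roughly
the χ² error rate; following the usual information-theoretic support
convention, the package's power checks count a model as selected when
it ranks first or lies within 2 AICc of first. Maximum-likelihood
discrete power-law fitting is deliberately out of scope.

## Nestedness temperature and the Ce null

Temperature follows the classic packed-matrix geometry. Rows and
columns are sorted by marginal totals (descending); ties are broken by
presence-weighted marginals of the other axis and then by the line's
pattern, which makes `T` invariant to the input ordering of species.
The packed matrix maps onto the unit square; the isocline of perfect
nestedness at fill `φ` is

    y(x) = 1 − (1 − (1 − x)^p)^{1/p},

with `p` solved (Gauss–Legendre area + Brent root) so the enclosed area
equals `φ` (`p = 1` is the anti-diagonal at fill 0.5). An absence on
the filled side or a presence on the empty side is unexpected and is
charged `(d/D)²`, the squared distance to the isocline along the cell's
45° diagonal relative to that diagonal's full length (found by a
vectorised bisection over all cells at once). `T` is the mean charge
over all cells scaled by the conventional maximum 0.04145 onto
[0, 100]; all-zero and all-one matrices are defined to `T = 0` with a
warning. Food webs are unipartite, but the matrix is scored exactly as
the consumer × resource incidence it is.

The Ce null fills cell `(i, j)` independently with probability
`(f_rowᵢ + f_colⱼ)/2` from the observed row/column fills. Default
ensemble size is 1000; the tail probability uses the pseudo-count form
`p = (1 + #{T_null ≤ T_obs})/(R + 1)`, and relative nestedness is
`n* = (N − N̄)/N̄` with `N = (100 − T)/100`. Because the null
re-estimates marginal fills from each observed matrix, the procedure
carries a small plug-in bias: on matrices generated from the Ce model
itself, p-values are near-uniform (KS ≈ 0.12 at 30 × 30) but drift
further from uniform as the matrix shrinks. Swap (fixed-marginal)
nulls and NODF are not implemented.

## Centrality and core/periphery

All four positional metrics are computed on the symmetrised undirected
web — direction is kept only in G and V. Eigenvector centrality is the
leading eigenvector by power iteration (tolerance 1e-10) of the
symmetrised adjacency shifted by the maximum degree; the shift leaves
eigenvectors unchanged while breaking the ±λ tie of bipartite-like
graphs. Scores are scaled so the maximum is exactly 1. Betweenness is
Brandes' algorithm with fractional credit over tied geodesics, reported
as raw pair counts (endpoints excluded, no ×2). Closeness is
`(n − 1)/Σ distances`; on a disconnected web it is computed within
components and the result flagged. These conventions are fixed and
documented rather than matched to any particular software's output —
published ranges from other tools depend on normalisation choices that
are not recoverable.

Coreness fits the continuous core/periphery model by MINRES: minimise
`Σ_{i≠j} (A_{ij} − cᵢcⱼ)²` over non-negative `c`, ignoring the
diagonal. Updates are cyclic coordinate descent,
`cᵢ ← Σ_{j≠i} A_{ij}cⱼ / Σ_{j≠i} cⱼ²`, each being the exact
non-negative minimiser, so the objective never increases. The start is
the (scaled) degree vector, which is deterministic and already ordered
roughly core-outwards. The reported `fit` is the Pearson correlation
between the off-diagonal adjacency and the fitted pattern.

## The group (block) model

For a partition into `g` groups, each ordered block `(k, l)` has
`N_kl = n_k n_l` potential links (self-cells included, consistent with
`S²` connectance) and MLE `p_kl = L_kl/N_kl`; the log-likelihood is the
sum of Bernoulli block terms with `0·ln 0 = 0`. AIC uses `n_params = g²`
(the block matrix only); an alternative convention adding `S`
assignment terms sits behind `param_convention="g2+assign"` because the
convention behind published minimum-AIC values is not always stated.

The partition search is simulated annealing over single-species moves
(moves that would empty a group are rejected), Metropolis acceptance on
ΔAIC, geometric cooling (factor 0.995 per proposal), initial
temperature calibrated so the mean uphill move from the initial state
accepts with probability ~0.5, default `max(3000, 60·S)` proposals and
10 restarts, followed by a best-improvement descent to a local optimum
(the temperature-zero limit of the same move set). Block counts are
maintained incrementally (O(S + g²) per proposal). All randomness is
`random_state`-reproducible.

Model-selection behaviour worth knowing: because the annealed MLE can
always carve partitions out of binomial noise, the AIC-optimal `g` for
a *structureless* web of moderate size is not 1 — refinement keeps
paying until blocks are small. The reliable signatures of real modular
structure are (i) recovery of a planted partition (adjusted Rand index
≈ 1 well into `p_in/p_out` contrast), and (ii) an AIC improvement over
`g = 1` that dwarfs the improvement obtainable on a density-matched
random web. The test suite asserts both; it does not assert that a
random web yields `g = 1`.

## Parasite overlay

A parasite record is an ordered list of life stages, each with a set of
suitable hosts and a transmission mode (`trophic`, `direct`, `vector`)
describing how the parasite reaches that stage. Free-living stages use
the reserved pseudo-host `environment`, present in every web. The
viability rule is the strict reading: every stage needs a present host
AND every trophic hand-off needs at least one observed feeding link
from a next-stage host to a current-stage host
(`require_trophic_support=False` relaxes to presence-only, since the
looser reading is also defensible). Transitions with a free-living side
are supported by presence alone. A parasite found in a predator implies
the predator eats the intermediate host: `infer_trophic_links` adds
those links (never removes, idempotent) with per-link provenance.
Richness counts each viable parasite once per host, regardless of how
many stages use that host. Abundance/intensity and parasite sub-webs
are out of scope.

## Diversity models

Nine predictors per host: eigenvector, betweenness, closeness, degree,
group membership, coreness, marsh diversity (the `S` of the host's
web), generality and vulnerability; the response is viable-parasite
richness. Group levels are web-qualified ("group 3" of different webs
are unrelated categories) and one-hot encoded for the split search
because sklearn's CART has no categorical subset search; the one-hot
importances are summed back into a single group predictor, so reported
importances always cover exactly the nine predictors. Missing
predictors are hard errors, not NAs — surrogate splits are therefore
disabled by construction.

The regression tree is CART with squared-error loss; the
cost-complexity path is computed on the full tree and the pruning
strength chosen by 10-fold cross-validation with the 1-SE rule
(smallest tree within one standard error of the CV minimum; a
`rule="min"` flag selects the CV minimum instead). `pseudo_r2` is the
training `1 − SSE/SST`; a constant response yields a stump with
`pseudo_r2 = 0`. The forest is 1000 bootstrap trees with
`mtry = ⌈9/3⌉ = 3`; `pseudo_r2` is the out-of-bag `1 − MSE/Var(y)`.
Permutation importance is computed the classic way — per tree, each
predictor block is shuffled among that tree's out-of-bag rows and the
MSE increase averaged over trees; the per-tree bootstrap indices are
reconstructed from each tree's `random_state` exactly as the installed
sklearn draws them, and the test suite validates the reconstruction by
reproducing the forest's own OOB predictions bit-for-bit. Mean decrease
in node impurity is reported as the second importance measure.

## The synthetic generator

`generate_web` plants two structures at once: `n_groups` blocks with
within/between link probabilities `p_in/p_out`, and a degree hierarchy
`w_i ∝ rank^{−λ}` multiplying both endpoints' propensities. Raw
probabilities are rescaled after clipping so the expected fill stays at
the block design's value regardless of λ (otherwise a strong hierarchy
starves the web of links). Defaults — S = 80, 4 groups, `p_in = 0.30`,
`p_out = 0.05` (fill ≈ 0.11), λ = 1 — match the magnitudes of real
brackish-marsh webs: 70–125 species, connectance 0.08–0.13,
significantly nested with positive `n*`. λ = 0 gives a blocked
Erdős–Rényi web; `n*` increases with λ at constant fill.

`generate_parasites` draws each parasite's stage count from a
distribution over {1, 2, 3} (default 0.2/0.5/0.3, mostly complex
cycles), then builds host chains along existing consumer→resource
links: the next host is sampled among the predators of the current host
with weight `(eigenvector centrality)^β` (a flag switches the bias to
degree). Three chains per parasite give each stage a small suitable-host
set. Every generated parasite passes the strict viability filter by
construction. Defaults: 25 parasites, β = 2.

What the generator does *not* emulate: body-size constraints, trophic
levels and the near-interval diet structure of real webs, basal/consumer
asymmetry (any species can be eaten), parasite host specificity
phylogenetics, and abundance. Passing tests therefore demonstrate that
the estimators recover structure *of the planted kinds* at realistic
scales — not that real marsh webs have that structure.

`recovery_experiment` is the end-to-end power check: can the pipeline
tell β = 3 from β = 0? Its webs default to λ = 0 because a planted
degree hierarchy makes every centrality collinear with diet breadth and
would confound the placement bias under test; the group predictor uses
the planted labels (annealing per run adds cost, not information, to
this question). One caveat is intrinsic and worth stating: even at
β = 0 the response carries some positional signal, because chains ride
feeding links and well-connected species mechanically host more of
them. The baseline is therefore compared against the biased condition
(top-2 importance rates ~0.5 vs ~0.9 over 20 seeds), not against zero.

## Pipeline, seeds, determinism

`run_pipeline` drives all stages from one config (YAML or constructed);
every stochastic stage derives its seed from the master seed through
named substreams (`SeedSequence` over a CRC of the stage name), so runs
are byte-identical given the config and adding stages does not disturb
existing streams. The manifest records versions, the seed, input
checksums and per-stage status; a failed stage keeps earlier outputs
and marks the failure.

## Problem sizes used in the checks

The bundled checks run on synthetic webs of 20–122 species: planted
partition recovery at 60 species (3 blocks, `p_in = 0.4`,
`p_out = 0.03`), the group-count scan at 24 species (where the AIC
penalty can dominate noise refinement), null-uniformity at 30 × 30 with
200 observed draws × 100 nulls, degree-model power at 50 species × 30
replicates, and the recovery experiment at 80 species × 20 seeds per β.
These sizes are chosen so each property is measured where it is
statistically meaningful while the whole suite stays quick to run.

## Known limitations

* Temperature constants follow the published geometry but no two
  temperature implementations agree exactly; cross-software comparisons
  of `T` (and hence `n*`) carry a few points of algorithmic slack.
* AIC-based group-count selection overfits structureless noise (see
  above); treat `best_g` on real webs as a descriptive summary, not an
  inference that exactly that many compartments exist.
* Least-squares fits to cumulative degree distributions have correlated
  residuals; the AICc ranking is the conventional tool, not a
  calibrated hypothesis test.
* The viability filter is static presence/absence; seasonal turnover
  and abundance thresholds are not modelled.
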