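# Methods

This note documents the models, algorithms and numerical choices behind
`dtnet`, the assumptions they make, and what the synthetic test networks
do and do not establish about real data.

## The network model

Interactions are modeled as a directed graph *G = (V, E)*: each edge runs
from a drug to a macromolecule it binds with a therapeutic or adverse
effect.  Only *target*-category partners are admitted from DrugBank-style
sources; carriers, transporters and enzymes are excluded because the drug
does not alter their function the way it alters a pharmacological
target's.  "Approved" is operationalized as the drug's group list
containing the token `approved` (case-insensitive) — the only
machine-readable proxy for regulatory approval in such exports; a drug
whose groups are e.g. `approved; withdrawn` is kept.  Targets of every
organism are retained (isolated components in real data are dominated by
bacterial and viral targets), and self-loops are kept unless explicitly
dropped.

Node identity is the canonicalized display name (trimmed, case-folded).
With dual-role merging on (the default), a drug and a target with the same
canonical name become one node carrying both roles.  The matcher is
deliberately conservative — exact canonical-name equality — because no
cross-namespace mapping between drug and target identifiers can be assumed;
anything fuzzier risks false merges, and the merge predicate is the single
place to swap in a better mapping.

## Bipartiteness and connectivity

Two notions of bipartiteness are reported separately.  The operative one
for drug–target networks is *role disjointness*: the network stops being
two-sided as soon as any compound appears on both sides.  The
graph-theoretic one is 2-colorability of the undirected view, checked by
BFS coloring; when it fails an explicit odd-cycle witness is returned.
Role-disjoint drug→target graphs are always 2-colorable; the converse is
not true, which is why both are reported.

Components are *weak* (BFS on the undirected view).  Strong connectivity
would be meaningless here: almost no directed cycles exist, so nearly every
node would be its own strongly connected component.  Component indexing is
deterministic — descending size, ties by smallest member id.

## Degree structure

Degree distributions are computed over nodes with k ≥ 1 (the count of
zero-degree nodes is recorded in the distribution's metadata, since log k
is undefined at 0), optionally restricted to one role's nodes.  The
power-law fit *P(k) = A k^(−γ)* defaults to ordinary least squares of
log P(k) on log k with k_min = 1, with A anchored so the fitted curve
passes through the empirical P at the smallest used degree, and r² of the
log-log regression reported as goodness.  Least squares on the empirical
distribution is the field's historical default and tends to produce the
γ < 2 values reported for drug–target data, whereas discrete MLE on
heavy-tailed samples is typically steeper; the MLE (Clauset-style,
normalized by the Hurwitz zeta ζ(γ, k_min), or a finite sum when a cap is
given, maximized by bounded scalar search on γ ∈ (1, 20]) is therefore
provided as a cross-check and both can be reported side by side.  At
n = 10⁵ zipf samples the MLE recovers γ ∈ {1.5, 2.0, 2.5} within 0.005.

Clustering uses *C_i = 2E_i / (k_i (k_i − 1))* on the undirected view with
C_i = 0 for k_i < 2.  A strictly two-sided graph has no triangles, so mean
C = 0; nonzero clustering in a merged network is attributable entirely to
dual-role compounds.  C(k) is binned by exact degree (no logarithmic
binning).

## Centrality conventions

The direction conventions per metric are explicit parameters; the defaults
were chosen to be the informative ones for a directed drug→target graph:

- **Degree centrality**: k/(n−1) with k in, out or total.
- **Closeness** (default incoming sense): for node v with reachable set
  R(v), the raw value |R(v)| / Σ d is damped by |R(v)|/(n−1)
  (Wasserman–Faust).  On heavily disconnected graphs the unscaled formula
  rewards isolation; the component scaling keeps scores comparable across
  components.  On shallow two-level graphs incoming closeness reduces to
  (almost) the in-degree ranking — visible in the examples, and a real
  property of such networks, not an artifact.
- **Betweenness** (default directed): exact Brandes-style accumulation,
  endpoints excluded, normalized by (n−1)(n−2) (the undirected sense
  visits each unordered pair from both endpoints, which is equivalent to
  the usual 2/((n−1)(n−2)) factor on unordered-pair sums).  In the
  directed sense, only dual-role compounds can be interior vertices of any
  shortest path, so the betweenness ranking is a ranking of dual-role
  nodes — a structural fact worth knowing before interpreting it.
  Correctness is defined against explicit enumeration of all shortest
  paths, and the test suite enforces equality on hundreds of random small
  graphs.
- **Eigenvector** centrality runs on the undirected adjacency B of one
  connected component (default: the giant component; other nodes score 0),
  from the uniform positive vector, normalizing to unit Euclidean norm each
  step, stopping when the max-norm change drops below 10⁻¹⁰ (default) or
  10⁶ iterations.  The iteration actually multiplies by B + I: on a
  bipartite component the ±λ eigenvalue pair of B ties in magnitude and
  plain iteration oscillates forever, while the shift makes λ + 1 strictly
  dominant and leaves the Perron vector unchanged.  The reported λ is the
  converged Rayleigh quotient minus one, and the residual ‖Bx − λx‖∞ is
  below 10⁻⁶ at convergence.

Rankings break value ties lexicographically by node id, so top-k tables
are stable across runs.

## Community detection

Modularity is computed on the undirected, unweighted view:
*Q = Σ_c [e_c/m − r (d_c/2m)²]*, where the resolution r multiplies the
null-model term.  The optimizer is the classic two-phase multilevel
scheme: every node starts in its own community; nodes are visited in a
seeded random permutation and moved to the neighboring community with the
highest positive gain (ties to the smallest community label); when a full
pass makes no move, communities are aggregated into super-nodes (intra
weights become self-loops) and the procedure repeats until Q cannot
increase.  Q is recomputed on the original graph after every level and
asserted non-decreasing.  Isolated nodes stay singletons.  A single
seeded run is the default; the seed is part of the result object.

Like every Louvain implementation, the optimizer can stop in a local
optimum.  On small community-structured graphs (cliques joined by sparse
bridges, dense 8-node random graphs) it reaches the exhaustive-search
optimum in ≥ 95% of seeded runs — the same rate as the igraph reference
implementation.  On degenerate landscapes with near-tied optima (paths,
cycles, very sparse random graphs) both this and the reference
implementation split between two Q values a few percent apart; that is an
algorithmic property of greedy modularity ascent, not an implementation
defect.

## Coregulation and the covering-drug set

Two drugs are coregulated when both are in-neighbors of at least one
common target; the projection's edge weight is the number of shared
targets and a drug's partner count is its degree in the projection.

The covering-set reduction starts from all drug-role nodes of a (weakly
connected) component and performs a fixed number of random draws
(default 100 000, seeded): draw a drug uniformly from the current set,
remove it iff every target would still keep a retained in-neighbor, else
keep it and consume the iteration.  Because a finite random phase can
provably leave removable drugs behind, a deterministic final sweep
(each survivor tried once, in seeded random order) is applied by default,
after which the result is *minimal*: removing any single retained drug
uncovers some target.  The sweep can be disabled to replicate the bare
randomized procedure.  Dual-role nodes participate on both sides: as
removable drugs and as coverage-requiring targets.  The retained size is
a heuristic upper bound on the minimum dominating set; the tests verify
it never undercuts the exact optimum found by exhaustive search on small
instances.  Across seeds the retained size varies by a few percent; a
distribution over seeds, not a single number, is the meaningful summary.

## Enrichment

Over-representation of a query node set against an annotation table uses
the upper-tail hypergeometric probability P(X ≥ hits) with the background
universe as an explicit, required input (results are not interpretable
without stating the universe), and Benjamini–Hochberg step-up adjustment
by default, mirroring the p < 0.05 reporting convention of annotation
tools.  No annotation corpus is bundled; users supply term→node tables.

## Synthetic generator

The generator emulates the statistical shape of curated drug–target
snapshots: truncated discrete power-law out-degrees for drugs and
in-degrees for targets (inverse-CDF sampling on [1, k_max]), bipartite
stub matching (the larger side's stub total is trimmed by decrementing
random stubs, never below 1; stubs are randomly paired; parallel edges
collapse), promotion of a few random targets to dual-role drugs with 1–3
out-edges, and a fringe of isolated drug–target pairs.  Identical
parameters and seed give a byte-identical table.

`paper_scale_preset` fixes the study-scale conditions: 2186 drugs, 2689
targets, γ_out = 1.47, γ_in = 1.6, k_max = 30, 13 dual-role compounds, 94
isolated pairs.  The cap k_max = 30 was chosen analytically so the two
sides' expected stub totals nearly coincide (≈ 9.6k vs ≈ 10.2k) at the
target edge scale of ≈ 9.3k.  Realized networks land within ±10% of the
nominal counts with the giant component near 90% of nodes.

What the generator does *not* emulate, and hence what passing tests do not
show about real data: planted community structure (a stub-matched
configuration model is maximally random given its margins, so its
modularity ≈ 0.5 is far below the ≈ 0.8 of curated data, and community
composition is meaningless); extreme hubs beyond k_max (real promiscuous
kinase inhibitors reach hundreds of targets); correlated drug families
sharing target panels (which drive the very high coregulation counts of
real antipsychotics); and any annotation semantics.  Stub collapse also
slightly deflates realized hub degrees relative to the sampled sequence,
which biases the realized-degree exponent a few hundredths above the
sampling exponent — parameter-recovery checks therefore use a tolerance
(±0.15) wider than pure fit noise.

## Problem sizes and tolerances in the test suite

Oracle-equivalence tests run on hundreds of random graphs of ≤ 15 nodes,
where exhaustive enumeration (all shortest paths, all set partitions, all
2-colorings, all drug subsets) is exact and fast.  Parameter recovery uses
50 generator seeds at 5000 drugs.  Pipeline smoke tests use a ~140-node
synthetic network; preset-scale checks (counts, components, community
statistics, the reduction) run at the full ≈ 5000-node scale, where a
complete analysis takes a couple of seconds excluding all-pairs
centralities and under a minute with them.  Numerical tolerances:
eigenvector vs dense eigendecomposition 10⁻⁸; Brandes vs enumeration and
modularity vs closed form 10⁻¹²; MLE exponent bias 0.05 at n = 10⁵;
least-squares recovery of an exact power law 10⁻⁹.
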