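# Methods

## Scope and model of the analysis

The pipeline treats a herbal medicine as a set of compounds, each linked
to protein targets identified by gene symbol, and a disease as a set of
implicated genes. All graphs are undirected, unweighted simple graphs
over string identifiers: protein interaction sources do not provide
directions that any downstream statistic here would use, and self-loops
or parallel edges carry no meaning for centrality or module density.
Gene identity is canonicalized by trimming and uppercasing, with an
optional user-supplied alias table followed to a fixed point; full
database-backed identifier mapping is intentionally out of scope, so a
study that needs it should pre-map its inputs.

## Activity screen

A compound is active when OB ≥ ob_min and DL ≥ dl_min, with defaults
30 (%) and 0.18 (dimensionless), read inclusively — several reference
compounds (quinizarin at DL 0.19, aurantio-obtusin at OB 31.55) sit near
the boundary, and the inclusive reading is the one under which the
packaged 13-compound table passes intact. A strict (`inclusive=False`)
variant is exposed. Active compounds with no known targets are kept and
reported; they simply contribute nothing downstream.

## Network construction

The compound–target network is bipartite; compounds and genes share one
node namespace, and a collision is an error rather than a silent merge.
Disease and compound PPI subnetworks are induced on the seed gene sets
*without* neighbour expansion — only background edges with both
endpoints among the seeds survive — and nodes left without any
connection are dropped by default. The merged network is the induced
subgraph on the union of both seed sets, with provenance labels
(compound / disease / shared) on every retained node. Seed-only
induction is a deliberate choice: it keeps the merged network a function
of the user's inputs alone, rather than of an interactome-expansion
policy.

## Six-metric key-target screen

Definitions (v a node, N(v) its neighbours, d_v its degree):

- DC(v) = d_v.
- CC(v) = (|C_v| − 1) / Σ_{u∈C_v} d(v,u), distances by unweighted BFS
  within v's component C_v; 0 for isolated nodes. On disconnected
  graphs this never mixes components; means are still taken over all
  nodes, because the screen is applied to the (isolate-free) graph it
  is computed on.
- BC(v) = Σ_{{s,t}, s≠v≠t} σ_st(v)/σ_st, by Brandes' accumulation,
  unnormalized, each unordered pair counted once. Normalization is a
  reporting option only; it cannot change the screen, which compares
  each metric only to its own mean (asserted as a test).
- EC: principal eigenvector of the adjacency matrix, entries
  nonnegative, L2-normalized. Computed by power iteration on A + I
  (same eigenvectors; the shift makes the operator primitive on
  connected graphs so the iteration cannot oscillate on bipartite
  spectra), uniform start, max-norm tolerance 1e-10, cap 10,000
  iterations; hitting the cap raises a ConvergenceWarning and flags the
  table rather than failing silently.
- LAC(v) = 2·e(N(v))/|N(v)|, where e(N(v)) counts edges among the
  neighbours; 0 for isolated nodes.
- NC(v) = Σ_{u∈N(v)} ECC(u,v), ECC(u,v) = z_uv / min(d_u−1, d_v−1)
  with z_uv the common-neighbour count and ECC = 0 when the denominator
  vanishes (the usual convention for degree-1 endpoints).

A node is a key target when its value strictly exceeds the
network-wide arithmetic mean on all six metrics; `strict=False` relaxes
to ≥. Strict is the default because the rule is stated as "greater than
the mean", and it has the right degenerate behaviour: on any
vertex-transitive graph (complete graphs, and the LAC-degenerate star)
the key set is empty. The screen runs once; no iterative re-screening.

## Dense-module detection

The MCODE scheme with the published tool defaults (vertex-weight
percentage 0.2, haircut on, fluff off, minimum size 3): node weight =
k × density of the highest k-core of the closed neighbourhood N[v];
seeds in decreasing weight among unassigned nodes (ties by id);
breadth-first expansion admits neighbours with weight ≥ (1 − vwp) ×
seed weight; each node joins at most one module, and nodes consumed by
a discarded (sub-minimum) module stay consumed. Haircut iteratively
removes members with fewer than two in-module connections. Density uses
the simple-graph formula 2E/(n(n−1)) — the only definition under which
a 6-node module missing a single edge scores (14/15)·6 = 5.60 — and the
module score is density × size, so score ≤ n with equality exactly for
cliques. All tie-breaks are lexicographic for reproducibility.

## Over-representation analysis

The statistic is the hypergeometric upper tail P(X ≥ k) for k of n
query genes falling in a K-gene term within an M-gene universe, summed
in log space (log-gamma binomials + log-sum-exp) for stability; tests
verify it against exact big-integer rationals to 1e-10 relative. The
default universe is the union of annotated genes in the collection — a
remote service's background is not knowable offline — with an explicit
universe supported. DAVID's conservative EASE variant (tail at
max(k−1, 0)) is available but not the default, because the plain tail
is exactly testable and the original service's setting is not
documented. Selection uses raw p < 0.05 (strict) and top-k truncation
(10 for GO-style, 20 for pathway-style collections);
Benjamini–Hochberg adjustment (scipy's step-up implementation) is
computed on request and reported alongside, never used for selection
unless configured.

The qPCR statistic is fold change = 2^−ΔΔCt with
ΔCt = Ct(target) − Ct(reference) and ΔΔCt = ΔCt(treated) −
ΔCt(control); replicate Cts are averaged per group. Error propagation
across replicates is out of scope.

## Synthetic data

The generator emulates the statistical features of the real inputs that
the downstream stages actually depend on, with ground truth recorded:

- **Compounds** (default n = 40): OB ~ Normal(32, 12²) truncated at 0
  — centred near the activity threshold so the screen genuinely
  partitions the table — and DL ~ Beta(2, 5), whose mass straddles
  0.18. The true active set is computed from the drawn values.
- **Interactome** (default 300 genes): preferential attachment with
  m = 2 edges per new node, giving the heavy-tailed degree distribution
  of real PPI networks — in a uniform random graph essentially nothing
  passes all six strict above-mean tests, so the screen would be
  untestable. Five planted hubs receive 40 extra uniform-random edges
  each (comparable, as a fraction of the network, to the most-connected
  proteins in curated interactomes). One planted module of 6 fresh
  genes is wired to density 14/15 internally (mirroring the anchor
  cluster score 5.60) with exactly one edge per member into the
  backbone.
- **Annotations** (default 50 terms): one planted term = the designated
  key genes padded to 20, the rest uniform draws of size 10–40 over the
  gene namespace; universe = the whole namespace.
- **Study bundle**: the disease gene list (default 60 genes) contains
  the planted module and hubs (planted structures are
  disease-associated by construction), a 35 % overlap drawn from the
  compound targets, and random padding. Compound→target counts follow a
  Zipf(1.8) law capped at 40.

All sub-generators draw from `default_rng([seed, stream])` with fixed
per-generator stream ids, so outputs are byte-identical per seed and
independent across stages. What the generator does *not* emulate: real
gene nomenclature, literature-biased study of popular proteins,
interactome false-positive structure, or correlated annotation terms
(GO ancestry). Passing the recovery tests therefore demonstrates that
the algorithms detect the planted signal under realistic degree
heterogeneity — not that any particular biological database would yield
the same target lists.

## Problem sizes and numerical choices

Oracle suites compare every metric against exhaustive or dense-algebra
re-computations on graphs of ≤ 8 nodes (where path enumeration and
eigendecomposition are trivially trustworthy), 200+ graphs per suite;
recovery experiments use 20 seeds at the default configuration
(300-gene interactomes), which keeps the whole suite under a minute on
one core while leaving the planted-structure statistics stable.
Eigenvector comparisons are restricted to connected graphs, where the
principal eigenvector is unique up to sign. Floating-point comparisons
use absolute tolerances of 1e-12 for combinatorial quantities, 1e-9 for
accumulated betweenness, and 1e-8 for iteratively computed eigenvector
entries (tolerance 1e-10 in the iteration itself).

## Known limitations

- No identifier mapping beyond uppercase/trim + alias table; symbol
  synonymy must be resolved upstream.
- Induction is seed-only; interactome-expansion workflows (adding
  first-neighbour interactors before induction) are not emulated.
- MCODE "fluff" is implemented in a node-disjoint form (a fluffed node
  is consumed), so overlapping-module output is never produced.
- Enrichment ignores term topology: GO parent/child propagation and
  term clustering are out of scope.
- The screen's means are computed on the isolate-free graph that is
  screened; screening a graph with isolates retained will shift CC/DC
  means accordingly.
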