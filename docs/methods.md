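# Methods

This note documents the models and procedures implemented in `scgeom`, the
parameters that matter, the numerical choices, what the synthetic generators
emulate, and the package's known limitations.

## Preprocessing

Raw counts are scaled per cell to a common total (`target_sum`, default 1e4)
and log1p-transformed. Highly variable genes are ranked by the variance of the
log-normalized values — the simplest deterministic dispersion statistic; more
elaborate mean-variance-trend flavors exist, but the downstream topology is
insensitive to the flavor at the scales this package targets. PCA scores are
mean-centered SVD scores with each component's sign fixed so that its
largest-absolute loading is positive, which makes embeddings bit-stable across
runs. The cell graph connects each cell to its `k` nearest neighbors (default
15; Euclidean, cosine or correlation distances) with **union** symmetrization —
an edge is kept if either endpoint selects the other — so every node has degree
at least k and thin bridges between dense regions are preserved. Distance ties
break by lower node index.

## Ollivier–Ricci curvature

Edge curvature is 1 − W₁(m_i, m_j)/d(i, j) with m_v the α-lazy neighborhood
measure (α = 0.5 by default: half the mass stays on the cell, the rest spreads
uniformly over its graph neighbors). The transport problem is solved **exactly**
as a linear program (HiGHS) after cancelling the mass the two measures share in
place — W₁(m_i, m_j) = W₁((m_i − m_j)₊, (m_j − m_i)₊) — which preserves
exactness and roughly halves the solve time on kNN graphs, whose adjacent
neighborhoods overlap heavily. Entropic regularization was deliberately
avoided: the supports are tiny (≤ 2k + 2 nodes) and exactness makes the solver
directly comparable to the independent min-cost-flow oracle
(`orc_edge_oracle`, networkx network-simplex on integer-scaled masses), which
the test suite runs on random graphs.

The ground metric is the shortest-path distance on the graph; `hop` (unweighted)
is the default, `length` (embedding distances on edges) is available. Node
curvature is the **sum** of incident edge curvatures (a scalar-curvature
analogy); a degree-normalized mean is available.

Neighborhood scale matters when hunting transition cells: the kNN neighborhoods
must be large enough to couple a sparse corridor to the states it connects. At
the bridge-fixture geometry shipped here (two 120-cell states, one 60-cell
corridor), k = 30 resolves the corridor — neighborhoods of corridor cells reach
the cores, corridor curvature drops — while at k = 15 the corridor is its own
well-connected one-dimensional community and hop curvature does not single it
out. The transition analyses in the examples and the acceptance script
therefore use k = 30; the preprocessing default stays k = 15.

## Persistent homology

Filtrations are explicit simplex lists sorted by (value, dimension, vertex
tuple), built to dimension `max_dim + 1` so homology in dimension `max_dim`
(default 1) is correct. Persistence uses standard left-to-right column
reduction over Z/2 with columns as integer bitmasks and a pivot table; an
intentionally naive reduction (`persistence_oracle`, Python sets, linear pivot
scans) provides an independent code path for validation. Zero-persistence
pairs are dropped everywhere — they carry no information and destabilize
entropy. Infinite bars are kept in stored diagrams and capped at δ_max only
inside featurization and Wasserstein computations.

**Gene-network filtrations.** Edge-weighted networks (CSNs) are thresholded
from the largest edge weight downwards and re-expressed as an ascending
filtration in δ_max − δ; only cliques of the network become simplices, each
entering at δ_max minus its smallest edge weight. Vertices enter with their
first (largest-weight) incident edge; isolated vertices enter at δ_max, so they
contribute only a trivial bar. Adding a constant to all weights shifts δ_max by
the same constant and leaves the transformed diagram unchanged (tested).
Node-weighted prior networks use the vertex-based clique filtration: a clique
enters at δ_max minus its smallest node weight.

**Local and relative persistence.** Local topology of a cell is the VR
persistence of the cell plus its `k_local` (default 30) nearest neighbors in
the embedding, at ambient Euclidean distances, capped at the neighborhood
diameter. Relative persistence of the dataset modulo a cell's `l_size`-cell
neighborhood (default 10) is computed by coning the full subcomplex on those
vertices to a virtual apex entering at the minimum filtration value — homotopy
equivalent to the quotient — and removing the apex component's essential H0
bar; a direct reduction of the quotient chain complex serves as the oracle.
The global filtration is truncated at the 90th percentile of pairwise distances
to bound complex size (configurable). The cell's importance score sums, over
dimensions, the Wasserstein distance between the capped relative and regular
diagrams.

**Diagram distance.** Order-q Wasserstein (default q = 1; the order is not
canonical and is exposed) with the L∞ ground metric on the plane and diagonal
projections as slack, solved exactly by the Hungarian algorithm on the
augmented cost matrix. Infinite deaths must be capped first; the functions
refuse silently guessing a cap.

## Featurization

Total persistence Σ (min(d, δ_max) − b), persistence entropy
−Σ (l/L) log₂(l/L) in bits (single bar → 0; empty diagram → 0 with a warning,
keeping feature tables total), and Betti curves on a shared grid (100 even
values on [0, δ_max]) with the half-open convention: a bar [b, d) counts at
grid value t iff b ≤ t < d. The entropy is scale-invariant; the Betti curve
integrates (trapezoid) to total persistence for finite bars.

## Cell-specific gene networks

The box statistic ρ_xy = n_xy/n − (n_x/n)(n_y/n) uses symmetric **rank**
windows of `round(box_fraction·n)` cells around cell k's expression of each
gene (greedy two-pointer expansion in rank space, side ties broken by lower
cell index). Rank windows make the statistic invariant under strictly monotone
transforms of either gene. A constant gene yields a degenerate window: ρ = 0
with a warning. Because a cell always lies inside its own boxes, ρ carries a
small positive O(1/n) bias on independent genes; tests therefore compare
against the permutation-null mean, not literal zero.

Edge retention tests ρ against a seeded permutation null (shuffling one gene's
values). Two implementation points matter:

* the null is **simulated on distinct ranks with both windows drawn from
  independent permutations** — simulating only one window against a fixed cell
  set interacts with the index tie-break and inflates the null (this was
  validated against the closed-form 1 + Hypergeometric law);
* ρ is a discrete count, so a plain empirical-quantile cutoff is conservative
  by up to a factor of two; retention instead uses the standard randomized
  tie-break permutation p-value (uniform on the boundary atom, seeded), which
  makes the retention rate on independent genes equal `sig_level` by
  construction. One independent null sample is drawn per cell so that
  different cells' decisions do not share one sample's tail wobble.

Defaults follow the method's convention: box fraction 0.1, significance 0.01,
1000 permutations (the resolution check requires n_perm ≥ 1/sig_level).

## Transition calling and classification

Transition cells are the `round(q·n)` highest-scoring cells (default q = 0.1;
score: local H0 total persistence by default — negated curvature, H1 totals or
relative importance are equally valid choices), ties broken by (score, index);
the rule is invariant under monotone transforms of the score. Flagged cells
split into groups by connected components of the flagged-induced subgraph of
the cell graph, each group is associated to the original clusters by ranked
population overlap, and a modified clustering reassigns flagged cells to new
transition labels.

Classification uses scikit-learn's random forest (5000 trees) or SVM (C = 0.5),
both with class-balanced weights, on gene features, topology features, or their
concatenation, with a seeded stratified split. Metrics are implemented from
their explicit formulas: accuracy; adjusted balanced accuracy = mean per-class
recall − 1/C (0 at chance, 1 − 1/C when perfect; the conventional normalized
form, which rescales to [−…, 1], is available via `adjusted="normalized"` and
equals the plain form divided by 1 − 1/C); macro precision with empty
predicted classes contributing 0; macro recall. Classes are the distinct
ground-truth labels.

## Synthetic study conditions

The generators are pure functions of (parameters, seed) and define the
conditions under which the package's claims are tested:

* **bridge_clusters** — Gaussian state cores (σ = 1) at separation 10 in 2-D,
  corridor cells uniform on the interior 10–90 % of the inter-center segments
  with the same noise. Defaults 2 × 120 cores + 60 bridge cells. Emulates
  stable states with genuine low-density transition corridors.
* **ring / blob** — evenly spaced noisy circle (planted H1: for the clean
  circle the loop is born at the chord spacing 2 sin(π/n) and dies at √3 r)
  versus an isotropic Gaussian cloud.
* **modular_network** — planted-partition gene graph (40 genes, 4 modules,
  p_in = 0.6, p_out = 0.05), connected at these defaults.
* **pluripotency_profiles** — broad profiles (all modules at level 1.0 ± 0.1)
  versus localized profiles (one module at 3.0, background 0.05). Broad
  activation keeps the active network in one piece with cross-module loops;
  localized activation isolates one island — the directions the H0/H1 totals
  measure.
* **topo_signal_classes** — every gene an exactly Uniform(0, 2π) angle in both
  classes (so per-gene means carry no signal); the *loop* class couples genes
  by a wrapped Brownian bridge around the gene ring (step σ = 0.35, strong
  local coupling decaying with ring distance), the *pairs* class couples
  disjoint gene pairs with the same step size, anchored on an arc (half-width
  1.8 rad) around a shared cell state. The arc width balances two leaks that
  plagued simpler designs: fully independent pairs reveal the class through
  the per-cell profile spread alone, while a tightly shared state couples all
  genes and washes out the topology contrast. Near-deterministic local
  coupling is necessary at box fraction 0.1 — the box statistic's per-edge
  detection power was measured at only ~0.3–0.6 for Gaussian correlations of
  0.9 at these sample sizes.
* **nb_counts** — gamma-Poisson counts with a 3× spread of cell size factors,
  to exercise normalization on realistic raw data.

What passing these tests shows — and does not. The fixtures plant idealized
versions of the structures of interest: clean Gaussian states, a single
corridor, exactly modular networks, noiseless marginal matching. Real scRNA-seq
data add dropout, batch structure, library-size artifacts and diffuse cluster
boundaries that the generators deliberately do not model; passing here
establishes correctness and directional behavior of the statistics, not
end-to-end performance on real tissue atlases.

## Problem sizes and cost

Complexes are explicit, so cost is driven by neighborhood size: local
persistence at `k_local = 30` and `max_dim = 1` builds ~5000 simplices per
cell (milliseconds each); exact ORC solves one small LP per edge (~3–10 ms);
the full 300-cell transition analysis takes under a minute on one CPU, and the
acceptance script about a minute end to end. Relative persistence over the
whole dataset is the one global (hence expensive) computation and is off by
default in the feature table; the 90th-percentile distance cap bounds it.

## Limitations

Dense distance matrices and explicit simplex enumeration cap practical sizes
at a few thousand cells (per-cell local computations scale linearly; global
relative persistence does not). Homology is computed over Z/2 up to dimension
`max_dim` (default 1); no zigzag, multiparameter or cohomology optimizations,
no representative cycles. The CSN null assumes tie-free expression within a
gene (guaranteed for continuous values; heavily tied counts make the test
conservative). Forman curvature, Ricci flow and directed graphs are out of
scope.
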