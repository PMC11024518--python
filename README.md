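# scgeom

Geometric and topological signatures of single-cell RNA-seq data: Ollivier–Ricci
curvature and persistent homology of **cell networks** (kNN graphs over a PCA
embedding) and of **per-cell gene networks** (statistical cell-specific networks
and node-weighted prior-knowledge networks), with downstream transition-cell
calling and topology-augmented cell-type classification.

## Who this is for

Analysts of scRNA-seq data who want structure-aware per-cell descriptors that do
not depend on a prior clustering: which cells sit *between* stable expression
states (transition cells), how the gene network activated by each cell is shaped
(a readout of differentiation potential), and whether those shapes help a
classifier tell cell types apart.

## The quantities it computes

**Ollivier–Ricci curvature (ORC).** Each node of the cell graph carries the
measure m_v(α) with mass α on itself and (1−α)/|N(v)| on each neighbor
(default α = 0.5). The curvature of edge (i, j) is

    κ_ij = 1 − W₁(m_i, m_j) / d(i, j),

with W₁ the exact optimal-transport distance under the shortest-path ground
metric. Edges inside dense communities are positively curved; bridges between
communities are not. Node curvature sums the incident edge curvatures.

**Persistent homology.** Filtrations supported:

* Vietoris–Rips of a point cloud (local neighborhoods of each cell, or the
  whole embedding) — a simplex enters at its largest pairwise distance;
* descending edge-weight Rips for edge-weighted gene networks — thresholding
  from δ_max down, re-expressed ascending as δ_max − min edge weight;
* vertex-based clique filtration for node-weighted gene networks — a clique
  enters at δ_max − min node weight.

Persistence is computed by boundary-matrix reduction over Z/2. Relative
persistent homology — the homology of C(K)/C(K ∩ L) for a subcomplex L spanned
by a cell's neighborhood — is computed by coning L to a virtual apex, and the
cell's importance is the Wasserstein distance between the relative and the
regular diagram. Diagrams are summarized by total persistence
Σ min(dᵢ, δ_max) − bᵢ, persistence entropy −Σ (lᵢ/L) log₂(lᵢ/L), and Betti
curves (bar counts over a filtration grid, half-open convention).

**Cell-specific gene networks (CSN).** For cell k and genes x, y, the box
statistic ρ = n_xy/n − (n_x/n)(n_y/n) counts cells falling in both rank-windows
around cell k's expression; edges significant against a seeded permutation null
(box fraction 0.1, significance 0.01 by default) form the cell's network.

**Classification metrics.** Accuracy, adjusted balanced accuracy (mean per-class
recall − 1/C; the normalized variant is available), and macro precision/recall,
with random forest (5000 trees) and SVM (C = 0.5) baselines, both class-weight
balanced.

## Worked example

`python examples/transition_cells.py` — two Gaussian cell states (120 cells
each) joined by a sparse 60-cell corridor; curvature and local topology flag
the corridor without any clustering:

```
mean node curvature: bridge 5.78 vs core 7.79  (one-sided rank test p = 1.8e-16)
mean local H0 total persistence: bridge 25.1 vs core 8.8  (p = 6.1e-33)
transition calls at q = 0.2: 60 cells, 58/60 planted corridor cells recovered
  transition group 0: overlaps [('bridge0', 58), ('core0', 1), ('core1', 1)]
```

Corridor cells have lower curvature (their neighborhoods bridge communities)
and longer local H0 bars (their neighborhoods are sparse and stretched); the
upper-quantile rule on the H0 score recovers 58 of the 60 planted transition
cells, and the flagged group overlaps the planted corridor label.

The other examples print, among else:

* `differentiation_potential.py` — broadly active cells vs module-localized
  cells on a modular gene network: H0 total persistence 1.51 vs 3.40 (lower),
  H1 total persistence 17.63 vs 0.70 (higher), both rank tests p = 3.5e-18 —
  pluripotent-like profiles keep the network in one piece with wide loops.
* `topology_assisted_classification.py` — two classes with identical per-gene
  marginals but different co-activation topology: random-forest accuracy 0.840
  with expression features alone, 0.900 after appending CSN persistence
  features.
* `persistence_basics.py` — a noisy ring's dominant H1 bar [0.250, 1.602)
  against the clean-circle death at √3.

## Command line

A thin CLI mirrors the library:

```bash
scgeom synth --kind bridge_clusters --seed 0 --out fx/
scgeom preprocess --counts counts.csv --format csv --knn 15 --out pp/
scgeom curvature --graph pp/graph.tsv --alpha 0.5 --out curvature.csv
scgeom cell-topology --embedding pp/embedding.csv --k-local 30 --out features.csv
scgeom gene-topology --counts counts.csv --mode csn --n-perm 1000 --out gt/
scgeom transitions --features features.csv --score h0_total_persistence \
    --q 0.1 --graph pp/graph.tsv --out calls.csv
scgeom classify --gene-features g.csv --topo-features t.csv --labels l.csv \
    --model rf --feature-set gene+topo --out report.json
scgeom run --config config.yaml          # end-to-end from a YAML RunConfig
```

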