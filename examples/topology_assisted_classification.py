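"""Topology-augmented cell-type classification.

Two cell classes share every per-gene marginal distribution (no mean
signal) but differ in the topology of their gene-gene co-activation: one
class's dependency graph contains a planted cycle, the other's does not.
Cell-specific gene networks are built per cell (box statistic + seeded
permutation test), featurized by persistence, and appended to the raw
expression features of a random forest (5000 trees, class-balanced).

Runs in a couple of minutes (two 5000-tree forests).
"""

from scipy.stats import mannwhitneyu

from scgeom.downstream import classify
from scgeom.gene_topology import csn_features_table
from scgeom.synthetic import make_topo_signal_classes

X, labels = make_topo_signal_classes(n_cells=300, n_genes=12, seed=0)
tab = csn_features_table(X, box_fraction=0.1, sig_level=0.01, n_perm=1000,
                         seed=0, include_betti=True)
loop = labels == "loop"
h1 = tab["h1_total_persistence"].to_numpy()
p = mannwhitneyu(h1[loop], h1[~loop], alternative="greater").pvalue
print(f"CSN H1 total persistence: loop {h1[loop].mean():.4f} vs pairs "
      f"{h1[~loop].mean():.4f}  (rank test p = {p:.1e})")

topo = tab[[c for c in tab.columns if c != "cell_id"]].to_numpy()
rep_gene, _ = classify(X.values, topo, labels, model="rf",
                       feature_set="gene", split=0.5, seed=0)
rep_both, _ = classify(X.values, topo, labels, model="rf",
                       feature_set="gene+topo", split=0.5, seed=0)
print(f"RF accuracy, gene features only : {rep_gene.accuracy:.3f}")
print(f"RF accuracy, gene + topology    : {rep_both.accuracy:.3f}")
print(f"adjusted balanced accuracy, gene + topology: "
      f"{rep_both.balanced_accuracy_adjusted:.3f}")
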