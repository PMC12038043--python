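"""Bulk-DEG to single-nucleus empirical projection.

Projects the synthetic knockout-vs-control DEG lists onto the cluster
landscape: per-cluster average expression, per-gene z-scores,
dendrogram-cut gene groups (largest k whose smallest group keeps >= 2%
of genes) and the affected-population statistic.
"""

from gonadomics import project
from gonadomics.dataset import build_bundle

bundle = build_bundle(seed=7)
sim = bundle.sim
labels = sim.cells["cluster_label"].to_numpy()

results = project(bundle.bulk_de, sim.rna, labels)
for label, r in results.items():
    fracs = ", ".join(f"{c}={v:.2f}" for c, v in r.affected_fractions.items())
    print(f"{label}-regulated DEGs (n={len(r.z)}): gene groups k="
          f"{r.k_selected}; fraction of genes at z > 1 per cluster: {fracs}")
    print(f"  most affected populations: {r.affected or 'none'}")

print("\nA cluster is 'most affected' when more than 20% of the DEG list "
      "scores z > 1 there (both comparisons strict). The downregulated "
      "list was drawn from progenitor/contractile markers, so c0 and c1 "
      "are called; the upregulated list recovers the germ-cell-like "
      "clusters.")
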