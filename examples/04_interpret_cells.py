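"""Interpret a trained model: cell labels, phenotype tree, cluster validation.

Thresholding the oriented cell scores at 0.5 gives discrete cell labels; a
CART tree fit on the pooled labeled cells expresses the model's decision
surface as marker cutoffs (a data-driven gating strategy); projecting each
sample through the fixed global tree flags its "positive paths" (endotypes);
and an independent K-means check confirms the labeled cells form clusters
present only in positive samples.
"""

import numpy as np

import cellscore as cs
from cellscore.pipeline import train_pipeline

cohort, truth = cs.generate_cohort(
    cs.standard_fixture_config(seed=4, n_pos=6, n_neg=6, cells_per_sample=(1500, 2500)))

config = cs.TrainConfig(mode="reg", epochs=120, n_restarts=3, seed=4)
result, _, _ = train_pipeline(cohort, config, density_kwargs={"max_fit_cells": 8000})
preds = cs.predict(result, cohort)
labels = cs.label_cells(preds, threshold=0.5)

tree = cs.build_global_tree(cohort, labels, max_depth=3, seed=4)
root = tree.nodes[tree.root]
print(f"global tree: root split on {root.marker} at {root.cutoff:.2f} "
      f"({len(tree.leaves())} leaves)")
for leaf in tree.leaves():
    if leaf.predicted_class == 1:
        path = " & ".join(f"{m}{op}{c:.2f}" for m, op, c in tree.path_description(leaf.node_id))
        print(f"  pathogenic phenotype: {path}")

s = cohort.positives()[0]
stats = cs.project_sample_tree(tree, s, labels)
print(f"\n{s.sample_id}: positive paths (endotypes present): {stats['positive_paths']}")

enr = cs.cancer_only_clusters(cohort, labels, k=8, seed=4)
print(f"\nK-means validation: cancer-only clusters {enr.cancer_only_cluster_ids()}, "
      f"Jaccard overlap with cell labels {enr.jaccard_with_labels:.3f}")
print("a Jaccard near 1 means the clustering, which never saw the model, "
      "recovers the same pathogenic cells the network labeled.")

pairs = [("M4", "M5"), ("M6", "M7")]
tables = cs.export_dotplot_data(s, labels, pairs, cohort.panel, tree=tree)
for pair, payload in tables.items():
    frac = payload["table"]["label"].mean()
    print(f"dot-plot table {pair}: {len(payload['table'])} cells, "
          f"{frac:.1%} labeled pathogenic, cutoffs {payload['cutoffs']}")
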