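"""Post-hoc interpretation of per-cell scores.

Cell scores are thresholded into discrete labels; a CART decision tree fit on
the pooled labeled cells turns the network's decision surface into marker
cutoffs a reviewer can read as a gating strategy; per-sample projections of
the global tree preserve the tree layout so samples can be compared path by
path; and an independent K-means check finds clusters present essentially
only in positive samples, validating the labeled cells without using the
model.  Dot-plot exports put labels and cutoffs back into original (inverse-
transformed) marker units for review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.tree import DecisionTreeClassifier

from .cohort import Cohort, SampleRecord
from .model import Predictions
from .panel import MarkerPanel


@dataclass
class CellLabels:
    """Thresholded oriented scores, per sample."""

    labels: Dict[str, np.ndarray]
    threshold: float

    def pooled(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.concatenate([self.labels[i] for i in sample_ids])


def label_cells(predictions: Predictions, threshold: float = 0.5) -> CellLabels:
    """label = 1 iff oriented score >= threshold (ties label positive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    labels = {
        sid: (sc >= threshold).astype(int)
        for sid, sc in predictions.oriented_scores.items()
    }
    return CellLabels(labels=labels, threshold=threshold)


@dataclass
class TreeNode:
    node_id: int
    marker: Optional[str] = None  # None at leaves
    cutoff: Optional[float] = None  # transformed units
    cutoff_raw: Optional[float] = None  # inverse-transformed units
    left: Optional[int] = None  # cells with marker <= cutoff
    right: Optional[int] = None
    predicted_class: Optional[int] = None  # leaves
    n_cells: int = 0  # pooled training cells reaching the node
    n_positive: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.marker is None


@dataclass
class PhenotypeTree:
    """Axis-aligned marker-cutoff tree distilled from cell labels."""

    nodes: Dict[int, TreeNode]
    root: int
    panel: MarkerPanel
    per_sample_stats: Dict[str, dict] = field(default_factory=dict)

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    @property
    def depth(self) -> int:
        def _d(i: int) -> int:
            n = self.nodes[i]
            if n.is_leaf:
                return 0
            return 1 + max(_d(n.left), _d(n.right))
        return _d(self.root)

    def route(self, X: np.ndarray) -> np.ndarray:
        """Leaf id for every row of X."""
        out = np.full(X.shape[0], self.root, dtype=int)
        active = {self.root: np.arange(X.shape[0])}
        while active:
            nxt: Dict[int, np.ndarray] = {}
            for nid, idx in active.items():
                node = self.nodes[nid]
                if node.is_leaf:
                    out[idx] = nid
                    continue
                col = self.panel.index(node.marker)
                goes_left = X[idx, col] <= node.cutoff
                nxt.setdefault(node.left, []), nxt.setdefault(node.right, [])
                nxt[node.left] = idx[goes_left]
                nxt[node.right] = idx[~goes_left]
            active = {k: v for k, v in nxt.items() if len(v)}
        return out

    def path_description(self, leaf_id: int) -> List[Tuple[str, str, float]]:
        """(marker, '<='|'>', cutoff in transformed units) from root to leaf."""
        parent = {}
        for n in self.nodes.values():
            if not n.is_leaf:
                parent[n.left] = (n.node_id, "<=")
                parent[n.right] = (n.node_id, ">")
        path = []
        cur = leaf_id
        while cur in parent:
            pid, side = parent[cur]
            p = self.nodes[pid]
            path.append((p.marker, side, p.cutoff))
            cur = pid
        return list(reversed(path))

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": [
                {
                    "id": n.node_id, "marker": n.marker, "cutoff": n.cutoff,
                    "cutoff_raw": n.cutoff_raw, "left": n.left, "right": n.right,
                    "predicted_class": n.predicted_class,
                    "n_cells": n.n_cells, "n_positive": n.n_positive,
                }
                for n in self.nodes.values()
            ],
            "per_sample_stats": {
                sid: {
                    "node_counts": {str(k): int(v) for k, v in st["node_counts"].items()},
                    "leaf_positive_fraction": {str(k): float(v) for k, v in st["leaf_positive_fraction"].items()},
                    "positive_paths": list(st["positive_paths"]),
                }
                for sid, st in self.per_sample_stats.items()
            },
        }


def build_global_tree(
    cohort: Cohort,
    labels: CellLabels,
    max_depth: int = 4,
    min_leaf_frac: float = 0.01,
    seed: int = 0,
    min_impurity_decrease: float = 1e-3,
) -> PhenotypeTree:
    """CART tree (Gini, axis-aligned marker splits) on pooled labeled cells.

    Cutoffs are reported both in transformed units and mapped back through
    the panel's inverse transform.  The impurity-decrease floor stops the
    tree from fragmenting near-pure populations to isolate a few stray
    cells, keeping one leaf per phenotype.  Single-class labels yield a
    degenerate one-leaf tree with a warning.
    """
    panel = cohort.panel
    X = np.vstack([s.events.values for s in cohort.samples])
    y = labels.pooled(cohort.sample_ids)
    if X.shape[0] != y.size:
        raise ValueError("labels are misaligned with the cohort's cells")

    nodes: Dict[int, TreeNode] = {}
    if len(np.unique(y)) < 2:
        warnings.warn("all cell labels identical; returning a single-leaf tree")
        nodes[0] = TreeNode(node_id=0, predicted_class=int(y[0]) if y.size else 0,
                            n_cells=int(y.size), n_positive=int(y.sum()))
        return PhenotypeTree(nodes=nodes, root=0, panel=panel)

    clf = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_leaf_frac,
        min_impurity_decrease=min_impurity_decrease,
        random_state=seed,
    )
    clf.fit(X, y)
    t = clf.tree_
    for i in range(t.node_count):
        counts = t.value[i][0] * t.weighted_n_node_samples[i] / max(t.value[i][0].sum(), 1e-300)
        n_cells = int(round(t.weighted_n_node_samples[i]))
        n_pos = int(round(counts[1])) if counts.size > 1 else 0
        if t.children_left[i] == -1:
            nodes[i] = TreeNode(
                node_id=i,
                predicted_class=int(np.argmax(t.value[i][0])),
                n_cells=n_cells, n_positive=n_pos,
            )
        else:
            marker = panel.names[int(t.feature[i])]
            cutoff = float(t.threshold[i])
            nodes[i] = TreeNode(
                node_id=i, marker=marker, cutoff=cutoff,
                cutoff_raw=panel.inverse_value(marker, cutoff),
                left=int(t.children_left[i]), right=int(t.children_right[i]),
                n_cells=n_cells, n_positive=n_pos,
            )
    return PhenotypeTree(nodes=nodes, root=0, panel=panel)


def project_sample_tree(
    tree: PhenotypeTree,
    sample: SampleRecord,
    labels: CellLabels,
    min_positive_fraction: float = 0.5,
    min_positive_coverage: float = 0.05,
) -> dict:
    """Route one sample's cells down the fixed global tree.

    Returns per-node cell counts, per-leaf positive-label fractions, and the
    "positive paths": leaves that are majority labeled-positive for this
    sample (fraction >= `min_positive_fraction`) and hold at least
    `min_positive_coverage` of the sample's positive-labeled cells — the
    coverage floor keeps a handful of stray cells from flagging a path.
    Counts conserve: children sum to parent.  The stats are also recorded on
    the tree under the sample id.
    """
    X = sample.events.values
    z = labels.labels.get(sample.sample_id)
    if z is None:
        raise KeyError(f"no cell labels for sample {sample.sample_id!r}")
    for name in {n.marker for n in tree.nodes.values() if not n.is_leaf}:
        if name not in tree.panel.names:
            raise KeyError(f"tree marker {name!r} missing from panel")

    leaf_of = tree.route(X)
    node_counts: Dict[int, int] = {nid: 0 for nid in tree.nodes}
    node_pos: Dict[int, int] = {nid: 0 for nid in tree.nodes}

    # accumulate up from leaves so counts conserve by construction
    parent = {}
    for n in tree.nodes.values():
        if not n.is_leaf:
            parent[n.left] = n.node_id
            parent[n.right] = n.node_id
    for leaf_id in np.unique(leaf_of):
        idx = leaf_of == leaf_id
        c, p = int(idx.sum()), int(z[idx].sum())
        nid = int(leaf_id)
        while True:
            node_counts[nid] += c
            node_pos[nid] += p
            if nid not in parent:
                break
            nid = parent[nid]

    leaf_pos_frac = {
        n.node_id: (node_pos[n.node_id] / node_counts[n.node_id]) if node_counts[n.node_id] else 0.0
        for n in tree.leaves()
    }
    total_pos = int(z.sum())
    positive_paths = [
        nid for nid, frac in leaf_pos_frac.items()
        if node_counts[nid] > 0
        and frac >= min_positive_fraction
        and total_pos > 0
        and node_pos[nid] / total_pos >= min_positive_coverage
    ]
    stats = {
        "node_counts": node_counts,
        "node_positive": node_pos,
        "leaf_positive_fraction": leaf_pos_frac,
        "positive_paths": sorted(positive_paths),
        "min_positive_fraction": min_positive_fraction,
        "min_positive_coverage": min_positive_coverage,
    }
    tree.per_sample_stats[sample.sample_id] = stats
    return stats


@dataclass
class ClusterEnrichment:
    """K-means pooled clustering with per-sample prevalence per cluster."""

    k: int
    assignments: np.ndarray  # cluster of every pooled cell
    pooled_sample_ids: List[str]  # sample id of every pooled cell
    pooled_cell_indices: np.ndarray  # index of each pooled cell within its sample
    prevalence: pd.DataFrame  # samples x clusters, rows sum to 1
    cancer_only: np.ndarray  # bool per cluster
    p_hi: float
    p_lo: float
    jaccard_with_labels: Optional[float] = None

    def cancer_only_cluster_ids(self) -> List[int]:
        return [int(c) for c in np.flatnonzero(self.cancer_only)]

    def member_mask(self, cluster_ids: Sequence[int]) -> np.ndarray:
        return np.isin(self.assignments, list(cluster_ids))


def cancer_only_clusters(
    cohort: Cohort,
    labels: Optional[CellLabels] = None,
    k: int = 8,
    seed: int = 0,
    cells_per_sample_cap: int = 5000,
    p_hi: float = 0.01,
    p_lo: float = 0.002,
) -> ClusterEnrichment:
    """K-means over pooled cells; flag clusters found essentially only in
    positive samples.

    A cluster is cancer-only when its median prevalence across positive
    samples is >= p_hi while its maximum prevalence across negative samples
    is <= p_lo.  Samples are subsampled to a per-sample cap before pooling so
    large samples do not dominate.  When cell labels are given, the Jaccard
    overlap between cancer-only-cluster membership and the labels is reported.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    mats, sids, cidx = [], [], []
    for s in cohort.samples:
        V = s.events.values
        if V.shape[0] > cells_per_sample_cap:
            idx = np.sort(rng.choice(V.shape[0], size=cells_per_sample_cap, replace=False))
        else:
            idx = np.arange(V.shape[0])
        mats.append(V[idx])
        sids.extend([s.sample_id] * len(idx))
        cidx.append(idx)
    X = np.vstack(mats)
    cell_indices = np.concatenate(cidx)

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assign = km.fit_predict(X)

    sid_arr = np.array(sids)
    rows = []
    for s in cohort.samples:
        mask = sid_arr == s.sample_id
        counts = np.bincount(assign[mask], minlength=k).astype(float)
        rows.append(counts / counts.sum())
    prevalence = pd.DataFrame(rows, index=cohort.sample_ids, columns=range(k))

    pos_ids = [s.sample_id for s in cohort.positives()]
    neg_ids = [s.sample_id for s in cohort.negatives()]
    med_pos = prevalence.loc[pos_ids].median(axis=0).to_numpy() if pos_ids else np.zeros(k)
    max_neg = prevalence.loc[neg_ids].max(axis=0).to_numpy() if neg_ids else np.zeros(k)
    cancer_only = (med_pos >= p_hi) & (max_neg <= p_lo)

    jaccard = None
    if labels is not None:
        lab = np.concatenate([
            labels.labels[s.sample_id][idx] for s, idx in zip(cohort.samples, cidx)
        ]).astype(bool)
        member = np.isin(assign, np.flatnonzero(cancer_only))
        union = np.sum(lab | member)
        jaccard = float(np.sum(lab & member) / union) if union else 0.0

    return ClusterEnrichment(
        k=k, assignments=assign, pooled_sample_ids=sids,
        pooled_cell_indices=cell_indices, prevalence=prevalence,
        cancer_only=cancer_only, p_hi=p_hi, p_lo=p_lo,
        jaccard_with_labels=jaccard,
    )


def export_dotplot_data(
    sample: SampleRecord,
    labels: CellLabels,
    marker_pairs: Sequence[Tuple[str, str]],
    panel: MarkerPanel,
    tree: Optional[PhenotypeTree] = None,
) -> Dict[Tuple[str, str], dict]:
    """Per marker pair, a (x, y, label) table in inverse-transformed units,
    with the global tree's cutoffs for the plotted markers as reference lines."""
    z = labels.labels.get(sample.sample_id)
    if z is None:
        raise KeyError(f"no cell labels for sample {sample.sample_id!r}")
    raw = panel.inverse_matrix(sample.events.values)
    cutoffs: Dict[str, List[float]] = {}
    if tree is not None:
        for n in tree.nodes.values():
            if not n.is_leaf:
                cutoffs.setdefault(n.marker, []).append(float(n.cutoff_raw))
    out = {}
    for mx, my in marker_pairs:
        ix, iy = panel.index(mx), panel.index(my)  # raises KeyError for unknown markers
        table = pd.DataFrame({"x": raw[:, ix], "y": raw[:, iy], "label": z})
        out[(mx, my)] = {
            "table": table,
            "cutoffs": {m: sorted(cutoffs.get(m, [])) for m in (mx, my)},
        }
    return out
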