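"""Hierarchical clustering of samples on the signature genes, used as a
binary LVSI classifier.

Samples are agglomeratively clustered on their signature-gene expression
vectors under Euclidean distance and the dendrogram is cut at the root
(the last merge) into exactly two groups.  The group with the higher
proportion of LVSI-positive samples is called **A** and is the
"test-positive" call; the other is **B**.

The linkage is selectable (``average`` — the historical default of
microarray clustering tools — ``complete`` or ``ward``).  Residual
below-detection cells among the signature genes are imputed with the
gene's across-sample mean of detected values before distances are
computed; the detection filter guarantees this imputation is mild.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io import ExpressionMatrix
from .select import _as_bool_labels

__all__ = ["ClusterAssignment", "cluster_samples", "label_groups", "predict",
           "to_newick", "plot_heatmap"]

LINKAGES = ("average", "complete", "ward")


@dataclass
class ClusterAssignment:
    """Result of the two-group dendrogram cut.

    ``merge_tree`` is the scipy linkage matrix (children, merge height in
    Euclidean-distance units, cluster size per agglomeration step).
    ``cluster_of`` maps each sample to the raw cluster index {0, 1} of the
    root cut; ``group_of`` maps to {"A", "B"} once :func:`label_groups`
    has identified the LVSI-enriched cluster.
    """

    merge_tree: np.ndarray
    sample_ids: list[str]
    cluster_of: pd.Series
    linkage: str
    distance: str = "euclidean"
    group_of: pd.Series | None = field(default=None)

    def members(self, cluster: int) -> list[str]:
        return list(self.cluster_of.index[self.cluster_of == cluster])


def _impute(matrix: ExpressionMatrix) -> pd.DataFrame:
    det = matrix.detected()
    if det.notna().sum(axis=1).eq(0).any():
        gid = det.index[det.notna().sum(axis=1) == 0][0]
        raise ValueError(f"gene {gid!r} has no detected value in any sample")
    gene_means = det.mean(axis=1, skipna=True)
    return det.apply(lambda col: col.fillna(gene_means))


def cluster_samples(matrix: ExpressionMatrix, linkage: str = "average"
                    ) -> ClusterAssignment:
    """Agglomerate samples and cut the dendrogram at the root into 2 groups."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    if matrix.n_genes == 0:
        raise ValueError("signature is empty")
    x = _impute(matrix).to_numpy().T  # samples x genes
    z = hierarchy.linkage(x, method=linkage, metric="euclidean")
    flat = hierarchy.cut_tree(z, n_clusters=2).ravel()
    return ClusterAssignment(
        merge_tree=z,
        sample_ids=matrix.sample_ids,
        cluster_of=pd.Series(flat, index=matrix.sample_ids, name="cluster"),
        linkage=linkage,
    )


def label_groups(assignment: ClusterAssignment, labels) -> ClusterAssignment:
    """Identify group A (LVSI-enriched) and B.

    A = the cluster with the higher proportion of LVSI-positive samples;
    ties broken by the higher absolute positive count, then by containing
    the first sample in input order.
    """
    lab = _as_bool_labels(labels).reindex(assignment.sample_ids)
    if lab.isna().any():
        sid = lab.index[lab.isna()][0]
        raise ValueError(f"no LVSI label for sample {sid!r}")

    def key(c: int):
        members = assignment.cluster_of == c
        n = int(members.sum())
        npos = int(lab[members].sum())
        first = members.to_numpy().argmax()  # position of first member
        return (npos / n, npos, -first)

    a = max((0, 1), key=key)
    mapping = {a: "A", 1 - a: "B"}
    assignment.group_of = assignment.cluster_of.map(mapping).rename("group")
    return assignment


def predict(assignment: ClusterAssignment) -> pd.Series:
    """Cluster membership as the diagnostic call: group A => LVSI-positive."""
    if assignment.group_of is None:
        raise ValueError("groups not labeled; call label_groups first")
    return (assignment.group_of == "A").rename("predicted_lvsi")


def to_newick(assignment: ClusterAssignment) -> str:
    """Serialize the dendrogram as Newick; branch lengths are differences
    of merge heights (leaves sit at height 0)."""
    z = assignment.merge_tree
    n = len(assignment.sample_ids)
    heights = np.concatenate([np.zeros(n), z[:, 2]])

    def node(i: int, parent_h: float) -> str:
        bl = parent_h - heights[i]
        if i < n:
            return f"{assignment.sample_ids[i]}:{bl:g}"
        l, r = int(z[i - n, 0]), int(z[i - n, 1])
        return f"({node(l, heights[i])},{node(r, heights[i])}):{bl:g}"

    root = n + len(z) - 1
    l, r = int(z[-1, 0]), int(z[-1, 1])
    h = heights[root]
    return f"({node(l, h)},{node(r, h)});"


def plot_heatmap(matrix: ExpressionMatrix, assignment: ClusterAssignment, path,
                 labels=None) -> None:
    """Samples x signature-genes heat map annotated with the A/B groups."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = hierarchy.leaves_list(assignment.merge_tree)
    data = _impute(matrix).to_numpy()[:, order]
    fig, ax = plt.subplots(figsize=(max(6, matrix.n_samples * 0.12),
                                    max(4, matrix.n_genes * 0.08)))
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(matrix.n_genes))
    ax.set_yticklabels(matrix.gene_ids, fontsize=4)
    groups = (assignment.group_of if assignment.group_of is not None
              else assignment.cluster_of.astype(str))
    ax.set_xticks(range(matrix.n_samples))
    ax.set_xticklabels(
        [f"{matrix.sample_ids[i]} ({groups.iloc[i]})" for i in order],
        rotation=90, fontsize=4)
    fig.colorbar(im, ax=ax, label="log2 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
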