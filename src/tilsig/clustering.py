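"""Unsupervised case clustering on signature-gene z-scores.

Agglomerative clustering with centroid linkage and euclidean distance:
the distance between two clusters is the euclidean distance between their
arithmetic-mean centroids, recomputed after every merge.  Centroid
linkage can produce height inversions (a merge lower than an earlier
one), so trees are cut by undoing merges in merge order rather than by a
height threshold — this keeps k-cluster partitions well defined and
nested.  Cases that fail to join any of the three primary clusters are
flagged as outliers and excluded downstream; the remaining clusters are
labelled high / intermediate / low by mean signature score, and the
intermediate and low clusters are merged into a single TIL-low group
when their response rates are statistically indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import build_table, fisher_exact_two_sided

__all__ = [
    "LinkageTree",
    "TILClassification",
    "centroid_linkage",
    "cut_tree",
    "detect_outliers",
    "label_and_merge",
    "classify_cases",
]


@dataclass(frozen=True)
class LinkageTree:
    """Merge list of an agglomeration: leaves are 0..n−1 in input order;
    the i-th merge creates internal node n+i.  Heights are recorded as
    computed; inversions are permitted."""

    leaf_ids: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]  # (node_a, node_b, height, size)

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(f"expected {n - 1} merges for {n} leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.merges, columns=["node_a", "node_b", "height", "size"])
        frame.to_csv(path, sep="\t", index=False)


def centroid_linkage(points: np.ndarray, leaf_ids: list[str]) -> LinkageTree:
    """Agglomerate ``points`` (n × d) under centroid linkage.

    Deterministic given input order: distance ties are broken by the
    lexicographically smallest (first-node, second-node) index pair.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if len(leaf_ids) != n:
        raise ValueError("leaf_ids length must match number of points")
    if not np.isfinite(points).all():
        raise ValueError("points contain missing/non-finite values")

    # Active clusters keyed by node index; centroids and sizes updated on merge.
    node_ids = list(range(n))
    centroids = [points[i].copy() for i in range(n)]
    sizes = [1] * n
    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    for _ in range(n - 1):
        m = len(node_ids)
        cent = np.asarray(centroids)
        d2 = ((cent[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        iu = np.triu_indices(m, k=1)
        flat = d2[iu]
        best = flat.min()
        # tie-break: among minimal distances pick smallest (i, j) position
        # pair, which (node ids being position-sorted) is the smallest
        # (first-node, second-node) pair.
        candidates = np.flatnonzero(flat <= best)
        pick = candidates[0]
        i, j = iu[0][pick], iu[1][pick]
        height = float(np.sqrt(d2[i, j]))
        size = sizes[i] + sizes[j]
        new_centroid = (sizes[i] * cent[i] + sizes[j] * cent[j]) / size
        merges.append((node_ids[i], node_ids[j], height, size))
        # remove j first (j > i) to keep indices valid
        for lst in (node_ids, centroids, sizes):
            del lst[j]
        node_ids[i] = next_node
        centroids[i] = new_centroid
        sizes[i] = size
        node_ids, centroids, sizes = _resort(node_ids, centroids, sizes)
        next_node += 1
    return LinkageTree(leaf_ids=tuple(leaf_ids), merges=tuple(merges))


def _resort(node_ids, centroids, sizes):
    order = np.argsort(node_ids, kind="stable")
    return (
        [node_ids[k] for k in order],
        [centroids[k] for k in order],
        [sizes[k] for k in order],
    )


def cut_tree(tree: LinkageTree, k: int) -> pd.Series:
    """Partition into k clusters by undoing the last k−1 merges.

    Robust to height inversions because only merge order matters.
    Cluster indices are assigned in decreasing cluster-size order (ties
    broken by smallest member leaf).  Returns sample_id → cluster index.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _h, _s) in enumerate(tree.merges[: n - k]):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new

    roots = [find(i) for i in range(n)]
    members: dict[int, list[int]] = {}
    for leaf, root in enumerate(roots):
        members.setdefault(root, []).append(leaf)
    ordered = sorted(members.values(), key=lambda ms: (-len(ms), ms[0]))
    assignment = np.empty(n, dtype=int)
    for idx, ms in enumerate(ordered):
        assignment[ms] = idx
    return pd.Series(assignment, index=list(tree.leaf_ids), name="cluster_index")


def detect_outliers(
    tree: LinkageTree, n_primary: int = 3, min_fraction: float = 0.05
) -> pd.DataFrame:
    """Find a cut yielding exactly ``n_primary`` clusters of size ≥
    min_fraction·n; members of smaller clusters are flagged outliers.

    Starts at k = n_primary and raises k until the condition holds.
    Returns a frame with sample_id index, primary-cluster index (−1 for
    outliers) and an ``outlier`` flag.
    """
    n = tree.n_leaves
    threshold = min_fraction * n
    for k in range(n_primary, n + 1):
        assignment = cut_tree(tree, k)
        sizes = assignment.value_counts()
        primary = sorted(idx for idx, size in sizes.items() if size >= threshold)
        if len(primary) == n_primary:
            remap = {old: new for new, old in enumerate(primary)}
            cluster_index = assignment.map(lambda c: remap.get(c, -1))
            return pd.DataFrame(
                {
                    "cluster_index": cluster_index,
                    "outlier": cluster_index == -1,
                }
            )
    raise ValueError(
        f"no cut with ≤ {n} clusters yields exactly {n_primary} primary "
        f"clusters at min_fraction={min_fraction}; adjust parameters"
    )


@dataclass
class TILClassification:
    """Per-sample cluster membership, ordered labels, and the merged
    binary TIL-high/TIL-low call."""

    table: pd.DataFrame  # sample_id index: cluster_index, ordered_label,
    #                      binary_label, outlier, signature_score
    merge_p: float | None = None
    merge_performed: bool = False
    cluster_means: dict[str, float] = field(default_factory=dict)

    def binary_labels(self) -> pd.Series:
        return self.table["binary_label"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def label_and_merge(
    assignment: pd.DataFrame,
    scores: pd.Series,
    outcomes: pd.Series | dict,
    merge_alpha: float = 0.05,
) -> TILClassification:
    """Order the three primary clusters by mean signature score into
    high / intermediate / low and merge intermediate+low into TIL-low
    when their response rates do not differ (two-sided Fisher p ≥ alpha).

    When the rates do differ, the merge is withheld: the three ordered
    labels stand, only the high cluster receives a binary label, and the
    result is flagged for analyst review via ``merge_performed=False``.
    """
    outcomes = pd.Series(dict(outcomes) if not isinstance(outcomes, pd.Series) else outcomes)
    primary = sorted(c for c in assignment["cluster_index"].unique() if c != -1)
    if len(primary) != 3:
        raise ValueError("label_and_merge requires exactly 3 primary clusters")

    means = {
        c: float(scores[assignment.index[assignment["cluster_index"] == c]].mean())
        for c in primary
    }
    by_score = sorted(primary, key=lambda c: (-means[c], c))
    label_of = dict(zip(by_score, ("high", "intermediate", "low")))

    table = assignment.copy()
    table["ordered_label"] = [
        label_of.get(c, "outlier") for c in table["cluster_index"]
    ]
    table["signature_score"] = scores.reindex(table.index)

    # Fisher comparison of intermediate vs low pCR rates
    sub = table[table["ordered_label"].isin(("intermediate", "low"))]
    exposure = (sub["ordered_label"] == "intermediate").map(
        {True: "intermediate", False: "low"}
    )
    outcome_sub = outcomes.reindex(sub.index)
    for label in ("intermediate", "low"):
        mask = sub["ordered_label"] == label
        if outcome_sub[mask].isna().all():
            raise ValueError(f"outcome missing for every member of the {label} cluster")
    contingency = build_table(
        exposure, outcome_sub, exposure_positive="intermediate", outcome_positive="pCR"
    )
    merge_p = fisher_exact_two_sided(contingency)
    merge = merge_p >= merge_alpha

    def binary(row_label: str) -> str:
        if row_label == "outlier":
            return "excluded"
        if row_label == "high":
            return "TIL-high"
        return "TIL-low" if merge else "withheld"

    table["binary_label"] = table["ordered_label"].map(binary)
    table = table[
        ["cluster_index", "ordered_label", "binary_label", "outlier", "signature_score"]
    ]
    return TILClassification(
        table=table,
        merge_p=float(merge_p),
        merge_performed=bool(merge),
        cluster_means={label_of[c]: means[c] for c in primary},
    )


def classify_cases(
    matrix,
    signature,
    outcomes,
    n_primary: int = 3,
    min_fraction: float = 0.05,
    merge_alpha: float = 0.05,
) -> TILClassification:
    """Convenience wrapper: score → cluster → outliers → label/merge."""
    from .signature import signature_score

    genes = list(signature.genes if hasattr(signature, "genes") else signature)
    scores = signature_score(matrix, genes)
    sub = matrix.subset_rows(genes)
    points = sub.data.to_numpy(dtype=float).T
    tree = centroid_linkage(points, sub.sample_ids)
    assignment = detect_outliers(tree, n_primary=n_primary, min_fraction=min_fraction)
    return label_and_merge(assignment, scores, outcomes, merge_alpha=merge_alpha)
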