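"""Ward minimum-variance clustering of cases on their z-score profiles.

Cases are points in K-dimensional z-score space (one coordinate per top-K
acupoint). Agglomeration follows Ward's criterion: at each step the pair of
clusters whose merge least increases the total within-cluster sum of squares
is fused. The height recorded for a merge is that criterion increase,

    delta(i, j) = n_i * n_j / (n_i + n_j) * ||centroid_i - centroid_j||^2,

which is monotone non-decreasing over the agglomeration (Ward has no
inversions). The raw squared distance between the two merged centroids is
kept alongside, since dendrogram y-axes are sometimes drawn in that unit
instead; the two differ only by the size factor n_i*n_j/(n_i+n_j).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .errors import ParameterError, ValidationError

__all__ = ["MergeStep", "MergeTree", "ward_linkage", "cut_tree", "export_dendrogram"]


@dataclass(frozen=True)
class MergeStep:
    """One agglomeration step.

    ``left`` and ``right`` are node ids: 0..n-1 are leaves (row order of the
    input profiles), and merge step t creates node n+t. ``height`` is the
    Ward criterion increase; ``centroid_sqdist`` the squared Euclidean
    distance between the merged centroids; ``size`` the merged cluster size.
    """

    left: int
    right: int
    height: float
    size: int
    centroid_sqdist: float


@dataclass
class MergeTree:
    """Full agglomeration history over a set of cases."""

    leaves: list[str]
    merges: list[MergeStep]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": t,
                    "left": m.left,
                    "right": m.right,
                    "height": m.height,
                    "centroid_sqdist": m.centroid_sqdist,
                    "size": m.size,
                }
                for t, m in enumerate(self.merges)
            ]
        )


def ward_linkage(profiles: pd.DataFrame) -> MergeTree:
    """Agglomerate case profiles under Ward's minimum-variance criterion.

    ``profiles`` holds one row per case (index = case ids). Heights are the
    Ward criterion increase (see module docstring). Requires at least two
    cases and no missing values.
    """
    if profiles.shape[0] < 2:
        raise ParameterError("ward_linkage needs at least 2 cases")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("profiles contain missing or non-finite values")
    Z = linkage(X, method="ward")
    n = X.shape[0]
    sizes = {i: 1 for i in range(n)}
    merges: list[MergeStep] = []
    for t in range(Z.shape[0]):
        left, right = sorted((int(Z[t, 0]), int(Z[t, 1])))
        size = int(Z[t, 3])
        # scipy's ward cophenetic distance h satisfies h^2 = 2 * delta
        height = Z[t, 2] ** 2 / 2.0
        ni, nj = sizes[left], sizes[right]
        merges.append(
            MergeStep(
                left=left,
                right=right,
                height=float(height),
                size=size,
                centroid_sqdist=float(height * (ni + nj) / (ni * nj)),
            )
        )
        sizes[n + t] = size
    return MergeTree(leaves=[str(c) for c in profiles.index], merges=merges)


def _labels(k: int) -> list[str]:
    """'A', 'B', ... 'Z', 'AA', 'AB', ... — spreadsheet-style labels."""
    out = []
    for i in range(k):
        s, j = "", i
        while True:
            s = string.ascii_uppercase[j % 26] + s
            j = j // 26 - 1
            if j < 0:
                break
        out.append(s)
    return out


def cut_tree(tree: MergeTree, k: int) -> dict[str, str]:
    """Cut the merge tree into k clusters (undo the last k-1 merges).

    Returns ``{case_id: label}``; labels 'A', 'B', ... are assigned to
    clusters in order of their smallest contained leaf index, so the
    labelling is deterministic under re-runs.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    # union-find over the first n-k merges
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, m in enumerate(tree.merges[: n - k]):
        node = n + t
        parent[find(m.left)] = node
        parent[find(m.right)] = node
    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(roots.values(), key=min)
    labels = _labels(k)
    assignment: dict[str, str] = {}
    for label, members in zip(labels, ordered):
        for leaf in members:
            assignment[tree.leaves[leaf]] = label
    return assignment


def to_newick(tree: MergeTree) -> str:
    """Render the merge tree as a newick string with branch lengths.

    A node's branch length is its parent's merge height minus its own height
    (leaves have height 0), so root-to-leaf path lengths equal the root merge
    height.
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for t, m in enumerate(tree.merges):
        node = n + t
        heights[node] = m.height
        children[node] = (m.left, m.right)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            name = tree.leaves[node].replace(" ", "_")
            return f"{name}:{length:.10g}"
        left, right = children[node]
        inner = f"({render(left, heights[node])},{render(right, heights[node])})"
        return f"{inner}:{length:.10g}"

    root = n + len(tree.merges) - 1
    left, right = children[root]
    return (
        f"({render(left, heights[root])},{render(right, heights[root])});"
    )


def export_dendrogram(tree: MergeTree, path) -> str:
    """Write the dendrogram as a newick file; returns the newick text."""
    text = to_newick(tree)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text + "\n")
    return text
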