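"""Agglomerative sample clustering: Euclidean metric, centroid linkage.

At each step the pair of clusters whose unweighted-mean centroids are
closest (ordinary Euclidean distance) is merged, and the merged centroid
is recomputed as the plain mean of all member points.  Centroid linkage
can produce height inversions (a merge lower than an earlier one); raw
heights are kept in the dendrogram and only floored when differencing
branch lengths for Newick export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


def centroid_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between the mean vectors of two point sets.

    ``a`` and ``b`` are (n_points, n_features) arrays; a single vector
    may be passed as a 1-D array.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty cluster")
    return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))


@dataclass
class Node:
    """Dendrogram node; a leaf has a name, an internal node two children."""

    height: float
    members: tuple[str, ...]
    name: str | None = None
    children: tuple["Node", "Node"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Dendrogram:
    root: Node
    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=list)

    @property
    def leaves(self) -> list[str]:
        return list(self.root.members)

    def first_merge_partner(self, sample: str) -> tuple[str, ...]:
        """Members of the cluster ``sample`` is first merged with."""
        for _, a, b in self.merges:
            if sample in a:
                return b
            if sample in b:
                return a
        raise ValidationError(f"sample {sample!r} not in dendrogram")


def _rep(members: tuple[str, ...]) -> str:
    return min(members)


def cluster_samples(matrix: ExpressionMatrix | pd.DataFrame) -> Dendrogram:
    """Cluster samples (columns) by repeated nearest-centroid merging.

    Ties in the minimal centroid distance are broken by the
    lexicographically smallest (repA, repB) pair, where a cluster's
    representative is its smallest member name; this makes the topology
    invariant to input sample order.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    samples = list(values.columns)
    if len(samples) < 2:
        raise ValidationError("clustering requires >= 2 samples")
    points = {s: values[s].to_numpy(float) for s in samples}
    active: dict[tuple[str, ...], Node] = {
        (s,): Node(0.0, (s,), name=s) for s in samples}
    merges = []
    while len(active) > 1:
        best = None
        for ka in active:
            for kb in active:
                if ka >= kb:
                    continue
                d = centroid_distance(
                    np.stack([points[s] for s in ka]),
                    np.stack([points[s] for s in kb]))
                pair_key = tuple(sorted((_rep(ka), _rep(kb))))
                cand = (d, pair_key, ka, kb)
                if best is None or d < best[0] - 1e-12 or (
                        abs(d - best[0]) <= 1e-12 and pair_key < best[1]):
                    best = cand
        d, _, ka, kb = best
        na, nb = active.pop(ka), active.pop(kb)
        members = tuple(na.members + nb.members)
        active[members] = Node(d, members, children=(na, nb))
        merges.append((d, na.members, nb.members))
    (root,) = active.values()
    return Dendrogram(root, merges)


def to_newick(dendrogram: Dendrogram, decimals: int = 6) -> str:
    """Serialise the dendrogram as Newick with branch lengths.

    Branch length = parent height - child height, floored at 0 when
    centroid-linkage inversions would make it negative (logged).
    """
    floored = 0

    def render(node: Node, parent_height: float) -> str:
        nonlocal floored
        length = parent_height - node.height
        if length < 0:
            floored += 1
            length = 0.0
        blen = f"{length:.{decimals}g}"
        if node.is_leaf:
            return f"{node.name}:{blen}"
        left, right = node.children
        inner = f"({render(left, node.height)},{render(right, node.height)})"
        return f"{inner}:{blen}"

    root = dendrogram.root
    left, right = root.children
    text = f"({render(left, root.height)},{render(right, root.height)});"
    if floored:
        log.warning("to_newick: floored %d negative branch length(s) from "
                    "centroid-linkage inversions", floored)
    return text
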