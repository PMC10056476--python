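"""Degradation-pattern structure: cosine distances between plastic types,
agglomerative clustering, and non-metric MDS ordination.

Plastic types are compared through the columns of the genus-plastic
association matrix: two plastics are close when largely the same genera are
reported to degrade both. Cosine distance on binary profiles lies in [0, 1]
(0 = identical reporting profile, 1 = disjoint genus sets). Note cosine
distance is not a metric — the triangle inequality can fail — which the
agglomerative and NMDS procedures tolerate by construction.

The agglomerative clusterer is written here rather than delegated because the
package guarantees deterministic, platform-independent merge order: ties in
the minimum inter-cluster distance are broken toward the pair of clusters
whose lexicographically smallest member labels sort first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import MDS
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.pairwise import cosine_distances

from .association import AssociationMatrix, GroupScheme

LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix has non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="plastic")


def cosine_distance_matrix(matrix: AssociationMatrix) -> DistanceMatrix:
    """All-vs-all cosine distances between plastic-type columns.

    d(p, q) = 1 - (u . v) / (||u|| ||v||) over the binary genus profiles.
    """
    X = matrix.data.to_numpy(dtype=float)
    colsums = X.sum(axis=0)
    if (colsums == 0).any():
        bad = [p for p, s in zip(matrix.plastics, colsums) if s == 0]
        raise ValueError(f"all-zero plastic column(s): {', '.join(bad)}")
    D = cosine_distances(X.T)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(tuple(matrix.plastics), D)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` lists (node_a, node_b, height, size) in merge order; leaves are
    numbered 0..n-1 in ``labels`` order and merge k creates node n+k
    (the scipy linkage-matrix convention).
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    linkage: str

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.labels) - 1:
            raise ValueError("a dendrogram on n leaves must have n-1 merges")

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(m[2] for m in self.merges)

    def to_scipy_linkage(self) -> np.ndarray:
        """Linkage matrix usable with scipy.cluster.hierarchy plotting/utilities."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def _cluster_distance(sub: np.ndarray, linkage: str) -> float:
    if linkage == "average":
        return float(sub.mean())
    if linkage == "complete":
        return float(sub.max())
    return float(sub.min())  # single


def hierarchical_cluster(
    dist: DistanceMatrix, linkage: str = "average"
) -> Dendrogram:
    """Agglomerate labels under average (UPGMA), complete, or single linkage.

    Deterministic: among tied minimum-distance pairs, the pair whose clusters
    contain the lexicographically smallest leaf labels is merged first.
    Inter-cluster distances are recomputed from the input matrix at every
    step, so the result is exactly the naive O(n^3) agglomeration.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    n = len(dist.labels)
    if n < 2:
        raise ValueError("clustering requires at least 2 labels")
    D = dist.values
    # active cluster id -> (leaf indices, smallest member label)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    minlab: dict[int, str] = {i: dist.labels[i] for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best: Optional[tuple] = None
        active = sorted(members)
        for ia, a in enumerate(active):
            for b in active[ia + 1:]:
                d = _cluster_distance(D[np.ix_(members[a], members[b])], linkage)
                la, lb = sorted((minlab[a], minlab[b]))
                key = (d, la, lb)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        merged = members.pop(a) + members.pop(b)
        merges.append((min(a, b), max(a, b), d, len(merged)))
        members[next_id] = merged
        minlab[next_id] = min(minlab.pop(a), minlab.pop(b))
        next_id += 1
    return Dendrogram(dist.labels, tuple(merges), linkage)


def cut_tree(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Partition the leaves into k clusters by removing the k-1 highest merges.

    Cluster ids are assigned 0..k-1 in leaf order (the cluster containing the
    first leaf gets id 0, and so on).
    """
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _, _) in enumerate(dendrogram.merges[: n - k]):
        node = n + i
        parent[find(a)] = node
        parent[find(b)] = node
    ids: dict[int, int] = {}
    partition: dict[str, int] = {}
    for leaf, label in enumerate(dendrogram.labels):
        root = find(leaf)
        if root not in ids:
            ids[root] = len(ids)
        partition[label] = ids[root]
    return partition


def dendrogram_to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with ultrametric branch lengths (node depth = height / 2)."""
    n = len(dendrogram.labels)
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: dendrogram.labels[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(dendrogram.merges):
        nid = n + i
        height[nid] = h
        bl_a = h / 2.0 - height[a] / 2.0
        bl_b = h / 2.0 - height[b] / 2.0
        node[nid] = f"({node[a]}:{bl_a:.10g},{node[b]}:{bl_b:.10g})"
        del node[a], node[b]
    return node[2 * n - 2] + ";"


@dataclass(frozen=True)
class Embedding:
    """2-D NMDS configuration with its stress-1 value."""

    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n, dims)
    stress: float
    seed: int
    n_restarts: int

    def __post_init__(self) -> None:
        if self.stress < 0 or not np.isfinite(self.coordinates).all():
            raise ValueError("embedding must have finite coordinates and stress >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=self.labels,
            columns=[f"nmds{i + 1}" for i in range(self.coordinates.shape[1])],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="label")


def nmds_embed(
    dist: DistanceMatrix,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 8,
    max_iter: int = 1000,
) -> Embedding:
    """Best-of-restarts non-metric MDS minimizing Kruskal stress-1.

    Disparities are fitted monotonically (isotonic regression) to the input
    dissimilarity ranks; the reported configuration is the lowest-stress one
    over ``n_restarts`` random starts. Same seed, same output.
    """
    if len(dist.labels) < 3:
        raise ValueError("NMDS requires at least 3 labels")
    mds = MDS(
        n_components=dims,
        metric="precomputed",
        metric_mds=False,
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=1e-12,
        random_state=seed,
        normalized_stress=True,  # Kruskal stress-1
    )
    coords = mds.fit_transform(dist.values)
    return Embedding(dist.labels, coords, float(mds.stress_), seed, n_restarts)


def compare_partition(
    partition: Mapping[str, int], scheme: GroupScheme
) -> float:
    """Adjusted Rand index between a clustering and the CC/CX group labels."""
    unmapped = [lab for lab in partition if scheme.group_of(lab) is None]
    if unmapped:
        raise ValueError(f"labels not mapped by the scheme: {', '.join(sorted(unmapped))}")
    labels = sorted(partition)
    return float(
        adjusted_rand_score(
            [scheme.group_of(lab) for lab in labels],
            [partition[lab] for lab in labels],
        )
    )
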