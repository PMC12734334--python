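"""Simple-matching similarity and UPGMA dendrograms for band data.

Similarity between two accessions is the simple matching coefficient:
the fraction of band columns on which they agree, counting shared
absences as agreement (the convention of dominant-style band scoring).
Columns of markers missing in either accession are excluded pairwise.
Distance is ``1 − similarity``, so a dendrogram built on it can be cut
directly in similarity units: a cut at similarity ``s`` separates
clusters that merge above height ``1 − s``.

UPGMA node heights are the size-weighted average distance at each merge
(not halved), matching dendrogram scales read in similarity units.
Ties between equally close pairs merge the pair whose (smallest leaf
label, largest leaf label) is lexicographically least, which makes the
tree deterministic under any input order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import BandMatrix


class UndefinedPairError(ValueError):
    """A pair of accessions shares no comparable band columns."""


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v

    def to_distance(self) -> np.ndarray:
        return 1.0 - self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def simple_matching(b: BandMatrix) -> SimilarityMatrix:
    """Pairwise simple matching coefficients over comparable columns."""
    labels = b.accessions
    if len(labels) < 2:
        raise ValueError("need at least two accessions")
    X = b.data.to_numpy()
    n, c = X.shape
    markers = np.asarray(b.marker_of_column)
    missing = b.missing.to_numpy()
    any_missing = missing.any()
    values = np.ones((n, n))
    if not any_missing:
        # all columns comparable for every pair
        agree = (X[:, None, :] == X[None, :, :]).sum(axis=2)
        values = agree / c
    else:
        col_marker_idx = pd.Index(b.missing.columns).get_indexer(markers)
        for i, j in itertools.combinations(range(n), 2):
            bad_markers = missing[i] | missing[j]
            keep = ~bad_markers[col_marker_idx]
            m = keep.sum()
            if m == 0:
                raise UndefinedPairError(
                    f"no comparable columns for ({labels[i]}, {labels[j]})"
                )
            s = (X[i, keep] == X[j, keep]).mean()
            values[i, j] = values[j, i] = s
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels=list(labels), values=values)


@dataclass
class Node:
    """Dendrogram node; leaves have height 0 and no children."""

    height: float
    leaves: list[str]
    label: str | None = None
    children: tuple["Node", "Node"] | None = None
    size: int = field(default=1)

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class Dendrogram:
    root: Node
    leaf_order: list[str]  # input order of accessions

    def nodes(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            if n.children:
                stack.extend(n.children)
        return out

    def cophenetic(self) -> pd.DataFrame:
        """Leaf × leaf matrix of merge heights (the height of the lowest
        common ancestor of each pair)."""
        labels = self.leaf_order
        idx = {l: i for i, l in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)))
        for node in self.nodes():
            if node.children:
                a, b = node.children
                for la in a.leaves:
                    for lb in b.leaves:
                        m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = node.height
        return pd.DataFrame(m, index=labels, columns=labels)


def upgma(distances: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a full distance matrix."""
    d = np.asarray(distances, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if d.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix shape must match labels")
    clusters: dict[int, Node] = {
        i: Node(height=0.0, leaves=[lab], label=lab, size=1)
        for i, lab in enumerate(labels)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j])
        for i, j in itertools.combinations(range(len(labels)), 2)
    }
    next_id = len(labels)
    while len(clusters) > 1:
        # tie rule: least distance, then lexicographically least
        # (min leaf label, max leaf label) over the two clusters
        def sort_key(pair: tuple[int, int]) -> tuple:
            i, j = pair
            a = min(clusters[i].leaves)
            b = min(clusters[j].leaves)
            lo, hi = sorted((a, b))
            return (dist[pair], lo, hi)

        (i, j) = min(dist, key=sort_key)
        h = dist[(i, j)]
        a, b = clusters.pop(i), clusters.pop(j)
        merged = Node(
            height=h,
            leaves=a.leaves + b.leaves,
            children=(a, b),
            size=a.size + b.size,
        )
        new_dist: dict[tuple[int, int], float] = {}
        for (p, q), v in dist.items():
            if i in (p, q) or j in (p, q):
                continue
            new_dist[(p, q)] = v
        for k, node in clusters.items():
            da = dist[(min(i, k), max(i, k))]
            db = dist[(min(j, k), max(j, k))]
            new_dist[(k, next_id)] = (a.size * da + b.size * db) / merged.size
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    return Dendrogram(root=next(iter(clusters.values())), leaf_order=list(labels))


def upgma_from_similarity(s: SimilarityMatrix) -> Dendrogram:
    return upgma(s.to_distance(), s.labels)


def cut_at_similarity(t: Dendrogram, threshold: float) -> dict[str, int]:
    """Cluster membership when the tree is cut at a similarity threshold.

    Leaves joined at height ≤ ``1 − threshold`` share a group.  Groups
    are numbered from 1 in order of their first accession in the input.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    h = 1.0 - threshold + 1e-12
    groups: list[list[str]] = []

    def collect(node: Node) -> None:
        if node.is_leaf or node.height <= h:
            groups.append(node.leaves)
        else:
            for child in node.children:
                collect(child)

    collect(t.root)
    order = {lab: i for i, lab in enumerate(t.leaf_order)}
    groups.sort(key=lambda g: min(order[l] for l in g))
    assignment: dict[str, int] = {}
    for gid, members in enumerate(groups, start=1):
        for lab in members:
            assignment[lab] = gid
    return assignment


def to_newick(t: Dendrogram) -> str:
    """Newick string; branch length = parent height − child height."""

    def fmt(node: Node, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{bl:.10g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{bl:.10g}"

    root = t.root
    if root.is_leaf:
        return f"{root.label}:0;"
    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(t: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(to_newick(t) + "\n")


def write_similarity(s: SimilarityMatrix, path: str | Path) -> None:
    s.to_frame().rename_axis("accession").to_csv(path, sep="\t")


def write_groups(assignment: dict[str, int], path: str | Path) -> None:
    pd.Series(assignment, name="group").rename_axis("accession").to_csv(
        path, sep="\t"
    )
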