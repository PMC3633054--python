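"""Topology comparison of phylogenetic trees over a common leaf set.

Two scores are provided.  The Robinson-Foulds symmetric distance counts
bipartitions (splits) present in one tree but not the other — a strict,
local measure.  The topology-similarity score instead aligns the two
edge sets: every pair of internal edges is scored by the Jaccard overlap
of the leaf subsets they induce, a maximum-weight one-to-one matching
between the edge sets is computed, and the matched score total is
normalised by the larger edge count.  Identical topologies score exactly
1; the score degrades gracefully with partial clustering agreement,
which is what makes it preferable to RF for judging whether two trees
tell the same taxonomic story.

Rooted trees are treated as unrooted for splitting purposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["Bipartition", "bipartitions", "rf_distance", "topology_similarity"]


@dataclass(frozen=True)
class Bipartition:
    """The two complementary leaf-label sets induced by one internal edge.

    Canonical form: ``first`` is the side containing the lexicographically
    smallest label of the whole leaf set; both sides are sorted tuples.
    """

    first: tuple[str, ...]
    second: tuple[str, ...]

    @classmethod
    def from_sets(cls, side_a, side_b) -> "Bipartition":
        a = tuple(sorted(side_a))
        b = tuple(sorted(side_b))
        smallest = min(a[0], b[0])
        if smallest in a:
            return cls(a, b)
        return cls(b, a)


def _leaf_sets_below_edges(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label set below each edge worth considering, unrooted view."""
    below: dict[int, frozenset[str]] = {}
    sets: list[frozenset[str]] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            s: frozenset[str] = frozenset()
            for ch in node.child_nodes():
                s = s | below[id(ch)]
            below[id(node)] = s
        if node.parent_node is not None:
            sets.append(below[id(node)])
    return sets


def bipartitions(tree: dendropy.Tree, include_trivial: bool = False) -> set[Bipartition]:
    """Splits of a tree, one per edge in the unrooted view.

    By default only informative splits (both sides >= 2, i.e. internal
    edges) are returned, so a star tree yields the empty set.  With
    ``include_trivial=True`` the pendant (single-leaf) splits are kept as
    well.  Duplicate splits arising from a degree-2 root collapse to one.
    """
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    out: set[Bipartition] = set()
    for side in _leaf_sets_below_edges(tree):
        other = all_leaves - side
        if not side or not other:
            continue
        if include_trivial or (len(side) >= 2 and len(other) >= 2):
            out.add(Bipartition.from_sets(side, other))
    return out


def _require_same_leaves(t1: dendropy.Tree, t2: dendropy.Tree) -> frozenset[str]:
    l1 = frozenset(leaf.taxon.label for leaf in t1.leaf_node_iter())
    l2 = frozenset(leaf.taxon.label for leaf in t2.leaf_node_iter())
    if l1 != l2:
        only1 = sorted(l1 - l2)
        only2 = sorted(l2 - l1)
        raise ValueError(
            f"leaf sets differ: only in first tree {only1}, only in second tree {only2}"
        )
    return l1


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric distance: |S1 ^ S2| over informative splits."""
    _require_same_leaves(t1, t2)
    s1 = bipartitions(t1)
    s2 = bipartitions(t2)
    return len(s1 ^ s2)


def _edge_matrix(splits: set[Bipartition], order: dict[str, int]) -> np.ndarray:
    """Boolean (n_edges, n_leaves) matrix; row = membership of the first side."""
    mat = np.zeros((len(splits), len(order)), dtype=bool)
    for r, bp in enumerate(sorted(splits, key=lambda b: (b.first, b.second))):
        for lab in bp.first:
            mat[r, order[lab]] = True
    return mat


def edge_score_matrix(
    t1: dendropy.Tree, t2: dendropy.Tree, include_trivial: bool = False
) -> np.ndarray:
    """Pairwise edge-alignment scores between the edges of two trees.

    The score of a pair of edges is the better of the two ways of pairing
    their sides, each pairing scored by the worse of its two Jaccard
    overlaps: max over pairings of min(|A1&A2|/|A1|A2|, |B1&B2|/|B1|B2|).
    """
    leaves = _require_same_leaves(t1, t2)
    order = {lab: k for k, lab in enumerate(sorted(leaves))}
    a1 = _edge_matrix(bipartitions(t1, include_trivial), order).astype(np.int64)
    a2 = _edge_matrix(bipartitions(t2, include_trivial), order).astype(np.int64)
    if a1.shape[0] == 0 or a2.shape[0] == 0:
        return np.zeros((a1.shape[0], a2.shape[0]))
    b1 = 1 - a1
    b2 = 1 - a2

    def jacc(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        inter = u @ v.T
        union = u.sum(axis=1)[:, None] + v.sum(axis=1)[None, :] - inter
        return inter / union

    same = np.minimum(jacc(a1, a2), jacc(b1, b2))
    swap = np.minimum(jacc(a1, b2), jacc(b1, a2))
    return np.maximum(same, swap)


def topology_similarity(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Edge-matching topology similarity in [0, 1].

    Maximum-weight one-to-one matching over *all* edges of the unrooted
    view — pendant edges included, as in Nye-style tree alignment —
    under the Jaccard side score, normalised by the larger edge count.
    Pendant edges of the same leaf always match at score 1, so the score
    of two n-leaf trees never collapses to 0; it equals 1 iff the
    informative split sets are identical.  Two trees with no internal
    structure at all (stars) score exactly 1.
    """
    s = edge_score_matrix(t1, t2, include_trivial=True)
    m1, m2 = s.shape
    if m1 == 0 and m2 == 0:
        return 1.0
    if m1 == 0 or m2 == 0:
        return 0.0
    rows, cols = linear_sum_assignment(s, maximize=True)
    return float(s[rows, cols].sum() / max(m1, m2))
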