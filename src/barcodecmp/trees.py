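"""Distance-based tree inference (NJ, UPGMA) and Newick I/O.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package: NJ returns an unrooted tree with a trifurcating seed node,
UPGMA a rooted ultrametric tree.  Both algorithms are deterministic:
ties in the NJ Q-criterion and in the UPGMA minimum search are broken
toward the lowest (row, column) pair in node-creation order (leaves in
input-label order, merged clusters in order of creation), and negative
intermediate NJ branch lengths are clamped to zero.
"""

from __future__ import annotations

import dendropy
import numpy as np

from barcodecmp.compdist import DistanceMatrix

__all__ = ["nj", "upgma", "read_newick", "write_newick", "leaf_labels", "is_ultrametric"]


def _check_matrix(m: DistanceMatrix) -> np.ndarray:
    d = np.asarray(m.values, dtype=float)
    if len(m) < 3:
        raise ValueError("tree inference requires at least 3 taxa")
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return d.copy()


def _new_leaf_nodes(labels, namespace):
    nodes = []
    for lab in labels:
        taxon = namespace.require_taxon(label=lab)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    return nodes


def _masked_argmin(mat: np.ndarray, active: list[int]) -> tuple[int, int]:
    """Row-major argmin over the strict upper triangle restricted to *active*.

    *active* is kept in ascending node-creation order, so first occurrence
    in row-major order is the lowest (row, column) pair.
    """
    sub = mat[np.ix_(active, active)]
    iu = np.triu_indices(len(active), k=1)
    flat = sub[iu]
    k = int(np.argmin(flat))
    return active[iu[0][k]], active[iu[1][k]]


def nj(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Returns an unrooted tree (trifurcating seed node) whose leaves are
    exactly the matrix labels.
    """
    d0 = _check_matrix(m)
    n = len(m)
    ns = dendropy.TaxonNamespace()
    nodes = _new_leaf_nodes(m.labels, ns)

    # grow the working matrix; new cluster rows are appended
    size = 2 * n - 2
    d = np.zeros((size, size))
    d[:n, :n] = d0
    active = list(range(n))
    next_id = n

    while len(active) > 3:
        N = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (N - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(N, k=1)
        k = int(np.argmin(q[iu]))
        ai, aj = iu[0][k], iu[1][k]
        i, j = active[ai], active[aj]

        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (N - 2))
        vj = dij - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)

        parent = dendropy.Node()
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)

        for a in active:
            if a in (i, j):
                continue
            duk = 0.5 * (d[i, a] + d[j, a] - dij)
            d[next_id, a] = d[a, next_id] = max(duk, 0.0)
        active = [a for a in active if a not in (i, j)] + [next_id]
        active.sort()
        next_id += 1

    # final three-way join
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.edge.length = max(ln, 0.0)
        root.add_child(node)

    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def upgma(m: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration; rooted ultrametric tree.

    Cluster heights are half the average-linkage distance; edge lengths
    are height differences, so root-to-leaf path lengths are equal.
    """
    d0 = _check_matrix(m)
    n = len(m)
    ns = dendropy.TaxonNamespace()
    nodes = _new_leaf_nodes(m.labels, ns)

    size = 2 * n - 1
    d = np.zeros((size, size))
    d[:n, :n] = d0
    heights = [0.0] * size
    sizes = [1] * size
    active = list(range(n))
    next_id = n

    while len(active) > 1:
        i, j = _masked_argmin(d, active)
        h = d[i, j] / 2.0
        parent = dendropy.Node()
        nodes[i].edge.length = max(h - heights[i], 0.0)
        nodes[j].edge.length = max(h - heights[j], 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]

        for a in active:
            if a in (i, j):
                continue
            duk = (sizes[i] * d[i, a] + sizes[j] * d[j, a]) / (sizes[i] + sizes[j])
            d[next_id, a] = d[a, next_id] = duk
        active = [a for a in active if a not in (i, j)] + [next_id]
        active.sort()
        next_id += 1

    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[active[0]])
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialise to Newick (branch lengths at full precision).

    If *path* is given the string is also written to that file.
    """
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=False,
        real_value_format_specifier=".17g",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def read_newick(text_or_path) -> dendropy.Tree:
    """Parse a Newick string (or file path ending in .nwk/.tre/.newick)."""
    src = str(text_or_path)
    kwargs = dict(schema="newick", preserve_underscores=True)
    try:
        if src.lstrip().startswith("(") or src.rstrip().endswith(";"):
            return dendropy.Tree.get(data=src, **kwargs)
        return dendropy.Tree.get(path=src, **kwargs)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick input: {exc}") from exc


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    """True if all root-to-leaf path lengths agree within *rel_tol* (relative)."""
    depths = []
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        depths.append(depth)
    dmax = max(depths)
    if dmax == 0:
        return True
    return (dmax - min(depths)) <= rel_tol * dmax
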