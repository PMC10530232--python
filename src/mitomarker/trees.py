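"""Distance-based phylogenetic trees: Saitou-Nei neighbor joining.

Trees are `dendropy.Tree` objects (unrooted; the seed node is the final
trifurcation).  The agglomeration itself is implemented here because the
pipeline's outputs must be bit-reproducible: ties in the Q-criterion are
broken by the lowest (i, j) index pair, and negative branch lengths are
clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal over ordered ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise TreeError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise TreeError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise TreeError("distance matrix diagonal is not zero")
        finite = v[np.isfinite(v)]
        if np.any(finite < 0):
            raise TreeError("negative distances")
        self.values = v

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.values):
                fh.write(name.replace(" ", "_")[:50].ljust(52))
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining with the standard Q-criterion.

    Deterministic: among equal-Q pairs the lowest (i, j) in row-major order
    wins.  Negative branch lengths are clamped to 0.  Requires >= 3 taxa and
    finite distances.
    """
    n = len(dm.ids)
    if n < 3:
        raise TreeError("neighbor joining requires at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise TreeError("distance matrix contains undefined entries")

    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)
    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = (np.inf, -1, -1)
        for ai in range(k):
            for aj in range(ai + 1, k):
                q = (k - 2) * sub[ai, aj] - r[ai] - r[aj]
                if q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = max(0.0, li)
        nodes[j].edge.length = max(0.0, lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for am in range(k):
            m = active[am]
            if m in (i, j):
                continue
            new_row[m] = 0.5 * (D[i, m] + D[j, m] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [m for m in active if m not in (i, j)] + [D.shape[0] - 1]

    a, b, c = active
    center = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.edge.length = max(0.0, ln)
        center.add_child(node)
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def leaf_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side)."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = frozenset(labels - side)
        if 1 < len(side) < len(labels) - 1:
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    return leaf_splits(t1) == leaf_splits(t2)


def patristic_distances(tree: dendropy.Tree, leaf: str) -> dict[str, float]:
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    t0 = tns.get_taxon(leaf)
    return {t.label: pdm.patristic_distance(t0, t)
            for t in tns if t.label != leaf}


def nearest_leaf(tree: dendropy.Tree, leaf: str) -> str:
    """The leaf's sister taxon: its cherry partner when it sits in a cherry,
    otherwise the leaf at minimal patristic distance (ties alphabetical)."""
    target = None
    for node in tree.leaf_node_iter():
        if node.taxon.label == leaf:
            target = node
            break
    if target is None:
        raise TreeError(f"leaf {leaf!r} not in tree")
    parent = target.parent_node
    if parent is not None:
        siblings = [c for c in parent.child_nodes() if c is not target]
        leaf_sibs = sorted(c.taxon.label for c in siblings if c.is_leaf())
        if leaf_sibs:
            return leaf_sibs[0]
    dists = patristic_distances(tree, leaf)
    return min(sorted(dists), key=lambda k: dists[k])
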