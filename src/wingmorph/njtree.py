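"""Neighbor-joining trees from morphometric (Mahalanobis) distance matrices.

The tree is built by the classical Saitou-Nei agglomeration and decorated with
bootstrap supports obtained by resampling specimens with replacement within
each taxon, recomputing group means, the pooled within-group covariance, and
the Mahalanobis distance matrix in the fixed global superimposition/PC space,
and rebuilding the tree.  Supports are the percentage of replicates containing
each internal bipartition.  The tree illustrates taxon segregation patterns in
shape space; it is not an evolutionary hypothesis.

Trees are held as :mod:`dendropy` trees (Newick serializable, with supports as
internal node labels); negative NJ branch-length estimates are clamped to zero
and the clamped deficit recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .cva_classify import _group_stats, _mahalanobis_matrix, _ordered_groups, _pca_reduce
from .gpa import ProcrustesResult

logger = logging.getLogger(__name__)


@dataclass
class MorphoTree:
    """A (possibly bootstrapped) morphometric tree.

    ``tree`` is a dendropy tree whose internal node labels carry bootstrap
    percentages (when ``n_bootstrap > 0``); ``clamped_length`` is the total
    negative branch length clamped to zero during NJ.
    """

    tree: dendropy.Tree
    n_bootstrap: int = 0
    seed: int | None = None
    clamped_length: float = 0.0

    @property
    def taxa(self) -> list:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def supports(self) -> dict:
        """Map frozenset(leaf labels) -> bootstrap percent for internal edges."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            out[leaves] = float(node.label)
        return out

    def bipartitions(self) -> set:
        """Unrooted internal bipartitions as frozensets of the smaller side."""
        all_taxa = frozenset(self.taxa)
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            other = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def is_monophyletic(self, labels) -> bool:
        """Whether ``labels`` form a clade on the unrooted tree (i.e. the
        bipartition labels-vs-rest exists or labels are a trivial split)."""
        want = frozenset(labels)
        all_taxa = frozenset(self.taxa)
        if not want <= all_taxa:
            raise ValueError("labels not all present in tree")
        if len(want) <= 1 or len(all_taxa - want) <= 1:
            return True
        comp = all_taxa - want
        target = min(want, comp, key=lambda s: (len(s), sorted(s)))
        return target in self.bipartitions()


def _validate_distance_matrix(dist: np.ndarray):
    dist = np.asarray(dist, float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(dist < 0):
        raise ValueError("distance matrix must be nonnegative")
    return dist


def neighbor_joining(dist: np.ndarray, taxa,
                     taxon_namespace: dendropy.TaxonNamespace | None = None) -> MorphoTree:
    """Classical Saitou-Nei neighbor joining.

    Q-criterion ties are broken by the smallest (i, j) index pair; negative
    branch-length estimates are clamped to zero with the deficit logged.
    """
    dist = _validate_distance_matrix(dist).copy()
    taxa = list(taxa)
    n0 = len(taxa)
    if dist.shape[0] != n0:
        raise ValueError("taxa list does not match matrix size")
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(taxa)
    nodes = [dendropy.Node(taxon=taxon_namespace.get_taxon(t)) for t in taxa]
    clamped = 0.0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = dist.sum(axis=1)
        q = (n - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(n)] = np.inf
        # row-major argmin gives the lexicographically smallest (i, j) on ties
        i, j = np.unravel_index(np.argmin(q), q.shape)
        d_ij = dist[i, j]
        li = d_ij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d_ij - li
        parent = dendropy.Node()
        nodes[i].edge.length = _clamp(li)
        nodes[j].edge.length = _clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_d = (dist[i] + dist[j] - d_ij) / 2.0
        keep = [x for x in range(n) if x not in (i, j)]
        dist = np.vstack([dist[keep][:, keep],
                          new_d[keep][None, :]])
        dist = np.hstack([dist, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    # resolve the final three lineages around an unrooted central node
    d12, d13, d23 = dist[0, 1], dist[0, 2], dist[1, 2]
    lengths = [(d12 + d13 - d23) / 2.0,
               (d12 + d23 - d13) / 2.0,
               (d13 + d23 - d12) / 2.0]
    root = dendropy.Node()
    for node, length in zip(nodes, lengths):
        node.edge.length = _clamp(length)
        root.add_child(node)

    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=root)
    tree.is_rooted = False
    if clamped > 0:
        logger.info("NJ clamped %.6g of negative branch length to zero", clamped)
    return MorphoTree(tree=tree, clamped_length=clamped)


def mahalanobis_matrix_from_groups(proc: ProcrustesResult, grouping: str,
                                   variance_retained: float = 0.99):
    """Mahalanobis distance matrix among group means (taxa in first-appearance
    order), plus the reduced scores and labels used to compute it."""
    labels = proc.group_labels(grouping)
    taxa = _ordered_groups(labels)
    y, _, _ = _pca_reduce(proc.tangent_coords, len(taxa), variance_retained)
    means, pooled = _group_stats(y, labels, taxa)
    return _mahalanobis_matrix(means, pooled), taxa, y, labels


def bootstrap_tree(proc: ProcrustesResult, grouping: str = "species",
                   n_bootstrap: int = 1000, seed: int | None = 0,
                   outgroup: str | None = None,
                   variance_retained: float = 0.99) -> MorphoTree:
    """Neighbor-joining tree of group Mahalanobis distances with bootstrap.

    Each replicate resamples specimens with replacement within every taxon and
    recomputes means, pooled covariance, and the distance matrix in the fixed
    global superimposition/PC space.  Support = percent of replicates
    containing each internal bipartition.  When ``outgroup`` is given, the
    returned tree is rooted at the midpoint of the outgroup's terminal edge.
    """
    dist, taxa, y, labels = mahalanobis_matrix_from_groups(
        proc, grouping, variance_retained)
    if outgroup is not None and outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not among taxa {taxa}")
    counts = {t: int((labels == t).sum()) for t in taxa}
    small = [t for t, c in counts.items() if c < 3]
    if small:
        raise ValueError(f"taxa too small to resample (<3 specimens): {small}")

    point = neighbor_joining(dist, taxa)
    if outgroup is not None:
        # root before attaching supports: rerooting re-wires parent/child
        # relations, which would detach labels from their bipartitions
        _root_on_outgroup(point.tree, outgroup)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        idx_by_taxon = {t: np.flatnonzero(labels == t) for t in taxa}
        counter: dict = {}
        for _ in range(n_bootstrap):
            rows = []
            lab = []
            for t in taxa:
                take = rng.choice(idx_by_taxon[t], size=counts[t], replace=True)
                rows.append(y[take])
                lab.extend([t] * counts[t])
            yb = np.vstack(rows)
            labb = np.array(lab)
            means, pooled = _group_stats(yb, labb, taxa)
            try:
                db = _mahalanobis_matrix(means, pooled)
            except np.linalg.LinAlgError:
                continue  # degenerate resample; skip
            rep = neighbor_joining(db, taxa)
            for bip in rep.bipartitions():
                counter[bip] = counter.get(bip, 0) + 1
        all_taxa = frozenset(taxa)
        for node in point.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if not (1 < len(side) < len(all_taxa) - 1):
                continue
            key = min(side, all_taxa - side, key=lambda s: (len(s), sorted(s)))
            node.label = f"{100.0 * counter.get(key, 0) / n_bootstrap:g}"

    point.n_bootstrap = n_bootstrap
    point.seed = seed
    return point


def _root_on_outgroup(tree: dendropy.Tree, outgroup: str):
    """Root the tree at the midpoint of the outgroup's terminal edge."""
    leaf = next(l for l in tree.leaf_node_iter() if l.taxon.label == outgroup)
    length = leaf.edge.length or 0.0
    tree.reroot_at_edge(leaf.edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)
    tree.is_rooted = True


def write_newick(tree: MorphoTree, path) -> None:
    """Serialize to Newick with branch lengths and internal support labels."""
    from pathlib import Path

    Path(path).write_text(tree.newick() + "\n")


def read_newick(path) -> MorphoTree:
    """Read a Newick tree (supports parsed from internal node labels)."""
    t = dendropy.Tree.get(path=str(path), schema="newick",
                          suppress_internal_node_taxa=True,
                          preserve_underscores=True)
    return MorphoTree(tree=t)
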