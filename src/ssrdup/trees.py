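"""Distance-based dendrograms with column-bootstrap branch support.

Trees are built from the raw band-difference counts (not proportions):
UPGMA produces a rooted ultrametric dendrogram in which every merge sits at
half the average between-cluster difference, and neighbor joining produces an
unrooted tree by the standard Q-criterion with negative branch-length
estimates clamped to zero.  Both use deterministic lowest-index tie-breaking
so identical inputs give identical trees.

Branch support is estimated by resampling the fragment columns of the band
matrix with replacement, recomputing pairwise-deletion differences, and
rebuilding the tree for each replicate; the support of an internal edge of
the point-estimate tree is the percentage of replicate trees containing the
same leaf bipartition (same clade, for rooted UPGMA trees).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import dendropy
import numpy as np

from .distances import DistanceResult, pairwise_differences
from .matrix import ABSENT, BandMatrix, PRESENT


class TreeError(ValueError):
    """Raised on invalid tree-construction input."""


@dataclass
class SupportedTree:
    """A dendrogram with branch lengths and optional bootstrap supports.

    Attributes
    ----------
    tree
        dendropy tree; internal nodes carry a ``support`` attribute
        (percentage, ``None`` when unset).
    rooted
        True for UPGMA dendrograms, False for NJ trees (whose seed node is
        an arbitrary trifurcation).
    n_replicates
        Bootstrap replicate count behind the supports, or ``None``.
    log
        Run notes: clamped negative branch-length deficit, redrawn
        bootstrap replicates.
    """

    tree: dendropy.Tree
    rooted: bool
    n_replicates: int | None = None
    log: dict = field(default_factory=dict)

    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def supported_nodes(self) -> list[dendropy.Node]:
        """Internal non-root nodes, i.e. those that can carry support."""
        return [
            nd
            for nd in self.tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]

    def supports(self) -> dict[frozenset[str], float | None]:
        """Map from (normalised) leaf set per internal edge to support."""
        ref = min(self.leaf_labels())
        out: dict[frozenset[str], float | None] = {}
        for nd in self.supported_nodes():
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            key = below if self.rooted else _normalise(below, self.leaf_labels(), ref)
            out[key] = getattr(nd, "support", None)
        return out

    def root_to_leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            h = 0.0
            nd = leaf
            while nd.parent_node is not None:
                h += nd.edge.length or 0.0
                nd = nd.parent_node
            depths[leaf.taxon.label] = h
        return depths


def _normalise(side: frozenset[str], all_labels: set[str], ref: str) -> frozenset[str]:
    """Canonical side of an unrooted bipartition: the one without ``ref``."""
    return frozenset(all_labels - side) if ref in side else side


def _check_square(d: DistanceResult) -> np.ndarray:
    D = np.asarray(d.diff_counts, dtype=float)
    if D.shape != (d.n, d.n):
        raise TreeError("distance matrix must be square over the accession ids")
    if not np.allclose(D, D.T):
        raise TreeError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise TreeError("distance matrix must have a zero diagonal")
    return D


# ---------------------------------------------------------------------------
# UPGMA

def _upgma_merges(D: np.ndarray) -> list[tuple[int, int, float]]:
    """Average-linkage merge list: (node_a, node_b, height).

    Leaves are nodes ``0..n-1``; merge ``k`` creates node ``n+k``.  Ties are
    broken toward the lowest (row, column) pair, scanning row-major.
    """
    n = D.shape[0]
    W = D.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    node = list(range(n))
    size = [1] * n
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        i, j = divmod(int(np.argmin(W)), n)
        merges.append((node[i], node[j], W[i, j] / 2.0))
        ni, nj = size[i], size[j]
        newrow = (ni * W[i] + nj * W[j]) / (ni + nj)
        W[i, :] = newrow
        W[:, i] = newrow
        W[i, i] = np.inf
        W[j, :] = np.inf
        W[:, j] = np.inf
        node[i] = n + step
        size[i] = ni + nj
    return merges


def _merge_leafsets(n: int, merges: list[tuple[int, int, float]]) -> list[set[int]]:
    sets: list[set[int]] = [{i} for i in range(n)]
    for a, b, _ in merges:
        sets.append(sets[a] | sets[b])
    return sets


def _upgma_clades(D: np.ndarray, labels: list[str]) -> set[frozenset[str]]:
    """Leaf sets of all non-root internal nodes of the UPGMA tree of D."""
    n = len(labels)
    merges = _upgma_merges(D)
    sets = _merge_leafsets(n, merges)
    return {
        frozenset(labels[i] for i in sets[n + k])
        for k in range(len(merges) - 1)  # last merge is the root
    }


def upgma(d: DistanceResult) -> SupportedTree:
    """Rooted average-linkage (UPGMA) dendrogram; supports unset.

    Node heights are half the average between-cluster difference at the
    merge, so the tree is ultrametric in difference units.
    """
    D = _check_square(d)
    if d.n < 2:
        raise TreeError("UPGMA needs at least 2 accessions")
    labels = d.accession_ids
    merges = _upgma_merges(D)
    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[int, dendropy.Node] = {}
    height: dict[int, float] = {}
    for i, lab in enumerate(labels):
        nodes[i] = dendropy.Node(taxon=tns.get_taxon(lab))
        height[i] = 0.0
    for k, (a, b, h) in enumerate(merges):
        parent = dendropy.Node()
        parent.support = None
        for child in (a, b):
            nodes[child].edge.length = h - height[child]
            parent.add_child(nodes[child])
        nodes[len(labels) + k] = parent
        height[len(labels) + k] = h
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[len(labels) + len(merges) - 1]
    tree.is_rooted = True
    return SupportedTree(tree=tree, rooted=True)


# ---------------------------------------------------------------------------
# Neighbor joining

def _nj_join_order(
    D: np.ndarray,
) -> tuple[list[tuple[int, int, float, float]], list[int], list[float], float]:
    """Pair joins until three clusters remain.

    Returns (joins, final cluster ids, final 3x3 distances flattened, clamped
    deficit).  Join ``k`` of clusters (a, b) creates cluster ``n+k`` with the
    recorded child branch lengths.  Ties break to the lowest (row, column).
    """
    n = D.shape[0]
    M = D.astype(float).copy()
    ids = list(range(n))
    joins: list[tuple[int, int, float, float]] = []
    deficit = 0.0
    nxt = n
    while len(ids) > 3:
        m = len(ids)
        r = M.sum(axis=1)
        Q = (m - 2) * M - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        dij = M[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            deficit += -li
            li = 0.0
        if lj < 0:
            deficit += -lj
            lj = 0.0
        joins.append((ids[i], ids[j], li, lj))
        dnew = 0.5 * (M[i] + M[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        M2 = np.empty((m - 1, m - 1))
        M2[:-1, :-1] = M[np.ix_(keep, keep)]
        M2[:-1, -1] = dnew[keep]
        M2[-1, :-1] = dnew[keep]
        M2[-1, -1] = 0.0
        M = M2
        ids = [ids[k] for k in keep] + [nxt]
        nxt += 1
    return joins, ids, M, deficit


def _nj_structure(
    D: np.ndarray,
) -> tuple[dict[int, list[tuple[int, float]]], int, float]:
    """Full NJ adjacency: children per internal node, root id, clamp deficit."""
    n = D.shape[0]
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 accessions")
    children: dict[int, list[tuple[int, float]]] = {}
    if n == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lengths = [
            (d01 + d02 - d12) / 2.0,
            (d01 + d12 - d02) / 2.0,
            (d02 + d12 - d01) / 2.0,
        ]
        deficit = sum(-x for x in lengths if x < 0)
        children[3] = [(k, max(0.0, lengths[k])) for k in range(3)]
        return children, 3, deficit
    joins, ids, M3, deficit = _nj_join_order(D)
    nxt = n
    for a, b, la, lb in joins:
        children[nxt] = [(a, la), (b, lb)]
        nxt += 1
    a, b, c = ids
    la = (M3[0, 1] + M3[0, 2] - M3[1, 2]) / 2.0
    lb = (M3[0, 1] + M3[1, 2] - M3[0, 2]) / 2.0
    lc = (M3[0, 2] + M3[1, 2] - M3[0, 1]) / 2.0
    for x in (la, lb, lc):
        if x < 0:
            deficit += -x
    children[nxt] = [(a, max(0.0, la)), (b, max(0.0, lb)), (c, max(0.0, lc))]
    return children, nxt, deficit


def _leafset(children: dict[int, list[tuple[int, float]]], node: int, n: int) -> set[int]:
    if node < n:
        return {node}
    out: set[int] = set()
    stack = [node]
    while stack:
        x = stack.pop()
        if x < n:
            out.add(x)
        else:
            stack.extend(c for c, _ in children[x])
    return out


def _nj_biparts(D: np.ndarray, labels: list[str]) -> set[frozenset[str]]:
    """Normalised internal-edge bipartitions of the NJ tree of D."""
    n = len(labels)
    children, root, _ = _nj_structure(D)
    all_labels = set(labels)
    ref = min(all_labels)
    out: set[frozenset[str]] = set()
    for node in children:
        if node == root:
            continue
        side = frozenset(labels[i] for i in _leafset(children, node, n))
        out.add(_normalise(side, all_labels, ref))
    return out


def neighbor_joining(d: DistanceResult) -> SupportedTree:
    """Unrooted neighbor-joining tree; supports unset.

    Negative branch-length estimates (possible on non-additive data) are
    clamped to zero; the total clamped length is reported in
    ``log["clamped_negative_length"]``.
    """
    D = _check_square(d)
    labels = d.accession_ids
    children, root, deficit = _nj_structure(D)
    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[int, dendropy.Node] = {
        i: dendropy.Node(taxon=tns.get_taxon(lab)) for i, lab in enumerate(labels)
    }
    for node in sorted(children):
        parent = dendropy.Node()
        parent.support = None
        for child, length in children[node]:
            nodes[child].edge.length = length
            parent.add_child(nodes[child])
        nodes[node] = parent
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[root]
    tree.is_rooted = False
    return SupportedTree(
        tree=tree, rooted=False, log={"clamped_negative_length": float(deficit)}
    )


# ---------------------------------------------------------------------------
# Bootstrap

def _diff_matrix(P: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    diff = P @ A.T
    diff = diff + diff.T
    scored = P + A
    compared = scored @ scored.T
    np.fill_diagonal(diff, 0)
    return diff, compared


def bootstrap_support(
    m: BandMatrix,
    method: str = "upgma",
    n_replicates: int = 500,
    seed: int = 0,
    max_redraws: int | None = None,
) -> SupportedTree:
    """Point-estimate tree with column-bootstrap branch supports.

    Fragment columns are resampled with replacement (same count) for each
    replicate; replicates in which some accession pair loses every mutually
    scored band are rejected and redrawn (counted in
    ``log["redrawn_replicates"]``).  Support of each internal edge of the
    point tree is the percentage of replicates whose tree contains the same
    clade (UPGMA) or unrooted leaf bipartition (NJ).
    """
    if n_replicates < 1:
        raise TreeError("n_replicates must be >= 1")
    if method not in ("upgma", "nj"):
        raise TreeError(f"unknown tree method {method!r}")
    d = pairwise_differences(m)
    point = upgma(d) if method == "upgma" else neighbor_joining(d)

    labels = m.accession_ids
    replicate_sets: Callable[[np.ndarray], set[frozenset[str]]] = (
        (lambda D: _upgma_clades(D, labels))
        if method == "upgma"
        else (lambda D: _nj_biparts(D, labels))
    )

    P = (m.cells == PRESENT).astype(np.int32)
    A = (m.cells == ABSENT).astype(np.int32)
    n, M = P.shape
    off_diag = ~np.eye(n, dtype=bool)
    rng = np.random.default_rng(seed)
    if max_redraws is None:
        max_redraws = 100 + 10 * n_replicates

    counts: dict[frozenset[str], int] = {}
    done = 0
    redrawn = 0
    while done < n_replicates:
        cols = rng.integers(0, M, size=M)
        diff, compared = _diff_matrix(P[:, cols], A[:, cols])
        if ((compared == 0) & off_diag).any():
            redrawn += 1
            if redrawn > max_redraws:
                raise TreeError(
                    "too many bootstrap replicates rejected for zero-overlap pairs"
                )
            continue
        for s in replicate_sets(diff.astype(float)):
            counts[s] = counts.get(s, 0) + 1
        done += 1

    all_labels = set(labels)
    ref = min(all_labels)
    for nd in point.supported_nodes():
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        key = below if method == "upgma" else _normalise(below, all_labels, ref)
        nd.support = 100.0 * counts.get(key, 0) / n_replicates
    point.n_replicates = n_replicates
    point.log["redrawn_replicates"] = redrawn
    return point


# ---------------------------------------------------------------------------
# Collapse and serialisation

def _copy_tree(t: SupportedTree) -> SupportedTree:
    tns = t.tree.taxon_namespace

    def clone(nd: dendropy.Node) -> dendropy.Node:
        new = dendropy.Node(taxon=nd.taxon)
        new.edge.length = nd.edge.length
        new.support = getattr(nd, "support", None)
        for child in nd.child_nodes():
            new.add_child(clone(child))
        return new

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = clone(t.tree.seed_node)
    tree.is_rooted = t.rooted
    return SupportedTree(
        tree=tree,
        rooted=t.rooted,
        n_replicates=t.n_replicates,
        log=dict(t.log),
    )


def collapse_branches(t: SupportedTree, min_support: float = 75.0) -> SupportedTree:
    """Contract internal edges with support below ``min_support`` into polytomies.

    The leaf set is unchanged and surviving supports are untouched; the
    collapsed edge's length is absorbed (the children attach to the former
    grandparent with their own lengths).
    """
    out = _copy_tree(t)
    weak = [
        nd
        for nd in out.tree.postorder_node_iter()
        if not nd.is_leaf()
        and nd.parent_node is not None
        and getattr(nd, "support", None) is not None
        and nd.support < min_support
    ]
    for nd in weak:
        nd.edge.collapse()
    return out


def to_newick(t: SupportedTree) -> str:
    """Newick string: branch lengths plus integer supports as internal labels.

    Round-trips through any standard Newick parser to an isomorphic tree.
    """
    for nd in t.tree.preorder_node_iter():
        if not nd.is_leaf():
            sup = getattr(nd, "support", None)
            nd.label = str(int(round(sup))) if sup is not None else None
    return t.tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip() + "\n"


def ascii_sketch(t: SupportedTree) -> str:
    """Plain-text dendrogram sketch (for terminal inspection)."""
    return t.tree.as_ascii_plot(plot_metric="length")
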