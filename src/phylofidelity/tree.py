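"""Rooted time-calibrated phylogenies and the distance/covariance primitives.

The :class:`Phylogeny` is an array-backed rooted tree with branch lengths in
time units.  Nodes are stored in preorder (the root is node 0 and every node's
parent precedes it), which lets every traversal be a plain forward or backward
loop over ``range(n_nodes)``.  Polytomies are allowed; branch lengths may be
absent (recorded as NaN, never silently 0).

Newick parsing and serialisation are delegated to :mod:`dendropy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "CovarianceMatrix",
    "read_newick",
    "write_newick",
    "patristic_distances",
    "phylo_covariance",
    "prune_to_tips",
    "root_age",
]


class NewickParseError(ValueError):
    """Raised when a newick string cannot be interpreted as a rooted tree."""


@dataclass
class Phylogeny:
    """Rooted tree; node 0 is the root and ``parent[i] < i`` for all i > 0.

    Parameters
    ----------
    parent
        Integer array, ``parent[0] == -1`` for the root.
    blen
        Branch length of the edge above each node (time units); NaN marks an
        absent length.  ``blen[0]`` is ignored.
    labels
        One entry per node; tips must carry unique non-empty labels, internal
        labels are optional and preserved but otherwise unused.
    """

    parent: np.ndarray
    blen: np.ndarray
    labels: list

    children: list = field(init=False, repr=False)
    tip_ids: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=np.float64)
        n = self.parent.size
        if n == 0 or self.parent[0] != -1:
            raise ValueError("node 0 must be the root (parent -1)")
        if n > 1 and not np.all(self.parent[1:] < np.arange(1, n)):
            raise ValueError("nodes must be in preorder (parent index < child index)")
        self.children = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.tip_ids = np.array(
            [i for i in range(n) if not self.children[i]], dtype=np.int64
        )
        tips = [self.labels[i] for i in self.tip_ids]
        if any(t is None or t == "" for t in tips):
            raise ValueError("every tip must carry a non-empty label")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_ids]

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def has_lengths(self) -> bool:
        return not np.isnan(self.blen[1:]).any() if self.n_nodes > 1 else True

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.blen.copy(), list(self.labels))

    # ------------------------------------------------------------ time-related
    def _require_lengths(self) -> None:
        if not self.has_lengths():
            raise ValueError(
                "tree has absent branch lengths; date the tree first "
                "(e.g. with bladj_date)"
            )

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        self._require_lengths()
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.blen[i]
        return depth

    def root_age(self) -> float:
        """Maximum root-to-tip distance (= every tip's depth when ultrametric)."""
        return float(self.node_depths()[self.tip_ids].max())

    def node_ages(self) -> np.ndarray:
        """Age of each node measured back from the deepest tip."""
        depth = self.node_depths()
        return float(depth[self.tip_ids].max()) - depth

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        depths = self.node_depths()[self.tip_ids]
        t = depths.max()
        if t == 0:
            return True
        return bool((depths.max() - depths.min()) <= rtol * t)

    def polytomy_count(self) -> int:
        """Number of internal nodes with more than two children."""
        return sum(1 for ch in self.children if len(ch) > 2)

    # -------------------------------------------------------------- conversion
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [None] * self.n_nodes
        nodes[0] = tree.seed_node
        for i in range(1, self.n_nodes):
            nd = dendropy.Node()
            nodes[self.parent[i]].add_child(nd)
            nodes[i] = nd
        for i in range(self.n_nodes):
            nd = nodes[i]
            if i > 0 and not np.isnan(self.blen[i]):
                nd.edge.length = float(self.blen[i])
            if not self.children[i]:
                nd.taxon = taxa.new_taxon(label=str(self.labels[i]))
            elif self.labels[i]:
                nd.label = str(self.labels[i])
        return tree

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        seed = dtree.seed_node
        order = []
        stack = [seed]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(reversed(nd.child_nodes()))
        index = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.full(n, np.nan)
        labels: list = [None] * n
        for i, nd in enumerate(order):
            if nd is not seed:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = np.nan if nd.edge.length is None else float(nd.edge.length)
            if nd.is_leaf():
                labels[i] = None if nd.taxon is None else nd.taxon.label
            else:
                labels[i] = nd.label
        return cls(parent, blen, labels)


# ---------------------------------------------------------------------- I/O
def read_newick(text: str) -> Phylogeny:
    """Parse a single rooted newick string (must end in ';').

    Quoted labels are accepted, square-bracket comments ignored, duplicate tip
    labels rejected.  Missing branch lengths are recorded as absent, not 0.
    """
    if not text.strip().endswith(";"):
        raise NewickParseError("newick string must end in ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    # a bare leaf seed node with a stem edge gets an explicit root above it
    if dtree.seed_node.is_leaf() and dtree.seed_node.edge.length is not None:
        leaf = dtree.seed_node
        root = dendropy.Node()
        root.add_child(leaf)
        dtree.seed_node = root
    try:
        return Phylogeny.from_dendropy(dtree)
    except ValueError as exc:
        raise NewickParseError(str(exc)) from exc


def write_newick(tree: Phylogeny) -> str:
    """Serialise to newick with 10 significant digits; round-trips exactly
    enough that topology and lengths are preserved to well below 1e-9
    relative error."""
    s = tree.to_dendropy().as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
        unquoted_underscores=True,
    )
    return s.strip()


# ----------------------------------------------------------------- matrices
@dataclass
class DistanceMatrix:
    """Symmetric patristic (path-length) distances between tips."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=np.float64)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def index_of(self, labels) -> np.ndarray:
        return np.array([self._index[l] for l in labels], dtype=np.int64)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])


@dataclass
class CovarianceMatrix:
    """Brownian-motion covariance: C[i, j] = depth of MRCA(i, j) from the root.

    On an ultrametric tree the diagonal is constant and equals the root age T.
    """

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=np.float64)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def index_of(self, labels) -> np.ndarray:
        return np.array([self._index[l] for l in labels], dtype=np.int64)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])


def phylo_covariance(tree: Phylogeny) -> CovarianceMatrix:
    tree._require_lengths()
    depth = tree.node_depths()
    ntip = tree.n_tips
    pos = np.full(tree.n_nodes, -1, dtype=np.int64)
    pos[tree.tip_ids] = np.arange(ntip)
    C = np.zeros((ntip, ntip))
    # tips under each node, accumulated in postorder
    tipsets: list = [None] * tree.n_nodes
    for u in range(tree.n_nodes - 1, -1, -1):
        if tree.is_tip(u):
            tipsets[u] = [pos[u]]
            C[pos[u], pos[u]] = depth[u]
        else:
            groups = [tipsets[c] for c in tree.children[u]]
            for a in range(len(groups)):
                ga = np.asarray(groups[a])
                for b in range(a + 1, len(groups)):
                    gb = np.asarray(groups[b])
                    C[np.ix_(ga, gb)] = depth[u]
                    C[np.ix_(gb, ga)] = depth[u]
            merged = []
            for g in groups:
                merged.extend(g)
            tipsets[u] = merged
    return CovarianceMatrix(tuple(tree.tip_labels), C)


def patristic_distances(tree: Phylogeny) -> DistanceMatrix:
    """All pairwise tip-to-tip path lengths, via d(i,j) = C_ii + C_jj - 2 C_ij."""
    C = phylo_covariance(tree).values
    d = np.diag(C)[:, None] + np.diag(C)[None, :] - 2.0 * C
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0  # guard against -0.0 / float dust
    return DistanceMatrix(tuple(tree.tip_labels), d)


def root_age(tree: Phylogeny) -> float:
    return tree.root_age()


def prune_to_tips(tree: Phylogeny, keep) -> Phylogeny:
    """Induced subtree on ``keep``; unbranched internal nodes are suppressed
    with their branch lengths summed, so pairwise patristic distances and
    root-to-tip depths of the kept tips are unchanged.  The original root is
    retained even if it ends up with a single child."""
    keep = set(keep)
    tipset = set(tree.tip_labels)
    missing = sorted(keep - tipset)
    if missing:
        raise KeyError(f"labels not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("need at least 2 tips to keep")

    n = tree.n_nodes
    kept_tip = np.zeros(n, dtype=bool)
    for i in tree.tip_ids:
        kept_tip[i] = tree.labels[i] in keep
    ndesc = kept_tip.astype(np.int64).copy()
    for i in range(n - 1, 0, -1):
        ndesc[tree.parent[i]] += ndesc[i]
    cand = ndesc > 0
    nchild = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        if cand[i]:
            nchild[tree.parent[i]] += 1
    suppressed = cand & (nchild == 1) & ~kept_tip
    suppressed[0] = False

    # survivors in original preorder keep that relative order -> still preorder
    survivors = [i for i in range(n) if cand[i] and not suppressed[i]]
    survivors = [0] + [i for i in survivors if i != 0]
    newid = {u: k for k, u in enumerate(survivors)}
    parent = np.full(len(survivors), -1, dtype=np.int64)
    blen = np.full(len(survivors), np.nan)
    labels = [tree.labels[u] for u in survivors]
    for k, u in enumerate(survivors[1:], start=1):
        acc = tree.blen[u]
        p = tree.parent[u]
        while suppressed[p]:
            acc += tree.blen[p]
            p = tree.parent[p]
        parent[k] = newid[p]
        blen[k] = acc
    return Phylogeny(parent, blen, labels)
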