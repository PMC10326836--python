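"""Host phylogenies: Newick I/O, Pagel's lambda transform, covariances, Yule simulation.

The tree container is a flat array representation (parent pointers in
parent-before-child order) that makes branch-length surgery and covariance
assembly cheap; dendropy handles all Newick parsing and writing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "TreeValidationError",
    "read_newick",
    "parse_newick",
    "write_newick",
    "lambda_transform",
    "phylo_covariance",
    "node_covariance",
    "simulate_pure_birth",
    "prune_to",
    "rescale_depth",
]

#: relative tolerance (fraction of tree depth) for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree violates the model's structural requirements."""


@dataclass(frozen=True, eq=False)
class Phylogeny:
    """A rooted, ultrametric, bifurcating tree with branch lengths.

    Nodes are indexed 0..m-1 with the root at 0 and every parent preceding
    its children, so a single forward (or backward) pass is a valid
    pre-order (post-order) traversal.

    Attributes
    ----------
    parent : (m,) int array; ``parent[0] == -1`` for the root.
    blen : (m,) float array of branch lengths above each node; ``blen[0] == 0``.
    labels : per-node labels; every tip must be labelled, internal labels
        are optional and preserved through I/O.
    """

    parent: np.ndarray
    blen: np.ndarray
    labels: tuple
    _children: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=np.int64)
        blen = np.asarray(self.blen, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "blen", blen)
        kids: list[list[int]] = [[] for _ in range(parent.size)]
        for v in range(1, parent.size):
            kids[parent[v]].append(v)
        object.__setattr__(self, "_children", tuple(tuple(k) for k in kids))

    # -- structure -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def children(self, v: int) -> tuple:
        return self._children[v]

    @property
    def is_tip(self) -> np.ndarray:
        return np.array([len(k) == 0 for k in self._children])

    @property
    def tip_indices(self) -> np.ndarray:
        """Tip node indices in post-order sequence."""
        order = []
        stack = [0]
        while stack:
            v = stack.pop()
            if not self._children[v]:
                order.append(v)
            else:
                stack.extend(reversed(self._children[v]))
        return np.array(order, dtype=np.int64)

    @property
    def tip_labels(self) -> list:
        return [self.labels[v] for v in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def node_depths(self) -> np.ndarray:
        """Root-to-node distances."""
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.blen[v]
        return d

    @property
    def depth(self) -> float:
        """Root-to-tip distance (tree height) of an ultrametric tree."""
        return float(np.max(self.node_depths))

    # -- validation ----------------------------------------------------
    def validation_errors(self, require_ultrametric: bool = True) -> list:
        errs = []
        if self.n_tips < 2:
            errs.append(f"tree has {self.n_tips} tips; at least 2 required")
        labels = self.tip_labels
        if any(lb is None or lb == "" for lb in labels):
            errs.append("all tips must be labelled")
        if len(set(labels)) != len(labels):
            dup = sorted({lb for lb in labels if labels.count(lb) > 1})
            errs.append(f"duplicate tip labels: {dup}")
        if np.any(self.blen[1:] < 0):
            errs.append("negative branch lengths")
        for v in range(self.n_nodes):
            k = len(self._children[v])
            if k not in (0, 2):
                errs.append(f"node {self.labels[v] or v} has {k} children (polytomy or unifurcation)")
        if require_ultrametric:
            d = self.node_depths[self.tip_indices]
            T = float(np.max(d)) if d.size else 0.0
            if T > 0 and (np.max(d) - np.min(d)) > ULTRAMETRIC_RTOL * T:
                errs.append(
                    f"tree is not ultrametric: tip depths range over "
                    f"[{np.min(d):.6g}, {np.max(d):.6g}]"
                )
        return errs

    def validate(self, require_ultrametric: bool = True) -> "Phylogeny":
        errs = self.validation_errors(require_ultrametric)
        if errs:
            raise TreeValidationError("; ".join(errs))
        return self


@dataclass(frozen=True, eq=False)
class PhyloCovariance:
    """Brownian covariance among tips: shared root-to-MRCA path lengths."""

    matrix: np.ndarray
    tip_order: list

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))


# ---------------------------------------------------------------------
# dendropy bridge
# ---------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree, resolve_polytomies: bool = False) -> Phylogeny:
    if resolve_polytomies:
        dtree.resolve_polytomies()
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.empty(len(nodes), dtype=np.int64)
    blen = np.zeros(len(nodes))
    labels = []
    for i, nd in enumerate(nodes):
        parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
        if i > 0:
            if nd.edge.length is None:
                raise TreeValidationError(
                    "every non-root edge must carry a branch length"
                )
            blen[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels.append(str(nd.taxon.label))
        else:
            labels.append(str(nd.label) if nd.label else None)
    return Phylogeny(parent=parent, blen=blen, labels=tuple(labels))


def _to_dendropy(tree: Phylogeny) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dnodes = [dendropy.Node() for _ in range(tree.n_nodes)]
    dtree.seed_node = dnodes[0]
    tips = set(tree.tip_indices.tolist())
    for v in range(tree.n_nodes):
        if v > 0:
            dnodes[tree.parent[v]].add_child(dnodes[v])
            dnodes[v].edge.length = float(tree.blen[v])
        if v in tips:
            dnodes[v].taxon = taxa.new_taxon(tree.labels[v])
        elif tree.labels[v]:
            dnodes[v].label = tree.labels[v]
    return dtree


def read_newick(
    path,
    resolve_polytomies: bool = False,
    require_ultrametric: bool = True,
) -> Phylogeny:
    """Read and validate a rooted ultrametric bifurcating tree from Newick.

    Parameters
    ----------
    resolve_polytomies : resolve multifurcations into zero-length
        bifurcations instead of rejecting them.
    require_ultrametric : set False to accept non-ultrametric trees
        (most downstream operations assume ultrametricity).
    """
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as e:  # dendropy's parse/taxon errors vary by failure
        raise TreeValidationError(f"could not parse Newick: {e}") from e
    tree = _from_dendropy(dtree, resolve_polytomies=resolve_polytomies)
    return tree.validate(require_ultrametric=require_ultrametric)


def parse_newick(
    newick: str,
    resolve_polytomies: bool = False,
    require_ultrametric: bool = True,
) -> Phylogeny:
    """Parse a Newick string (see :func:`read_newick`)."""
    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(newick), schema="newick", preserve_underscores=True
        )
    except Exception as e:
        raise TreeValidationError(f"could not parse Newick: {e}") from e
    tree = _from_dendropy(dtree, resolve_polytomies=resolve_polytomies)
    return tree.validate(require_ultrametric=require_ultrametric)


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialize to Newick; returns the string and optionally writes it."""
    s = _to_dendropy(tree).as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    ).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


# ---------------------------------------------------------------------
# transforms and covariances
# ---------------------------------------------------------------------

def lambda_transform(tree: Phylogeny, lam: float) -> Phylogeny:
    """Pagel's lambda transformation of an ultrametric tree.

    Internal branches are compressed by a factor ``lam`` while terminal
    branches are extended by ``(1 - lam)`` of the total tree depth, so the
    depth is unchanged. Off-diagonal entries of the Brownian covariance
    scale by ``lam``; the diagonal is preserved. ``lam = 1`` is the
    identity, ``lam = 0`` yields a star phylogeny (no shared history).
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if lam == 1.0:
        return tree
    T = tree.depth
    tips = tree.is_tip
    blen = tree.blen * lam
    blen[tips] = tree.blen[tips] * lam + (1.0 - lam) * T
    blen[0] = 0.0
    return replace(tree, blen=blen)


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Brownian covariance among tips: C_ij = depth of MRCA(i, j).

    Tips follow the post-order tip sequence of the tree.
    """
    tip_idx = tree.tip_indices
    n = tip_idx.size
    pos = {int(v): i for i, v in enumerate(tip_idx)}
    # tips below each node, accumulated in reverse (post-order) pass
    masks = np.zeros((tree.n_nodes, n), dtype=bool)
    for v in range(tree.n_nodes - 1, -1, -1):
        if not tree.children(v):
            masks[v, pos[v]] = True
        else:
            for c in tree.children(v):
                masks[v] |= masks[c]
    C = np.zeros((n, n))
    for v in range(1, tree.n_nodes):
        m = masks[v]
        C[np.ix_(m, m)] += tree.blen[v]
    return PhyloCovariance(matrix=C, tip_order=[tree.labels[v] for v in tip_idx])


def node_covariance(tree: Phylogeny) -> np.ndarray:
    """Brownian covariance among *all* nodes (tips and internals).

    Entry (u, v) is the shared root-to-MRCA path length; rows/columns
    follow node index order (root first). Used by GLS reconstruction.
    """
    m = tree.n_nodes
    V = np.zeros((m, m))
    below = np.zeros((m, m), dtype=bool)
    for v in range(m - 1, -1, -1):
        below[v, v] = True
        for c in tree.children(v):
            below[v] |= below[c]
    for v in range(1, m):
        b = below[v]
        V[np.ix_(b, b)] += tree.blen[v]
    return V


def rescale_depth(tree: Phylogeny, target: float = 1.0):
    """Rescale branch lengths to a given tree depth.

    Returns ``(scaled_tree, factor)`` with ``factor = original_depth / target``
    so that a per-unit-time rate matrix estimated on the scaled tree is
    divided by ``factor`` to recover the original time units.
    """
    T = tree.depth
    if T <= 0:
        raise ValueError("tree depth must be positive")
    factor = T / target
    return replace(tree, blen=tree.blen / factor), factor


def prune_to(tree: Phylogeny, keep_labels) -> Phylogeny:
    """Prune the tree down to the given tip labels (suppressing unifurcations)."""
    keep = set(keep_labels)
    have = set(tree.tip_labels)
    missing = keep - have
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    if keep == have:
        return tree
    dtree = _to_dendropy(tree)
    dtree.retain_taxa_with_labels(sorted(keep))
    # collapse a root with a single child introduced by pruning
    while len(dtree.seed_node.child_nodes()) == 1:
        child = dtree.seed_node.child_nodes()[0]
        child.parent_node = None
        dtree.seed_node = child
    return _from_dendropy(dtree).validate()


# ---------------------------------------------------------------------
# Yule (pure-birth) simulation
# ---------------------------------------------------------------------

def simulate_pure_birth(n: int, seed=None, birth_rate: float = 1.0) -> Phylogeny:
    """Simulate an ultrametric tree under a pure-birth (Yule) process.

    Starting from the crown (two lineages at time 0), each of the k active
    lineages splits at rate ``birth_rate``; after the n-th lineage appears,
    one further exponential waiting time is added so that terminal branches
    are not degenerate. Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 tips, got n={n}")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = rng.integers(k)
        v = active.pop(i)
        for _ in range(2):
            parent.append(v)
            birth.append(t)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (birth_rate * n))
    end = [t] * len(parent)
    for v in range(len(parent)):
        for c in range(len(parent)):
            if parent[c] == v:
                end[v] = birth[c]
                break
    blen = np.array([0.0 if p < 0 else end[v] - birth[v] for v, p in enumerate(parent)])
    labels: list = [None] * len(parent)
    has_child = set(parent)
    k = 0
    for v in range(len(parent)):
        if v not in has_child:
            k += 1
            labels[v] = f"t{k}"
    return Phylogeny(
        parent=np.array(parent), blen=blen, labels=tuple(labels)
    ).validate()
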