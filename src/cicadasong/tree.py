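"""Rooted phylogenies and the covariance machinery built on them.

The tree is the backbone of every comparative statistic in this package:
under Brownian motion the expected covariance of a trait between two
species is proportional to the branch length they share from the root to
their most recent common ancestor.  This module ingests Newick trees
(via :mod:`dendropy`), manipulates them (tip dropping, branch-length
transforms) and exposes the species-ordered covariance matrix and the
branch/tip incidence structure that the signal, regression and
model-fitting modules consume.

Branch lengths are treated as relative time; no calendar calibration is
attempted.  Trees are required to be strictly bifurcating after
ingestion — polytomies are rejected by default and may optionally be
resolved arbitrarily into zero-length branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "NewickError",
    "parse_newick",
    "write_newick",
    "drop_tips",
    "phylo_covariance",
    "lambda_transform",
    "eb_transform",
    "check_ultrametric",
]


class NewickError(ValueError):
    """Raised when a Newick string cannot be turned into a valid tree."""


@dataclass
class PhyloTree:
    """A rooted, strictly bifurcating tree in flat-array form.

    Nodes are indexed ``0 .. n_nodes-1`` with tips first
    (``0 .. n_tips-1``, in the order of ``tip_labels``) and the root
    last.  ``parent[i]`` is the parent index (-1 for the root) and
    ``length[i]`` the length of the branch subtending node ``i``
    (0 for the root).
    """

    parent: np.ndarray
    length: np.ndarray
    tip_labels: list[str]
    children: list[list[int]] = field(repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def postorder(self) -> np.ndarray:
        """Node indices with every child before its parent."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return np.array(order[::-1], dtype=int)

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1].copy()

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.length[v]
        return depth

    def height(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.node_depths()[: self.n_tips].max())

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def branch_tip_incidence(self) -> np.ndarray:
        """Boolean matrix ``M[v, i]`` = tip ``i`` descends from node ``v``.

        Row ``v`` describes the branch subtending node ``v`` (the root
        row covers all tips but carries zero length).  The phylogenetic
        covariance is ``M.T @ diag(length) @ M``, and the same incidence
        structure drives the multi-regime covariances.
        """
        n = self.n_tips
        M = np.zeros((self.n_nodes, n), dtype=bool)
        M[np.arange(n), np.arange(n)] = True
        for v in self.postorder():
            for c in self.children[v]:
                M[v] |= M[c]
        return M

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            parent=self.parent.copy(),
            length=self.length.copy(),
            tip_labels=list(self.tip_labels),
            children=[list(c) for c in self.children],
        )

    def is_bifurcating(self) -> bool:
        return all(
            len(c) in (0, 2) for c in self.children
        )


@dataclass
class PhyloCovariance:
    """Species-ordered phylogenetic covariance matrix.

    ``matrix[i, j]`` is the root-to-MRCA path length shared by species
    ``i`` and ``j``; the diagonal holds root-to-tip distances.
    ``transform`` records any branch-length manipulation applied
    (``"none"``, ``"lambda(x)"`` or ``"eb(r)"``).
    """

    matrix: np.ndarray
    species: list[str]
    transform: str = "none"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.species), len(self.species)):
            raise ValueError("covariance shape does not match species list")


# ---------------------------------------------------------------------------
# Newick I/O


def _from_dendropy(dtree: dendropy.Tree, resolve_polytomies: bool) -> PhyloTree:
    seed = dtree.seed_node
    # A root with >2 children is the unrooted convention; treat it like any
    # other polytomy under the configured policy.
    if resolve_polytomies:
        dtree.resolve_polytomies(limit=2, update_bipartitions=False)

    dnodes = list(dtree.preorder_node_iter())
    for nd in dnodes:
        kids = nd.child_nodes()
        if len(kids) not in (0, 2):
            raise NewickError(
                f"non-bifurcating node with {len(kids)} children "
                f"(near {kids[0].taxon.label if kids and kids[0].taxon else 'internal node'}); "
                "pass resolve_polytomies=True to resolve arbitrarily"
            )
        if nd is not seed and nd.edge.length is None:
            raise NewickError("branch length missing on at least one edge")
        if nd is not seed and nd.edge.length < 0:
            raise NewickError("negative branch length")

    tips = [nd for nd in dnodes if nd.is_leaf()]
    labels = [t.taxon.label if t.taxon else None for t in tips]
    if any(lab is None for lab in labels):
        raise NewickError("unlabelled tip")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate tip labels: {dup}")

    internals = [nd for nd in dnodes if not nd.is_leaf() and nd is not seed]
    ordering = tips + internals + [seed]
    index = {id(nd): i for i, nd in enumerate(ordering)}

    n = len(ordering)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    for nd in dnodes:
        i = index[id(nd)]
        if nd is not seed:
            parent[i] = index[id(nd.parent_node)]
            length[i] = float(nd.edge.length)
            children[parent[i]].append(i)
    return PhyloTree(parent=parent, length=length, tip_labels=labels, children=children)


def parse_newick(text: str, resolve_polytomies: bool = False) -> PhyloTree:
    """Parse a Newick string with mandatory branch lengths.

    Parameters
    ----------
    text:
        A single Newick tree; comments are ignored.
    resolve_polytomies:
        If True, multifurcations are resolved arbitrarily into
        zero-length branches instead of raising.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree, resolve_polytomies)


def write_newick(tree: PhyloTree, precision: int = 10) -> str:
    """Serialise a :class:`PhyloTree` back to Newick (with lengths)."""

    def emit(v: int) -> str:
        if not tree.children[v]:
            return f"{tree.tip_labels[v]}:{tree.length[v]:.{precision}g}"
        inner = ",".join(emit(c) for c in tree.children[v])
        if v == tree.root:
            return f"({inner})"
        return f"({inner}):{tree.length[v]:.{precision}g}"

    return emit(tree.root) + ";"


# ---------------------------------------------------------------------------
# Manipulation


def drop_tips(tree: PhyloTree, labels: Iterable[str]) -> PhyloTree:
    """Remove the named tips, fusing resulting degree-2 nodes.

    Pairwise path lengths among the surviving tips are preserved:
    unbranched internal nodes created by the removal are collapsed and
    their branch lengths summed.  A root left with a single child is
    replaced by that child (its stem length is discarded, so the new
    root sits at the old MRCA of the survivors).
    """
    labels = set(labels)
    unknown = labels - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    keep = [l for l in tree.tip_labels if l not in labels]
    if len(keep) < 2:
        raise ValueError("fewer than 2 tips would remain")
    if not labels:
        return tree.copy()

    # Rebuild recursively: a node survives if >=1 descendant tip survives.
    keep_set = set(keep)

    def build(v: int) -> tuple[str | None, float, list] | None:
        # returns (label, stem_length, children_nodes) or None if pruned
        if not tree.children[v]:
            if tree.tip_labels[v] in keep_set:
                return (tree.tip_labels[v], float(tree.length[v]), [])
            return None
        kids = [build(c) for c in tree.children[v]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            lab, stem, sub = kids[0]
            return (lab, stem + float(tree.length[v]), sub)
        return (None, float(tree.length[v]), kids)

    rootspec = build(tree.root)
    assert rootspec is not None

    # Flatten into arrays, tips first in original relative order.
    tip_entries: list[tuple[str, float, list]] = []

    def to_newick(spec) -> str:
        lab, stem, sub = spec
        if not sub:
            return f"{lab}:{stem!r}"
        return f"({','.join(to_newick(s) for s in sub)}):{stem!r}"

    lab, stem, sub = rootspec
    if not sub:  # pragma: no cover - guarded by len(keep) >= 2
        raise ValueError("degenerate tree after drop")
    text = f"({','.join(to_newick(s) for s in sub)});"
    out = parse_newick(text)
    # parse_newick orders tips by traversal; keep deterministic original order
    order = sorted(range(out.n_tips), key=lambda i: keep.index(out.tip_labels[i]))
    return _reorder_tips(out, order)


def _reorder_tips(tree: PhyloTree, order: Sequence[int]) -> PhyloTree:
    """Relabel tip indices 0..n-1 according to ``order`` (old index per slot)."""
    n = tree.n_tips
    mapping = {old: new for new, old in enumerate(order)}
    for v in range(n, tree.n_nodes):
        mapping[v] = v
    parent = np.full(tree.n_nodes, -1, dtype=int)
    length = np.zeros(tree.n_nodes)
    children: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for v in range(tree.n_nodes):
        nv = mapping[v]
        length[nv] = tree.length[v]
        if tree.parent[v] >= 0:
            parent[nv] = mapping[tree.parent[v]]
    for v in range(tree.n_nodes):
        if parent[v] >= 0:
            children[parent[v]].append(v)
    labels = [tree.tip_labels[order[i]] for i in range(n)]
    return PhyloTree(parent=parent, length=length, tip_labels=labels, children=children)


# ---------------------------------------------------------------------------
# Covariance machinery


def phylo_covariance(tree: PhyloTree) -> PhyloCovariance:
    """Brownian-motion covariance: shared root-to-MRCA path lengths."""
    M = tree.branch_tip_incidence().astype(float)
    C = (M * tree.length[:, None]).T @ M
    C = 0.5 * (C + C.T)  # exact symmetry
    return PhyloCovariance(matrix=C, species=list(tree.tip_labels))


def lambda_transform(cov: PhyloCovariance, lam: float,
                     bounds: tuple[float, float] = (0.0, 1.0)) -> PhyloCovariance:
    """Pagel's lambda: scale off-diagonal covariances by ``lam``.

    ``lam = 1`` leaves the Brownian structure untouched; ``lam = 0``
    removes all phylogenetic covariance (a star phylogeny).  The
    admissible range defaults to [0, 1] but can be overridden.
    """
    if not (bounds[0] <= lam <= bounds[1]):
        raise ValueError(f"lambda {lam} outside bounds {bounds}")
    if cov.transform != "none":
        raise ValueError("lambda_transform expects an untransformed covariance")
    C = cov.matrix
    out = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    return PhyloCovariance(matrix=out, species=list(cov.species),
                           transform=f"lambda({lam:g})")


def eb_transform(tree: PhyloTree, r: float) -> PhyloTree:
    """Early-burst branch-time transform.

    Under an early burst the evolutionary rate changes as ``exp(r t)``
    with ``t`` time from the root (``r <= 0``: deceleration).  A branch
    spanning node ages ``t1 -> t2`` is rescaled to
    ``(exp(r t2) - exp(r t1)) / r``; ``r = 0`` is the identity (limit).
    """
    if r > 0:
        raise ValueError("early-burst rate parameter r must be <= 0")
    out = tree.copy()
    if r == 0.0:
        return out
    depth = tree.node_depths()
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0:
            t1, t2 = depth[p], depth[v]
            # exp(r t1) * expm1(r (t2-t1)) / r, stable as r -> 0
            out.length[v] = np.exp(r * t1) * np.expm1(r * (t2 - t1)) / r
    return out


def check_ultrametric(tree: PhyloTree, tol: float = 1e-8) -> bool:
    """True iff all root-to-tip distances agree within ``tol``."""
    d = tree.node_depths()[: tree.n_tips]
    return bool(d.max() - d.min() <= tol)
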