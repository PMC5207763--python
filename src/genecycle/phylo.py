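"""Species-tree handling.

Provides a light rooted-tree container with Newick I/O (parsing delegated
to dendropy), outgroup identification following the "two outer-most
branches" rule, least-squares branch-length fitting from a pairwise
distance matrix (median Ka in the intended application), and patristic
distance queries.

Branch identifiers throughout the package are the identifier of the child
node of the branch: the branch "above" node ``x`` is referred to as ``x``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "Node",
    "Tree",
    "DistanceMatrix",
    "LineageConfig",
    "ResolvedLineage",
    "parse_newick",
    "read_newick",
    "identify_outgroup",
    "fit_branch_lengths",
    "patristic_distance",
    "resolve_lineage",
]


class TreeError(ValueError):
    """Malformed tree input or an invalid tree query."""


class Node:
    """A node of a rooted tree; the branch above it carries ``branch_length``."""

    __slots__ = ("id", "parent", "children", "branch_length")

    def __init__(self, id: str, branch_length: float | None = None):
        self.id = id
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.branch_length = branch_length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id!r}, bl={self.branch_length})"


class Tree:
    """Rooted tree with uniquely identified nodes and an optional focal leaf."""

    def __init__(self, root: Node, focal: str | None = None):
        self.root = root
        self._nodes: dict[str, Node] = {}
        for node in self.preorder():
            if node.id in self._nodes:
                raise TreeError(f"duplicate node identifier {node.id!r}")
            self._nodes[node.id] = node
        if root.parent is not None:
            raise TreeError("root must have no parent")
        if focal is not None:
            if focal not in self._nodes or not self._nodes[focal].is_leaf:
                raise TreeError(f"focal species {focal!r} is not a leaf of the tree")
        self.focal = focal
        self._clade_cache: dict[str, frozenset[str]] = {}

    # -- traversal -----------------------------------------------------

    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def nodes(self) -> list[Node]:
        return list(self._nodes.values())

    def node(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise TreeError(f"unknown node {node_id!r}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def leaves(self) -> list[Node]:
        return [n for n in self._nodes.values() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def branches(self) -> list[Node]:
        """All non-root nodes, i.e. all branches (identified by child node)."""
        return [n for n in self._nodes.values() if n.parent is not None]

    # -- queries -------------------------------------------------------

    def path_to_root(self, node_id: str) -> list[Node]:
        node: Node | None = self.node(node_id)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    def root_to_focal_path(self, focal: str | None = None) -> list[Node]:
        focal = focal if focal is not None else self.focal
        if focal is None:
            raise TreeError("no focal species set")
        return list(reversed(self.path_to_root(focal)))

    def mrca(self, *node_ids: str) -> Node:
        if not node_ids:
            raise TreeError("mrca of an empty set is undefined")
        ancestors = [n.id for n in self.path_to_root(node_ids[0])]
        anc_set = set(ancestors)
        for other in node_ids[1:]:
            anc_set &= {n.id for n in self.path_to_root(other)}
        for nid in ancestors:
            if nid in anc_set:
                return self._nodes[nid]
        raise TreeError("nodes share no common ancestor")  # pragma: no cover

    def is_ancestor(self, anc_id: str, desc_id: str) -> bool:
        """True iff ``anc_id`` is ``desc_id`` or a (proper) ancestor of it."""
        node: Node | None = self.node(desc_id)
        self.node(anc_id)
        while node is not None:
            if node.id == anc_id:
                return True
            node = node.parent
        return False

    def is_strict_descendant(self, node_id: str, anc_id: str) -> bool:
        return node_id != anc_id and self.is_ancestor(anc_id, node_id)

    def clade_leaves(self, node_id: str) -> frozenset[str]:
        cached = self._clade_cache.get(node_id)
        if cached is not None:
            return cached
        node = self.node(node_id)
        if node.is_leaf:
            result = frozenset([node.id])
        else:
            result = frozenset().union(*(self.clade_leaves(c.id) for c in node.children))
        self._clade_cache[node_id] = result
        return result

    def patristic_distance(self, a: str, b: str) -> float:
        if a == b:
            self.node(a)
            return 0.0
        m = self.mrca(a, b)
        total = 0.0
        for nid in (a, b):
            node = self.node(nid)
            while node.id != m.id:
                if node.branch_length is None:
                    raise TreeError(f"branch above {node.id!r} has no length")
                total += node.branch_length
                node = node.parent  # type: ignore[assignment]
        return total

    # -- construction / serialisation ---------------------------------

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.id, node.branch_length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root), focal=self.focal)

    def to_newick(self, include_lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.id
            else:
                label = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.id
            if include_lengths and node.branch_length is not None:
                label += f":{node.branch_length:.10g}"
            return label

        return fmt(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def parse_newick(text: str, focal: str | None = None) -> Tree:
    """Parse a rooted Newick string into a :class:`Tree`.

    Internal nodes without a label receive deterministic identifiers
    ``N0, N1, ...`` in preorder.  Raises :class:`TreeError` for malformed
    strings (the underlying parser message names the offending position)
    or duplicate leaf labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed Newick: {exc}") from None

    counter = 0

    def convert(dnode) -> Node:
        nonlocal counter
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        else:
            label = f"N{counter}"
            counter += 1
        node = Node(label, branch_length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    tree = Tree(root, focal=focal)
    labels = tree.leaf_names
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {dupes}")
    return tree


def read_newick(path: str | Path, focal: str | None = None) -> Tree:
    return parse_newick(Path(path).read_text(), focal=focal)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise species distances (e.g. median Ka, subst./site)."""

    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match species list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        self._index = {s: i for i, s in enumerate(self.species)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("distance matrix header row and column disagree")
        return cls(list(df.index), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class LineageConfig:
    """User-facing lineage anchors, by species or node name.

    ``local_threshold`` and ``wgd_branch`` may name a leaf: the threshold is
    then the split of the focal lineage with that leaf (its MRCA with the
    focal species), and the WGD branch the focal-path branch immediately
    below that split — matching the usage "after the split with K. waltii".
    """

    focal: str
    outgroup: frozenset[str] | None = None
    local_threshold: str | None = None
    wgd_branch: str | None = None
    ancient_root: str | None = None


@dataclass(frozen=True)
class ResolvedLineage:
    """Lineage anchors resolved to node identifiers on a specific tree."""

    focal: str
    outgroup: frozenset[str]
    outgroup_clade_roots: frozenset[str]
    local_threshold: str | None = None  # node id on root-to-focal path
    wgd_node: str | None = None  # child node of the WGD branch
    ancient_root: str | None = None


def identify_outgroup(
    tree: Tree,
    focal: str | None = None,
    override: Iterable[str] | None = None,
) -> frozenset[str]:
    """Leaves of the two clades attaching deepest on the root-to-focal path.

    The two "outer-most branches" are the first (closest to the root)
    off-path subtrees encountered walking from the root toward the focal
    leaf.  An explicit ``override`` species set short-circuits the
    heuristic.
    """
    if override is not None:
        out = frozenset(override)
        unknown = out - set(tree.leaf_names)
        if unknown:
            raise TreeError(f"outgroup override names unknown species: {sorted(unknown)}")
        return out
    if len(tree.leaves()) < 3:
        raise TreeError("no outgroup definable on a tree with fewer than 3 leaves")
    path = tree.root_to_focal_path(focal)
    on_path = {n.id for n in path}
    clades: list[Node] = []
    for node in path:
        for child in node.children:
            if child.id not in on_path:
                clades.append(child)
        if len(clades) >= 2:
            break
    clades = clades[:2]
    return frozenset().union(*(tree.clade_leaves(c.id) for c in clades))


def maximal_clades_within(tree: Tree, species: frozenset[str]) -> frozenset[str]:
    """Roots of the maximal clades whose leaves all belong to ``species``."""
    roots: list[str] = []

    def visit(node: Node) -> None:
        if tree.clade_leaves(node.id) <= species:
            roots.append(node.id)
            return
        for child in node.children:
            visit(child)

    if species:
        visit(tree.root)
    return frozenset(roots)


def _resolve_path_node(tree: Tree, name: str, focal: str) -> Node:
    """Resolve a leaf name (→ MRCA with focal) or node id to a focal-path node."""
    if tree.has_node(name) and tree.node(name).is_leaf and name != focal:
        node = tree.mrca(focal, name)
    elif tree.has_node(name):
        node = tree.node(name)
    else:
        raise TreeError(f"unknown species or node {name!r}")
    if not tree.is_ancestor(node.id, focal):
        raise TreeError(f"node {node.id!r} does not lie on the root-to-focal path")
    return node


def resolve_lineage(tree: Tree, cfg: LineageConfig) -> ResolvedLineage:
    """Resolve a :class:`LineageConfig` against a tree, applying defaults."""
    focal = cfg.focal
    if not tree.has_node(focal) or not tree.node(focal).is_leaf:
        raise TreeError(f"focal species {focal!r} is not a leaf of the tree")
    outgroup = identify_outgroup(tree, focal=focal, override=cfg.outgroup)
    if focal in outgroup:
        raise TreeError("focal species cannot be part of the outgroup")
    og_roots = maximal_clades_within(tree, outgroup)

    threshold_id: str | None = None
    if cfg.local_threshold is not None:
        threshold_id = _resolve_path_node(tree, cfg.local_threshold, focal).id

    wgd_id: str | None = None
    if cfg.wgd_branch is not None:
        node = _resolve_path_node(tree, cfg.wgd_branch, focal)
        if node.is_leaf and node.id != focal:
            # leaf name: the WGD branch is the focal-path branch right below
            # the split with that leaf
            split = node
            path = tree.root_to_focal_path(focal)
            idx = [n.id for n in path].index(split.id)
            node = path[idx + 1]
        wgd_id = node.id
    elif threshold_id is not None:
        path = tree.root_to_focal_path(focal)
        idx = [n.id for n in path].index(threshold_id)
        if idx + 1 < len(path):
            wgd_id = path[idx + 1].id

    ancient_id: str | None = None
    if cfg.ancient_root is not None:
        ancient_id = _resolve_path_node(tree, cfg.ancient_root, focal).id

    return ResolvedLineage(
        focal=focal,
        outgroup=outgroup,
        outgroup_clade_roots=og_roots,
        local_threshold=threshold_id,
        wgd_node=wgd_id,
        ancient_root=ancient_id,
    )


def fit_branch_lengths(dm: DistanceMatrix, tree: Tree) -> Tree:
    """Fit nonnegative branch lengths to a fixed topology by least squares.

    Minimises the squared error between patristic and observed leaf-pair
    distances.  When the matrix is additive on the topology the residual is
    zero.  Negative unconstrained estimates trigger a warning and a
    nonnegative (NNLS) refit.  The two root-adjacent branches of a rooted
    binary tree are only constrained through their sum; the minimum-norm
    solution splits it equally.
    """
    leaves = tree.leaf_names
    missing = [s for s in leaves if s not in dm.species]
    if missing:
        raise TreeError(f"distance matrix is missing species: {missing}")

    branch_ids = [n.id for n in tree.branches()]
    col = {b: i for i, b in enumerate(branch_ids)}
    pairs = list(combinations(leaves, 2))
    A = np.zeros((len(pairs), len(branch_ids)))
    d = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        m = tree.mrca(a, b)
        for nid in (a, b):
            node = tree.node(nid)
            while node.id != m.id:
                A[r, col[node.id]] = 1.0
                node = node.parent  # type: ignore[assignment]
        d[r] = dm.get(a, b)

    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    if x.min() < -1e-9:
        warnings.warn(
            "negative branch-length estimate(s) clamped to zero "
            "(distance matrix violates additivity)",
            stacklevel=2,
        )
        x, _ = nnls(A, d)
    x = np.clip(x, 0.0, None)

    fitted = tree.copy()
    for b, i in col.items():
        fitted.node(b).branch_length = float(x[i])
    return fitted


def patristic_distance(tree: Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between two nodes."""
    return tree.patristic_distance(a, b)
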