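"""Rooted species phylogeny with stable integer node ids and focal lineages.

The phylogeny is purely topological: branch lengths carry no information for
ordinal phylostratigraphy, so the reader accepts and discards them.  Nodes are
identified by preorder integers assigned at parse time (root = 0); every
downstream module refers to nodes by these ids, never by object identity, so a
tree parsed twice from the same Newick string yields identical ids.

A *focal lineage* is the ordered root-to-tip node path for one extant species.
Its positions define the phylostrata ps1..psN (1-based): ps1 is the root
internode, psN the focal species' terminal internode.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd


class TreeError(ValueError):
    """Base class for phylogeny errors."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class TreeValidationError(TreeError):
    """Structurally valid Newick violating a phylogeny invariant."""


class Phylogeny:
    """Immutable rooted tree over integer node ids (preorder, root = 0).

    Polytomies are legal; child order is the parse order.  Leaf names must be
    unique and non-empty.  Internal node labels, when present in the input,
    are retained (they can serve as phylostratum names).
    """

    __slots__ = (
        "_parent",
        "_children",
        "_name",
        "_label",
        "_leaf_id",
        "_depth",
        "_subtree_leaves",
    )

    def __init__(
        self,
        parent: Sequence[Optional[int]],
        children: Sequence[Sequence[int]],
        name: Sequence[Optional[str]],
        label: Sequence[Optional[str]],
    ):
        self._parent = tuple(parent)
        self._children = tuple(tuple(c) for c in children)
        self._name = tuple(name)
        self._label = tuple(label)
        self._validate()
        self._leaf_id = {n: v for v, n in enumerate(self._name) if n is not None}
        self._depth = tuple(self._compute_depths())
        self._subtree_leaves = tuple(self._compute_subtree_leaves())

    # -- construction ----------------------------------------------------

    def _validate(self) -> None:
        roots = [v for v, p in enumerate(self._parent) if p is None]
        if roots != [0]:
            raise TreeValidationError(f"expected unique root 0, found roots {roots}")
        names = [n for n in self._name if n is not None]
        if any(n == "" for n in names):
            raise TreeValidationError("empty leaf name")
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise TreeValidationError(f"duplicate leaf name: {n!r}")
            seen.add(n)
        for v, kids in enumerate(self._children):
            for c in kids:
                if self._parent[c] != v:
                    raise TreeValidationError("parent/children tables disagree")

    def _compute_depths(self) -> list[int]:
        depth = [0] * len(self._parent)
        for v in range(1, len(self._parent)):  # preorder: parent precedes child
            depth[v] = depth[self._parent[v]] + 1
        return depth

    def _compute_subtree_leaves(self) -> list[frozenset[int]]:
        out: list[frozenset[int] | None] = [None] * self.n_nodes
        for v in reversed(range(self.n_nodes)):  # reverse preorder = postorder-safe
            if not self._children[v]:
                out[v] = frozenset((v,))
            else:
                acc: set[int] = set()
                for c in self._children[v]:
                    acc |= out[c]  # type: ignore[arg-type]
                out[v] = frozenset(acc)
        return out  # type: ignore[return-value]

    # -- basic accessors -------------------------------------------------

    root: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self._parent)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_id)

    def parent(self, v: int) -> Optional[int]:
        return self._parent[v]

    def children(self, v: int) -> tuple[int, ...]:
        return self._children[v]

    def is_leaf(self, v: int) -> bool:
        return not self._children[v]

    def depth(self, v: int) -> int:
        return self._depth[v]

    def node_label(self, v: int) -> Optional[str]:
        """Internal-node label from the input Newick, if any."""
        return self._label[v]

    def leaf_name(self, v: int) -> str:
        n = self._name[v]
        if n is None:
            raise TreeValidationError(f"node {v} is not a leaf")
        return n

    def leaf_id(self, name: str) -> int:
        try:
            return self._leaf_id[name]
        except KeyError:
            raise TreeValidationError(f"unknown leaf name: {name!r}") from None

    @property
    def leaf_names(self) -> tuple[str, ...]:
        """Leaf names in parse (preorder) order."""
        return tuple(self._name[v] for v in range(self.n_nodes) if self.is_leaf(v))

    def nodes(self) -> range:
        return range(self.n_nodes)

    def subtree_leaf_ids(self, v: int) -> frozenset[int]:
        return self._subtree_leaves[v]

    def subtree_leaf_names(self, v: int) -> frozenset[str]:
        return frozenset(self._name[u] for u in self._subtree_leaves[v])  # type: ignore[arg-type]

    # -- topology queries ------------------------------------------------

    def is_ancestor_or_equal(self, a: int, v: int) -> bool:
        """True iff ``a`` lies on the path from the root to ``v`` (inclusive)."""
        while self._depth[v] > self._depth[a]:
            v = self._parent[v]  # type: ignore[assignment]
        return v == a

    def path_from_root(self, v: int) -> tuple[int, ...]:
        path = [v]
        while self._parent[path[-1]] is not None:
            path.append(self._parent[path[-1]])  # type: ignore[arg-type]
        return tuple(reversed(path))

    def lca_ids(self, ids: Iterable[int]) -> int:
        ids = list(ids)
        if not ids:
            raise TreeValidationError("lca of an empty node set")
        a = ids[0]
        for b in ids[1:]:
            a = self._lca_pair(a, b)
        return a

    def _lca_pair(self, a: int, b: int) -> int:
        while self._depth[a] > self._depth[b]:
            a = self._parent[a]  # type: ignore[assignment]
        while self._depth[b] > self._depth[a]:
            b = self._parent[b]  # type: ignore[assignment]
        while a != b:
            a = self._parent[a]  # type: ignore[assignment]
            b = self._parent[b]  # type: ignore[assignment]
        return a

    def lca(self, species: Iterable[str]) -> int:
        """Lowest common ancestor of a non-empty set of leaf names."""
        names = list(species)
        if not names:
            raise TreeValidationError("lca of an empty species set")
        return self.lca_ids(self.leaf_id(n) for n in names)

    # -- serialisation ---------------------------------------------------

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if self.is_leaf(v):
                return self._name[v]  # type: ignore[return-value]
            inner = ",".join(fmt(c) for c in self._children[v])
            return f"({inner}){self._label[v] or ''}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny {self.n_leaves} leaves, {self.n_nodes} nodes>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick tree into a :class:`Phylogeny`.

    Branch lengths and support values are discarded; internal labels are kept.
    Raises :class:`NewickParseError` on malformed input and
    :class:`TreeValidationError` on duplicate or empty leaf names.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except TreeError:
        raise
    except Exception as exc:  # dendropy raises schema-specific error classes
        msg = str(exc)
        if "duplicate" in msg.lower() or "multiple" in msg.lower():
            raise TreeValidationError(f"duplicate leaf name in Newick: {msg}") from exc
        raise NewickParseError(f"malformed Newick: {msg}") from exc

    parent: list[Optional[int]] = []
    children: list[list[int]] = []
    name: list[Optional[str]] = []
    label: list[Optional[str]] = []

    def visit(node: dendropy.Node, par: Optional[int]) -> int:
        v = len(parent)
        parent.append(par)
        children.append([])
        if node.is_leaf():
            leaf = node.taxon.label if node.taxon is not None else node.label
            name.append(leaf)
            label.append(None)
        else:
            name.append(None)
            label.append(node.label or None)
        for child in node.child_nodes():
            children[v].append(visit(child, v))
        return v

    visit(dtree.seed_node, None)
    if not any(n is not None for n in name):
        raise NewickParseError("tree has no named leaves")
    return Phylogeny(parent, children, name, label)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path=None) -> str:
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


@dataclass(frozen=True)
class FocalLineage:
    """Root-to-tip node path of one focal species; positions = phylostrata.

    ``path[0]`` is the root (ps1) and ``path[-1]`` the focal leaf (psN).
    Phylostratum indices are 1-based throughout.
    """

    focal: str
    path: tuple[int, ...]
    ps_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if len(self.path) < 2:
            raise TreeValidationError(
                f"lineage of {self.focal!r} has fewer than two phylostrata"
            )
        if self.ps_names and len(self.ps_names) != len(self.path):
            raise TreeValidationError("ps_names length differs from path length")

    @property
    def n_strata(self) -> int:
        return len(self.path)

    def ps_node(self, i: int) -> int:
        """Node id of phylostratum ``i`` (1-based)."""
        if not 1 <= i <= self.n_strata:
            raise TreeValidationError(f"phylostratum index {i} outside 1..{self.n_strata}")
        return self.path[i - 1]

    def node_to_ps(self, node: int) -> Optional[int]:
        """1-based phylostratum index of ``node``, or None if off the path."""
        try:
            return self.path.index(node) + 1
        except ValueError:
            return None

    def ps_name(self, i: int) -> str:
        self.ps_node(i)  # bounds check
        if self.ps_names:
            return self.ps_names[i - 1]
        return f"ps{i}"


def focal_lineage(
    tree: Phylogeny,
    focal: str,
    ps_names: Optional[dict[int, str]] = None,
) -> FocalLineage:
    """Build the :class:`FocalLineage` for one leaf.

    Default phylostratum names come from internal-node labels where the input
    Newick carried them, otherwise ``ps<i>``; an explicit ``ps_names`` mapping
    (1-based index -> clade label) overrides both.
    """
    path = tree.path_from_root(tree.leaf_id(focal))
    names = []
    for i, v in enumerate(path, start=1):
        if ps_names and i in ps_names:
            names.append(ps_names[i])
        elif not tree.is_leaf(v) and tree.node_label(v):
            names.append(tree.node_label(v))
        else:
            names.append(f"ps{i}")
    if any(node not in tree.nodes() for node in path):  # defensive
        raise TreeValidationError("lineage path contains foreign node ids")
    return FocalLineage(focal=focal, path=path, ps_names=tuple(names))


def node_to_ps(lineage: FocalLineage, node: int, tree: Optional[Phylogeny] = None) -> Optional[int]:
    """Phylostratum index of ``node`` on ``lineage``; None if off the path."""
    if tree is not None and node not in tree.nodes():
        raise TreeValidationError(f"node id {node} does not belong to the tree")
    return lineage.node_to_ps(node)


def read_ps_names(path) -> dict[str, dict[int, str]]:
    """Read a phylostratum-name table: focal_species, ps_index, ps_name (TSV)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["focal", "ps", "name"], comment="#")
    out: dict[str, dict[int, str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.focal), {})[int(row.ps)] = str(row.name)
    return out


def lineage_report(tree: Phylogeny, focal_species: Iterable[str],
                   ps_names: Optional[dict[str, dict[int, str]]] = None) -> pd.DataFrame:
    """Per-lineage phylostratum table (one row per focal species x ps)."""
    rows = []
    for focal in focal_species:
        lin = focal_lineage(tree, focal, (ps_names or {}).get(focal))
        for i in range(1, lin.n_strata + 1):
            v = lin.ps_node(i)
            rows.append(
                {
                    "focal_species": focal,
                    "ps_index": i,
                    "node_id": v,
                    "ps_name": lin.ps_name(i),
                    "n_descendant_species": len(tree.subtree_leaf_ids(v)),
                }
            )
    return pd.DataFrame(rows)
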