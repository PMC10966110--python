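"""Dollo-parsimony gain/loss assignment of gene families on focal lineages.

Under Dollo parsimony a family is gained exactly once and may only be lost
afterwards.  The unique minimal single-origin reconstruction places the gain
at the lowest common ancestor (LCA) of the species carrying the family; the
family is then *present* at a node v iff v descends from (or is) the gain
node and v's subtree still contains a carrier.  On a focal lineage the loss
phylostratum is the first path position where presence switches off.

Two structural consequences follow and are enforced:

* a gain must precede its loss by at least one internode (two phylostrata) —
  a gain at ps k with loss at ps k+1 is only reachable through a polytomy
  and means the family belongs to a side branch, not the focal lineage; such
  families are excluded from the lineage and reported on a side channel;
* the earliest possible loss phylostratum is the third from the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .families import FamilyTable
from .tree import FocalLineage, Phylogeny, TreeValidationError, focal_lineage


class DolloError(ValueError):
    pass


def gain_node(tree: Phylogeny, species: Iterable[str]) -> int:
    """Dollo gain node of a family = LCA of its species set."""
    return tree.lca(species)


def _presence(tree: Phylogeny, gain: int, member_leaves: frozenset[int], v: int) -> bool:
    # closed form: presence(v) <=> gain is ancestor-or-equal of v and v's
    # subtree still contains a carrier leaf
    return tree.is_ancestor_or_equal(gain, v) and bool(
        tree.subtree_leaf_ids(v) & member_leaves
    )


def _member_leaf_ids(tree: Phylogeny, species: Iterable[str]) -> frozenset[int]:
    return frozenset(tree.leaf_id(s) for s in species)


def infer_gain(
    tree: Phylogeny, lineage: FocalLineage, species: Iterable[str]
) -> Optional[int]:
    """Gain phylostratum of a family on ``lineage``; None if the gain node
    (LCA of the species set) lies off the focal path, i.e. the family never
    existed on this lineage."""
    return lineage.node_to_ps(gain_node(tree, species))


def infer_loss(
    tree: Phylogeny,
    lineage: FocalLineage,
    species: Iterable[str],
    gain_ps: int,
) -> Optional[int]:
    """Loss phylostratum on ``lineage``: the smallest i with the family
    present at path[i-1] and absent at path[i]; None when the focal species
    itself carries the family."""
    species = set(species)
    g = gain_node(tree, species)
    recomputed = lineage.node_to_ps(g)
    if recomputed != gain_ps:
        raise DolloError(
            f"inconsistent gain_ps {gain_ps} (recomputed {recomputed}) for lineage "
            f"{lineage.focal!r}"
        )
    if lineage.focal in species:
        return None
    leaves = _member_leaf_ids(tree, species)
    for i in range(gain_ps + 1, lineage.n_strata + 1):
        if not _presence(tree, g, leaves, lineage.ps_node(i)):
            return i
    return None  # unreachable when focal not in species, kept defensive


@dataclass(frozen=True)
class EventTable:
    """Per-family gain/loss phylostrata on one focal lineage.

    ``events`` columns: focal_species, family_id, gain_ps, gain_node_id,
    loss_ps (nullable), loss_node_id (nullable).  ``excluded`` holds the
    side-channel report of families removed by the immediate-loss rule.
    """

    focal: str
    n_strata: int
    events: pd.DataFrame
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        ev = self.events
        if len(ev):
            if ev["family_id"].duplicated().any():
                raise DolloError("a family appears twice on one focal lineage")
            loss = ev["loss_ps"].dropna()
            if len(loss):
                gains = ev.loc[loss.index, "gain_ps"]
                if (loss < gains + 2).any() or (loss < 3).any():
                    raise DolloError(
                        "loss_ps must be >= gain_ps + 2 and >= 3 (Dollo structure)"
                    )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, focal: str, n_strata: int) -> "EventTable":
        """Rebuild an event table from a (possibly wider) events data frame."""
        ev = df.loc[
            df["focal_species"] == focal,
            ["focal_species", "family_id", "gain_ps", "gain_node_id", "loss_ps", "loss_node_id"],
        ].copy()
        ev["loss_ps"] = ev["loss_ps"].astype("Int64")
        ev["loss_node_id"] = ev["loss_node_id"].astype("Int64")
        return cls(focal=focal, n_strata=n_strata, events=ev.reset_index(drop=True))

    def gains_per_ps(self) -> pd.Series:
        idx = pd.RangeIndex(1, self.n_strata + 1, name="ps_index")
        counts = self.events["gain_ps"].value_counts() if len(self.events) else pd.Series(dtype=int)
        return counts.reindex(idx, fill_value=0).astype(int)

    def losses_per_ps(self) -> pd.Series:
        idx = pd.RangeIndex(1, self.n_strata + 1, name="ps_index")
        if len(self.events):
            counts = self.events["loss_ps"].dropna().astype(int).value_counts()
        else:
            counts = pd.Series(dtype=int)
        return counts.reindex(idx, fill_value=0).astype(int)


_EVENT_COLS = ["focal_species", "family_id", "gain_ps", "gain_node_id", "loss_ps", "loss_node_id"]


def lineage_events(
    fams: FamilyTable, tree: Phylogeny, focal: str | FocalLineage
) -> EventTable:
    """Gain/loss events of every family that appears along one focal lineage.

    Expects species attached and the terminal-singleton filter already
    applied.  Families whose reconstruction would put the loss immediately
    after the gain (possible only at polytomies) are excluded and reported.
    """
    lineage = focal if isinstance(focal, FocalLineage) else focal_lineage(tree, focal)
    rows = []
    excluded = []
    for fam in fams.family_ids:
        species = fams.species_set(fam)
        g = gain_node(tree, species)
        gain_ps = lineage.node_to_ps(g)
        if gain_ps is None:
            continue
        loss_ps = infer_loss(tree, lineage, species, gain_ps)
        if loss_ps is not None and loss_ps == gain_ps + 1:
            # side-branch family: gained at a polytomy node, all carriers on
            # sister branches -> specific to the side branch, not this lineage
            excluded.append(
                {
                    "focal_species": lineage.focal,
                    "family_id": fam,
                    "reason": f"gain ps{gain_ps} followed by immediate loss ps{loss_ps}",
                }
            )
            continue
        rows.append(
            {
                "focal_species": lineage.focal,
                "family_id": fam,
                "gain_ps": gain_ps,
                "gain_node_id": g,
                "loss_ps": loss_ps,
                "loss_node_id": None if loss_ps is None else lineage.ps_node(loss_ps),
            }
        )
    events = pd.DataFrame(rows, columns=_EVENT_COLS)
    if len(events):
        events["loss_ps"] = events["loss_ps"].astype("Int64")
        events["loss_node_id"] = events["loss_node_id"].astype("Int64")
    excl = pd.DataFrame(excluded, columns=["focal_species", "family_id", "reason"])
    return EventTable(
        focal=lineage.focal, n_strata=lineage.n_strata, events=events, excluded=excl
    )


@dataclass(frozen=True)
class UnionEvents:
    """Whole-tree union of gain and loss events over all lineages.

    Each family has exactly one gain node (single origin); every loss branch
    — identified by its child node id — descends from that gain node.
    """

    gain_node: dict[str, int]
    loss_children: dict[str, frozenset[int]]

    def families_gained_at(self, node: int) -> frozenset[str]:
        return frozenset(f for f, g in self.gain_node.items() if g == node)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": fam,
                "gain_node_id": g,
                "loss_branch_child_ids": ",".join(
                    str(c) for c in sorted(self.loss_children.get(fam, frozenset()))
                ),
            }
            for fam, g in self.gain_node.items()
        ]
        return pd.DataFrame(rows, columns=["family_id", "gain_node_id", "loss_branch_child_ids"])


def union_events(
    fams: FamilyTable, tree: Phylogeny, focal_leaves: Optional[Iterable[str]] = None
) -> UnionEvents:
    """Union of gain/loss events over all root-to-leaf lineages.

    The per-lineage events of every leaf, deduplicated, are equivalent to the
    direct whole-tree reconstruction: one gain at the LCA and one loss on
    every maximal carrier-free branch below it.  The direct form is computed
    here; the per-lineage equivalence is an enforced property.  A
    ``focal_leaves`` restriction only checks that the names are leaves (the
    union over all leaves covers the whole tree).
    """
    if focal_leaves is not None:
        for name in focal_leaves:
            tree.leaf_id(name)
    gains: dict[str, int] = {}
    losses: dict[str, frozenset[int]] = {}
    for fam in fams.family_ids:
        species = fams.species_set(fam)
        g = gain_node(tree, species)
        leaves = _member_leaf_ids(tree, species)
        gains[fam] = g
        lost: set[int] = set()
        stack = [g]
        while stack:
            v = stack.pop()
            for c in tree.children(v):
                if tree.subtree_leaf_ids(c) & leaves:
                    stack.append(c)
                else:
                    lost.add(c)  # maximal carrier-free subtree => Dollo loss
        losses[fam] = frozenset(lost)
    return UnionEvents(gain_node=gains, loss_children=losses)
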