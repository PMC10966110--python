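"""Gene-family content profiles across phylostrata and per-node ancestral
content, plus log2 gain/loss ratio profiles.

Content is cumulative: content_i = content_{i-1} + gains_i - losses_i, with
content_0 = 0; the content at the terminal phylostratum equals the number of
retained families carried by the focal species.  The log2 gain/loss ratio is
left undefined (NaN, not +/-inf, no pseudocount) wherever either count is
zero or i < 3 — raw counts are always emitted alongside, so nothing is lost.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .dollo import DolloError, EventTable, UnionEvents
from .tree import FocalLineage, Phylogeny


def content_profile(events: EventTable, lineage: Optional[FocalLineage] = None) -> pd.DataFrame:
    """Per-phylostratum gains, losses and cumulative family content.

    Columns: ps_index, ps_name, gains, losses, content.  An event with
    loss_ps <= gain_ps + 1 is structurally impossible and raises.
    """
    if lineage is not None:
        if lineage.focal != events.focal or lineage.n_strata != events.n_strata:
            raise DolloError("events and lineage describe different focal paths")
    ev = events.events
    if len(ev):
        loss = ev["loss_ps"].dropna()
        if len(loss) and (loss < ev.loc[loss.index, "gain_ps"] + 2).any():
            raise DolloError("event with loss_ps <= gain_ps + 1")
    gains = events.gains_per_ps()
    losses = events.losses_per_ps()
    content = (gains - losses).cumsum()
    names = [
        lineage.ps_name(i) if lineage is not None else f"ps{i}"
        for i in range(1, events.n_strata + 1)
    ]
    return pd.DataFrame(
        {
            "ps_index": gains.index,
            "ps_name": names,
            "gains": gains.to_numpy(),
            "losses": losses.to_numpy(),
            "content": content.to_numpy(),
        }
    ).reset_index(drop=True)


def log2_gain_loss_ratio(profile: pd.DataFrame) -> pd.DataFrame:
    """Attach log2(gains/losses) per phylostratum.

    Defined only where gains > 0, losses > 0 and ps_index >= 3 (losses are
    structurally impossible earlier); elsewhere NaN with counts intact.
    """
    out = profile.copy()
    g = out["gains"].to_numpy(dtype=float)
    l = out["losses"].to_numpy(dtype=float)
    defined = (g > 0) & (l > 0) & (out["ps_index"].to_numpy() >= 3)
    ratio = np.full(len(out), np.nan)
    ratio[defined] = np.log2(g[defined] / l[defined])
    out["log2_ratio"] = ratio
    return out


def peak_range(profile: pd.DataFrame) -> tuple[int, int]:
    """Inclusive phylostratum range attaining the maximum content (ties spanned)."""
    if not len(profile):
        raise ValueError("empty profile")
    content = profile["content"].to_numpy()
    ps = profile["ps_index"].to_numpy()
    at_max = ps[content == content.max()]
    return int(at_max.min()), int(at_max.max())


def ancestral_content(union: UnionEvents, tree: Phylogeny) -> pd.DataFrame:
    """Family content at every node of the tree.

    A family counts at node v iff its gain node is ancestor-or-equal of v
    and no loss branch separates v from the gain node.  Columns: node_id,
    content.
    """
    counts = np.zeros(tree.n_nodes, dtype=int)
    for fam, g in union.gain_node.items():
        lost = union.loss_children.get(fam, frozenset())
        # presence spreads from the gain node, stopping at loss branches
        stack = [g]
        while stack:
            v = stack.pop()
            counts[v] += 1
            for c in tree.children(v):
                if c not in lost:
                    stack.append(c)
    return pd.DataFrame({"node_id": np.arange(tree.n_nodes), "content": counts})
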