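"""Synthetic gene-family evolution under the Dollo model, with fixture export.

The generator produces exactly the data the inference assumes: a rooted
species tree; families each gained at one node and lost independently on
branches strictly below it (subtrees below a loss are pruned, so no regain);
one or more paralogous proteins per surviving species; and term annotations
with planted term-phylostratum concentration over a uniform background.
Because generation and inference share the model, parameter recovery is
well-posed; a documented violation mode can plant a second, Dollo-violating
origin to exercise the mis-assignment reporting paths.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical configs give byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dollo import EventTable
from .families import FamilyTable, read_annotations, read_mcl_clusters, read_mmseqs_clusters
from .tree import FocalLineage, Phylogeny, parse_newick


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedTerm:
    """A term concentrated among families gained at one phylostratum."""

    term: str
    ps: int
    enriched_rate: float
    background_rate: float


@dataclass(frozen=True)
class SimulationConfig:
    n_leaves: int = 32
    topology: str = "bifurcating"  # "bifurcating" | "caterpillar" | a Newick string
    n_families: int = 300
    gain_weights: Optional[Sequence[float]] = None  # per node id; None = uniform
    loss_prob: float = 0.1  # per-branch loss probability q below the gain node
    paralog_mean: float = 1.5  # mean of the geometric paralog count (support >= 1)
    n_terms: int = 20
    planted: tuple[PlantedTerm, ...] = ()
    background_rate: float = 0.1  # per (family, background term) annotation rate
    violation_rate: float = 0.0  # fraction of families given a second origin
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.loss_prob < 1:
            raise SimulationError("loss_prob must lie in [0, 1)")
        if self.paralog_mean < 1:
            raise SimulationError("paralog_mean must be >= 1")
        for p in self.planted:
            if not (0 <= p.enriched_rate <= 1 and 0 <= p.background_rate <= 1):
                raise SimulationError("planted rates must lie in [0, 1]")
        if not 0 <= self.background_rate <= 1:
            raise SimulationError("background_rate must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Per-family generative record plus the planted term associations."""

    families: pd.DataFrame  # family_id, gain_node_id, loss_branch_child_ids, species, violation
    planted: tuple[PlantedTerm, ...] = ()
    n_regenerated: int = 0

    def to_frame(self) -> pd.DataFrame:
        return self.families.copy()


def simulate_tree(config: SimulationConfig | int, rng: Optional[np.random.Generator] = None) -> Phylogeny:
    """Rooted tree with leaves S1..Sn, deterministic under the config seed."""
    if isinstance(config, int):
        config = SimulationConfig(n_leaves=config)
    n = config.n_leaves
    if n < 2:
        raise SimulationError("n_leaves must be >= 2")
    names = [f"S{i}" for i in range(1, n + 1)]
    if config.topology == "caterpillar":
        nwk = f"({names[0]},{names[1]})"
        for nm in names[2:]:
            nwk = f"({nwk},{nm})"
        return parse_newick(nwk + ";")
    if config.topology == "bifurcating":
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        parts = list(names)
        while len(parts) > 1:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            merged = f"({parts[i]},{parts[j]})"
            parts = [p for t, p in enumerate(parts) if t not in (i, j)] + [merged]
        return parse_newick(parts[0] + ";")
    # user-supplied Newick
    return parse_newick(config.topology)


def _drop_losses(tree: Phylogeny, gain: int, rng: np.random.Generator, q: float) -> tuple[frozenset[int], frozenset[int]]:
    """Simulate per-branch loss below ``gain``; return (surviving leaves, loss children)."""
    lost: set[int] = set()
    survivors: set[int] = set()
    stack = [gain]
    while stack:
        v = stack.pop()
        if tree.is_leaf(v):
            survivors.add(v)
        for c in tree.children(v):
            if q > 0 and rng.random() < q:
                lost.add(c)  # pruned: branches below are never evaluated
            else:
                stack.append(c)
    return frozenset(survivors), frozenset(lost)


def simulate_families(
    tree: Phylogeny, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[FamilyTable, GroundTruth]:
    """Dollo-compatible family evolution on ``tree``.

    Each family draws a gain node, loses branches below it independently
    with probability ``loss_prob`` and keeps the leaves it reaches; families
    losing every species are regenerated so ``n_families`` is exact (the
    count of regenerations is recorded).  Surviving species receive
    geometric paralog counts; protein ids follow ``species|fam|index`` so
    the prefix species convention applies.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    nodes = np.arange(tree.n_nodes)
    if config.gain_weights is not None:
        w = np.asarray(config.gain_weights, dtype=float)
        if w.shape != (tree.n_nodes,) or (w < 0).any() or w.sum() == 0:
            raise SimulationError("gain_weights must be nonnegative per node, not all zero")
        w = w / w.sum()
    else:
        w = None

    members: dict[str, tuple[str, ...]] = {}
    species_of: dict[str, str] = {}
    truth_rows = []
    n_regen = 0
    p_geom = 1.0 / config.paralog_mean
    for idx in range(1, config.n_families + 1):
        fam = f"F{idx:05d}"
        while True:
            gain = int(rng.choice(nodes, p=w))
            survivors, lost = _drop_losses(tree, gain, rng, config.loss_prob)
            violated = False
            if config.violation_rate > 0 and rng.random() < config.violation_rate:
                second = int(rng.choice(nodes, p=w))
                extra, _ = _drop_losses(tree, second, rng, config.loss_prob)
                if extra - survivors:
                    violated = True
                survivors = survivors | extra
            if survivors:
                break
            n_regen += 1
        sp_names = sorted(tree.leaf_name(v) for v in survivors)
        prots = []
        for sp in sp_names:
            for j in range(1, int(rng.geometric(p_geom)) + 1):
                pid = f"{sp}|{fam}|{j}"
                prots.append(pid)
                species_of[pid] = sp
        members[fam] = tuple(prots)
        truth_rows.append(
            {
                "family_id": fam,
                "gain_node_id": gain,
                "loss_branch_child_ids": ",".join(str(c) for c in sorted(lost)),
                "species": ",".join(sp_names),
                "violation": violated,
            }
        )
    fams = FamilyTable(members=members, species_of=species_of, source="simulated")
    truth = GroundTruth(
        families=pd.DataFrame(truth_rows), planted=config.planted, n_regenerated=n_regen
    )
    return fams, truth


def plant_annotations(
    fams: FamilyTable,
    events: EventTable,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, frozenset[str]]:
    """Protein->terms map with planted term-phylostratum concentration.

    For each planted (term, ps, r_e, r_b): families gained at ps on the
    focal lineage receive the term with probability r_e, every other family
    with probability r_b; a receiving family's term goes to all its
    proteins.  The remaining of the ``n_terms`` terms (named T1, T2, ...)
    are scattered uniformly: each family receives each with probability
    ``background_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    for p in config.planted:
        if not 1 <= p.ps <= events.n_strata:
            raise SimulationError(
                f"planted ps {p.ps} outside lineage range 1..{events.n_strata}"
            )
    gained_at: dict[int, set[str]] = {}
    for row in events.events.itertuples(index=False):
        gained_at.setdefault(int(row.gain_ps), set()).add(row.family_id)

    fam_terms: dict[str, set[str]] = {fam: set() for fam in fams.family_ids}
    for p in config.planted:
        target = gained_at.get(p.ps, set())
        for fam in fams.family_ids:
            rate = p.enriched_rate if fam in target else p.background_rate
            if rng.random() < rate:
                fam_terms[fam].add(p.term)
    n_background = max(0, config.n_terms - len(config.planted))
    for t in range(1, n_background + 1):
        term = f"T{t}"
        for fam in fams.family_ids:
            if rng.random() < config.background_rate:
                fam_terms[fam].add(term)

    prot_terms: dict[str, frozenset[str]] = {}
    for fam, prots in fams.members.items():
        terms = frozenset(fam_terms[fam])
        for p_id in prots:
            prot_terms[p_id] = terms
    return prot_terms


def write_fixture_bundle(
    tree: Phylogeny,
    fams: FamilyTable,
    annotations: dict[str, frozenset[str]],
    out_dir,
    truth: Optional[GroundTruth] = None,
) -> dict[str, Path]:
    """Write the full plain-text fixture set for one simulated run.

    Files: ``tree.nwk``, ``clusters.mmseqs.tsv`` (representative = first
    member, self-row included), ``clusters.mcl.txt`` (same partition),
    ``species_map.tsv``, ``annotations.tsv`` and, when ground truth is
    given, ``ground_truth.tsv``.  The cluster files round-trip through the
    family readers to the identical partition.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "mmseqs": out / "clusters.mmseqs.tsv",
        "mcl": out / "clusters.mcl.txt",
        "species_map": out / "species_map.tsv",
        "annotations": out / "annotations.tsv",
    }
    paths["tree"].write_text(tree.to_newick() + "\n")
    with open(paths["mmseqs"], "w") as fh:
        for prots in fams.members.values():
            rep = prots[0]
            fh.write(f"{rep}\t{rep}\n")
            for p in prots[1:]:
                fh.write(f"{rep}\t{p}\n")
    with open(paths["mcl"], "w") as fh:
        for prots in fams.members.values():
            fh.write("\t".join(prots) + "\n")
    with open(paths["species_map"], "w") as fh:
        for prots in fams.members.values():
            for p in prots:
                sp = fams.species_of[p] if fams.species_of else p.split("|", 1)[0]
                fh.write(f"{p}\t{sp}\n")
    with open(paths["annotations"], "w") as fh:
        for prots in fams.members.values():
            for p in prots:
                fh.write(f"{p}\t{','.join(sorted(annotations.get(p, frozenset())))}\n")
    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.tsv"
        truth.to_frame().to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
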