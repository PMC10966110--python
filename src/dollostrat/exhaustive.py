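"""Exhaustive small-tree validation tools for the Dollo reconstruction.

These utilities enumerate every rooted tree shape with a handful of leaves
and reconstruct gain/loss events by brute force — trying every single-gain
node and every loss-branch subset that reproduces a presence/absence pattern
and keeping the minimum-loss solution.  The brute force shares no code with
the LCA-based inference in :mod:`dollostrat.dollo`; agreement between the
two over all shapes and patterns is the correctness argument for the closed
form, and the same enumeration establishes the structural bound that no loss
can be reported before the third phylostratum.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Optional

from .dollo import gain_node, infer_loss, union_events
from .families import FamilyTable
from .tree import FocalLineage, Phylogeny, focal_lineage, parse_newick


def scan_hypergeom_exact(max_universe: int = 60) -> dict:
    """Two-sided hypergeometric p values vs exact integer enumeration.

    For every achievable table (k, K, n, N) with N up to ``max_universe``,
    the implementation (floating-point pmf with tie-tolerant
    minimum-likelihood summation) is compared with an exact rational
    oracle built from binomial coefficients.  Returns the table count and
    the maximum absolute deviation.
    """
    import math

    from scipy import stats

    from .enrichment import _minlik_two_sided

    n_tables = 0
    max_err = 0.0
    for N in range(1, max_universe + 1):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                lo, hi = max(0, n + K - N), min(n, K)
                xs = range(lo, hi + 1)
                nums = [math.comb(K, x) * math.comb(N - K, n - x) for x in xs]
                denom = math.comb(N, n)
                # exact oracle: for each table, sum the numerators of all
                # outcomes no more likely than the observed one
                cum: dict[int, int] = {}
                acc = 0
                for v in sorted(set(nums)):
                    acc += sum(w for w in nums if w == v)
                    cum[v] = acc
                exact = [min(cum[v] / denom, 1.0) for v in nums]
                impl = _minlik_two_sided(
                    stats.hypergeom.pmf(list(xs), N, K, n)
                )
                err = max(abs(a - b) for a, b in zip(impl, exact))
                max_err = max(max_err, err)
                n_tables += len(nums)
    return {"n_tables": n_tables, "max_abs_err": max_err}


def _shape_partitions(n: int, max_part: int, min_parts: int) -> Iterator[tuple[int, ...]]:
    """Non-increasing partitions of n with at least ``min_parts`` parts."""
    def rec(remaining: int, cap: int, acc: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
        if remaining == 0:
            if len(acc) >= min_parts:
                yield acc
            return
        for part in range(min(cap, remaining), 0, -1):
            yield from rec(remaining - part, part, acc + (part,))

    yield from rec(n, max_part, ())


def _shapes(n: int, bifurcating_only: bool) -> list[tuple]:
    """Canonical rooted shapes with n leaves, as sorted nested tuples."""
    if n == 1:
        return [()]
    out: set[tuple] = set()
    for parts in _shape_partitions(n, n - 1, 2):
        if bifurcating_only and len(parts) != 2:
            continue
        child_choices = [_shapes(p, bifurcating_only) for p in parts]
        for combo in itertools.product(*child_choices):
            out.add(tuple(sorted(combo)))
    return sorted(out)


def tree_shapes(n_leaves: int, bifurcating_only: bool = True) -> list[Phylogeny]:
    """All rooted tree shapes with ``n_leaves`` leaves, named S1..Sn.

    Shapes are unlabeled topologies: because downstream checks enumerate
    every presence/absence pattern over the leaves, distinct labelings of
    the same shape are redundant.
    """
    trees = []
    for shape in _shapes(n_leaves, bifurcating_only):
        counter = itertools.count(1)

        def fmt(node: tuple) -> str:
            if node == ():
                return f"S{next(counter)}"
            return "(" + ",".join(fmt(c) for c in node) + ")"

        trees.append(parse_newick(fmt(shape) + ";"))
    return trees


def all_patterns(tree: Phylogeny) -> Iterator[frozenset[str]]:
    """All non-empty presence/absence patterns over the leaves."""
    names = tree.leaf_names
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            yield frozenset(combo)


def brute_force_dollo(
    tree: Phylogeny, present: Iterable[str]
) -> list[tuple[int, frozenset[int]]]:
    """All minimum-loss single-origin reconstructions of a leaf pattern.

    Enumerates every candidate gain node whose subtree covers the pattern
    and, per candidate, loss-branch subsets in order of increasing size
    until the pattern is reproduced; returns every solution attaining the
    global minimum loss count as (gain node, loss children).  Under single
    origin the minimum is unique; callers may assert that.
    """
    present_ids = frozenset(tree.leaf_id(n) for n in present)
    if not present_ids:
        raise ValueError("empty pattern")
    best: list[tuple[int, frozenset[int]]] = []
    best_size: Optional[int] = None
    for g in tree.nodes():
        under = tree.subtree_leaf_ids(g)
        if not present_ids <= under:
            continue
        edges = [v for v in tree.nodes() if v != g and tree.is_ancestor_or_equal(g, v)]
        for size in range(0, len(edges) + 1):
            if best_size is not None and size > best_size:
                break
            matched = False
            for losses in itertools.combinations(edges, size):
                surviving = set(under)
                for c in losses:
                    surviving -= tree.subtree_leaf_ids(c)
                if surviving == present_ids:
                    matched = True
                    if best_size is None or size < best_size:
                        best_size, best = size, [(g, frozenset(losses))]
                    elif size == best_size:
                        best.append((g, frozenset(losses)))
            if matched:
                break  # larger subsets at this gain node cannot be minimal
    return best


def brute_force_loss_ps(
    tree: Phylogeny,
    lineage: FocalLineage,
    gain: int,
    losses: frozenset[int],
) -> Optional[int]:
    """Loss phylostratum implied by one brute-force reconstruction."""

    def present_at(v: int) -> bool:
        if not tree.is_ancestor_or_equal(gain, v):
            return False
        path = tree.path_from_root(v)
        start = path.index(gain)
        return not any(u in losses for u in path[start:])

    for i in range(2, lineage.n_strata + 1):
        if present_at(lineage.ps_node(i - 1)) and not present_at(lineage.ps_node(i)):
            return i
    return None


def _single_protein_table(tree: Phylogeny, pattern: frozenset[str]) -> FamilyTable:
    prots = tuple(f"{s}|pat|1" for s in sorted(pattern))
    return FamilyTable(
        members={"pat": prots}, species_of={p: p.split("|")[0] for p in prots}
    )


def scan_loss_phylostrata(
    leaf_counts: Iterable[int] = (4, 5, 6), bifurcating_only: bool = True
) -> dict:
    """Every loss_ps reported over all shapes, patterns and focal leaves.

    Returns the minimum reported loss phylostratum, the number of
    (shape, pattern, focal) combinations examined, and how many violated
    the structural bounds loss_ps >= 3 and loss_ps >= gain_ps + 2 (zero,
    by construction of the reconstruction).
    """
    min_loss: Optional[int] = None
    n_checked = 0
    n_losses = 0
    n_violations = 0
    for n in leaf_counts:
        for tree in tree_shapes(n, bifurcating_only):
            for pattern in all_patterns(tree):
                g = gain_node(tree, pattern)
                for focal in tree.leaf_names:
                    lin = focal_lineage(tree, focal)
                    gain_ps = lin.node_to_ps(g)
                    if gain_ps is None:
                        continue
                    n_checked += 1
                    loss_ps = infer_loss(tree, lin, pattern, gain_ps)
                    if loss_ps is None:
                        continue
                    n_losses += 1
                    if loss_ps < 3 or loss_ps < gain_ps + 2:
                        n_violations += 1
                    min_loss = loss_ps if min_loss is None else min(min_loss, loss_ps)
    return {
        "min_loss_ps": min_loss,
        "n_lineage_patterns": n_checked,
        "n_loss_events": n_losses,
        "n_bound_violations": n_violations,
    }


def scan_oracle_agreement(
    leaf_counts: Iterable[int] = (2, 3, 4, 5, 6), bifurcating_only: bool = False
) -> dict:
    """LCA-based reconstruction vs the brute-force minimum-loss oracle.

    For every shape and pattern, checks that the oracle's minimal solution
    is unique and identical to the closed form: same gain node, same loss
    branches (via union_events), and — per focal leaf — the same loss
    phylostratum.  Returns counts of comparisons and disagreements.
    """
    n_patterns = 0
    n_disagree = 0
    n_nonunique = 0
    for n in leaf_counts:
        for tree in tree_shapes(n, bifurcating_only):
            for pattern in all_patterns(tree):
                n_patterns += 1
                solutions = brute_force_dollo(tree, pattern)
                if len(solutions) != 1:
                    n_nonunique += 1
                    continue
                oracle_gain, oracle_losses = solutions[0]
                fams = _single_protein_table(tree, pattern)
                union = union_events(fams, tree)
                impl_gain = union.gain_node["pat"]
                impl_losses = union.loss_children["pat"]
                ok = impl_gain == oracle_gain and impl_losses == oracle_losses
                if ok:
                    for focal in tree.leaf_names:
                        lin = focal_lineage(tree, focal)
                        gain_ps = lin.node_to_ps(impl_gain)
                        if gain_ps is None:
                            continue
                        impl_loss = infer_loss(tree, lin, pattern, gain_ps)
                        oracle_loss = brute_force_loss_ps(tree, lin, oracle_gain, oracle_losses)
                        if impl_loss != oracle_loss:
                            ok = False
                            break
                if not ok:
                    n_disagree += 1
    return {
        "n_patterns": n_patterns,
        "n_disagreements": n_disagree,
        "n_nonunique_minima": n_nonunique,
    }
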