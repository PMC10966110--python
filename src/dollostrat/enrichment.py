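"""Phylostratum-wise functional enrichment of gained and lost families.

For one focal lineage and one clustering run, each functional term is tested
per phylostratum with a two-tailed hypergeometric test: the frequency of the
term among families gained (or lost) at that phylostratum is compared to the
overall frequency of the term in the lineage-wide universe of event families.
Two-sidedness follows the minimum-likelihood convention (sum of all outcomes
whose pmf does not exceed that of the observed table), the standard exact
two-sided rule for Fisher-type tests.  Effect sizes are log2 odds ratios with
the Haldane–Anscombe +0.5 correction so degenerate tables stay finite.
P values are Benjamini–Hochberg adjusted, by default jointly across all
(term, phylostratum) pairs of one run and direction.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dollo import EventTable
from .families import NA_TERM, AnnotationMap

#: relative tolerance for pmf ties in the minimum-likelihood sum; pmf values
#: that differ only by floating-point noise count as equally likely
_TIE_RTOL = 1e-9


class EnrichmentError(ValueError):
    pass


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise EnrichmentError(f"invalid margins K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise EnrichmentError(f"k={k} outside achievable range for K={K}, n={n}, N={N}")


def _minlik_two_sided(pmf: np.ndarray) -> np.ndarray:
    """Minimum-likelihood two-sided p for every support point of a pmf."""
    mask = pmf[np.newaxis, :] <= pmf[:, np.newaxis] * (1.0 + _TIE_RTOL)
    return np.minimum(mask @ pmf, 1.0)


def hypergeom_two_sided(k: int, K: int, n: int, N: int) -> float:
    """Exact two-tailed hypergeometric p value (minimum-likelihood method).

    k = annotated successes in the sample, K = annotated in the universe,
    n = sample size, N = universe size.  p = sum of P(x) over all achievable
    x with P(x) <= P(k), clamped to <= 1.
    """
    _check_counts(k, K, n, N)
    lo, hi = max(0, n + K - N), min(n, K)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, N, K, n)
    return float(_minlik_two_sided(pmf)[k - lo])


def log_odds(k: int, K: int, n: int, N: int) -> float:
    """log2 odds ratio of the 2x2 table with +0.5 in every cell.

    Cells: [k, n-k; K-k, N-K-n+k].  The continuity correction keeps k=0 and
    k=n tables finite and makes the statistic antisymmetric under swapping
    the annotated/unannotated columns.
    """
    _check_counts(k, K, n, N)
    a = k + 0.5
    b = n - k + 0.5
    c = K - k + 0.5
    d = N - K - n + k + 0.5
    return float(np.log2((a * d) / (c * b)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise EnrichmentError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_RECORD_COLS = [
    "focal_species", "direction", "term", "ps_index",
    "k", "n", "K", "N", "log_odds", "p_raw", "p_adj", "significant",
]


def enrich(
    events: EventTable,
    ann: AnnotationMap,
    direction: str = "gain",
    alpha: float = 0.05,
    universe_mode: str = "all",
    bh_scope: str = "joint",
) -> pd.DataFrame:
    """Per-(term, phylostratum) enrichment records for one lineage and run.

    The universe is the set of families with an event of the requested
    direction: for gains under ``universe_mode="all"`` every family in the
    event table; under ``"lost_only"`` (and always for losses) only families
    with a loss event.  Records are emitted for every (term, ps) with n > 0
    and K > 0, including k = 0 (depletion is testable two-sidedly).
    ``bh_scope`` chooses the BH pool: ``"joint"`` across all (term, ps)
    pairs, ``"per_term"`` within each term across phylostrata.
    """
    if direction not in ("gain", "loss"):
        raise EnrichmentError(f"direction must be 'gain' or 'loss', got {direction!r}")
    if universe_mode not in ("all", "lost_only"):
        raise EnrichmentError(f"unknown universe_mode {universe_mode!r}")
    if bh_scope not in ("joint", "per_term"):
        raise EnrichmentError(f"unknown bh_scope {bh_scope!r}")

    ev = events.events
    if direction == "loss" or universe_mode == "lost_only":
        ev = ev[ev["loss_ps"].notna()]
    if not len(ev):
        return pd.DataFrame(columns=_RECORD_COLS)

    ps_col = "gain_ps" if direction == "gain" else "loss_ps"
    fam_ids = ev["family_id"].tolist()
    fam_ps = dict(zip(fam_ids, ev[ps_col].astype(int).tolist()))
    N = len(fam_ids)

    term_members: dict[str, set[str]] = {}
    for fam in fam_ids:
        # families without any transferred term carry the reserved NA
        # pseudo-term so they stay in the universe and are testable
        terms = ann.family_terms.get(fam) or frozenset((NA_TERM,))
        for t in terms:
            term_members.setdefault(t, set()).add(fam)

    ps_members: dict[int, set[str]] = {}
    for fam, ps in fam_ps.items():
        ps_members.setdefault(ps, set()).add(fam)

    rows = []
    for term, carriers in sorted(term_members.items()):
        K = len(carriers)
        for ps, at_ps in sorted(ps_members.items()):
            n = len(at_ps)
            k = len(carriers & at_ps)
            rows.append(
                {
                    "focal_species": events.focal,
                    "direction": direction,
                    "term": term,
                    "ps_index": ps,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "log_odds": log_odds(k, K, n, N),
                    "p_raw": hypergeom_two_sided(k, K, n, N),
                }
            )
    rec = pd.DataFrame(rows, columns=_RECORD_COLS[:-2])
    if bh_scope == "joint":
        rec["p_adj"] = bh_adjust(rec["p_raw"])
    else:
        rec["p_adj"] = (
            rec.groupby("term")["p_raw"].transform(lambda p: bh_adjust(p.to_numpy()))
        )
    rec["significant"] = rec["p_adj"] < alpha
    return rec


def enrichment_frequency(
    records: pd.DataFrame, terms_tested: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Overall enrichment frequency: the percentage of tested terms showing
    significant enrichment in at least one phylostratum.

    One row per (focal_species, direction).  With zero tested terms the
    frequency is emitted empty (NaN).
    """
    if terms_tested is None:
        terms = set(records["term"].unique()) if len(records) else set()
    else:
        terms = set(terms_tested)
    rows = []
    groups = (
        records.groupby(["focal_species", "direction"], sort=True)
        if len(records)
        else []
    )
    for (focal, direction), grp in groups:
        enriched = grp.loc[grp["significant"], "term"].nunique()
        n_tested = len(terms)
        rows.append(
            {
                "focal_species": focal,
                "direction": direction,
                "terms_tested": n_tested,
                "terms_enriched": int(enriched),
                "frequency_pct": 100.0 * enriched / n_tested if n_tested else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["focal_species", "direction", "terms_tested", "terms_enriched", "frequency_pct"],
    )


def gain_loss_balance(records_gain: pd.DataFrame, records_loss: pd.DataFrame) -> dict:
    """Counts of significantly enriched terms among gains vs losses and
    their ratio (NaN when no loss-side term is enriched).

    Meaningful when both record sets were computed on the lost-only universe,
    i.e. restricted to families that have a loss event.
    """
    n_gain = int(records_gain.loc[records_gain["significant"], "term"].nunique()) if len(records_gain) else 0
    n_loss = int(records_loss.loc[records_loss["significant"], "term"].nunique()) if len(records_loss) else 0
    ratio = n_gain / n_loss if n_loss else np.nan
    return {"gain_enriched_terms": n_gain, "loss_enriched_terms": n_loss, "ratio": ratio}
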