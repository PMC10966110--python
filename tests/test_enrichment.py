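"""Hypergeometric testing, effect sizes, BH correction and enrichment tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dollostrat as ds
from dollostrat.dollo import EventTable
from dollostrat.enrichment import EnrichmentError
from dollostrat.exhaustive import scan_hypergeom_exact
from dollostrat.families import NA_TERM, AnnotationMap


@st.composite
def tables(draw, max_n=40):
    N = draw(st.integers(1, max_n))
    K = draw(st.integers(0, N))
    n = draw(st.integers(0, N))
    k = draw(st.integers(max(0, n + K - N), min(n, K)))
    return k, K, n, N


class TestHypergeomTwoSided:
    def test_worked_table(self):
        # pmf over x in 0..4 is [6,60,120,60,6]/252; outcomes as unlikely as
        # x=4 are {0,4}, so p = 12/252
        assert ds.hypergeom_two_sided(4, 4, 5, 10) == pytest.approx(12 / 252)

    def test_symmetric_extremes(self):
        assert ds.hypergeom_two_sided(5, 5, 5, 10) == pytest.approx(2 / 252)

    def test_single_outcome(self):
        assert ds.hypergeom_two_sided(5, 5, 5, 5) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(EnrichmentError):
            ds.hypergeom_two_sided(3, 2, 5, 10)
        with pytest.raises(EnrichmentError):
            ds.hypergeom_two_sided(0, 4, 11, 10)

    def test_exact_enumeration_small_universes(self):
        # the acceptance suite sweeps N <= 60; this covers N <= 25
        result = scan_hypergeom_exact(25)
        assert result["max_abs_err"] < 1e-12

    @settings(deadline=None, max_examples=200)
    @given(tables())
    def test_two_sided_at_least_smaller_tail(self, table):
        # the minimum-likelihood two-sided p contains the whole tail on the
        # far side of the mode, so it can never undercut the smaller
        # one-sided p
        k, K, n, N = table
        from scipy import stats

        upper = stats.hypergeom.sf(k - 1, N, K, n)
        lower = stats.hypergeom.cdf(k, N, K, n)
        assert ds.hypergeom_two_sided(k, K, n, N) >= min(upper, lower) - 1e-12


class TestLogOdds:
    def test_balanced_table(self):
        assert ds.log_odds(2, 4, 5, 10) == pytest.approx(0.0)

    def test_saturated_table(self):
        assert ds.log_odds(4, 4, 5, 10) == pytest.approx(math.log2(33))

    def test_empty_cell_stays_finite(self):
        assert ds.log_odds(0, 4, 5, 10) == pytest.approx(-math.log2(33))

    @settings(deadline=None, max_examples=200)
    @given(tables())
    def test_antisymmetry_under_column_swap(self, table):
        k, K, n, N = table
        # swapping annotated/unannotated: k' = n - k, K' = N - K
        assert ds.log_odds(k, K, n, N) == pytest.approx(
            -ds.log_odds(n - k, N - K, n, N), abs=1e-9
        )


class TestBhAdjust:
    def test_step_up_by_hand(self):
        assert ds.bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_and_degenerate(self):
        assert ds.bh_adjust([0.5]) == pytest.approx([0.5])
        assert ds.bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, ps):
        adj = ds.bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _event_table(rows, focal="X", n_strata=5):
    df = pd.DataFrame(
        [
            {
                "focal_species": focal,
                "family_id": fam,
                "gain_ps": g,
                "gain_node_id": 0,
                "loss_ps": l,
                "loss_node_id": None,
            }
            for fam, g, l in rows
        ],
        columns=["focal_species", "family_id", "gain_ps", "gain_node_id", "loss_ps", "loss_node_id"],
    )
    if len(df):
        df["loss_ps"] = df["loss_ps"].astype("Int64")
    return EventTable(focal=focal, n_strata=n_strata, events=df)


def _annotation(fam_terms):
    return AnnotationMap(protein_terms={}, family_terms={f: frozenset(t) for f, t in fam_terms.items()})


class TestEnrich:
    def _worked_inputs(self):
        # universe of 10 gained families; term T carried by 4; 5 families
        # gained at ps2, 4 of them carrying T
        rows = [(f"f{i}", 2, None) for i in range(5)] + [(f"g{i}", 1, None) for i in range(5)]
        terms = {f"f{i}": {"T"} for i in range(4)}
        terms["f4"] = set()
        return _event_table(rows), _annotation(terms)

    def test_worked_example(self):
        events, ann = self._worked_inputs()
        rec = ds.enrich(events, ann, direction="gain")
        row = rec[(rec.term == "T") & (rec.ps_index == 2)].iloc[0]
        assert (row.k, row.n, row.K, row.N) == (4, 5, 4, 10)
        assert row.p_raw == pytest.approx(12 / 252)
        assert row.log_odds == pytest.approx(math.log2(33))
        assert row.p_raw < 0.05  # significant before correction

    def test_unannotated_families_become_na_universe(self):
        events, ann = self._worked_inputs()
        rec = ds.enrich(events, ann, direction="gain")
        assert "NA" in set(rec.term)
        assert (rec.N == 10).all()

    def test_absent_term_not_tested(self):
        events, ann = self._worked_inputs()
        rec = ds.enrich(events, ann, direction="gain")
        assert "UNSEEN" not in set(rec.term)

    def test_depletion_record_retained(self):
        events, ann = self._worked_inputs()
        rec = ds.enrich(events, ann, direction="gain")
        assert len(rec[(rec.term == "T") & (rec.ps_index == 1) & (rec.k == 0)]) == 1

    def test_loss_direction_uses_loss_universe(self):
        rows = [("a", 1, 3), ("b", 1, 4), ("c", 1, None), ("d", 2, None)]
        events = _event_table(rows)
        ann = _annotation({"a": {"T"}, "b": set(), "c": {"T"}, "d": set()})
        rec = ds.enrich(events, ann, direction="loss")
        assert (rec.N == 2).all()  # only families with a loss event
        assert set(rec.ps_index) == {3, 4}

    def test_lost_only_universe_for_gains(self):
        rows = [("a", 1, 3), ("b", 2, 4), ("c", 1, None)]
        events = _event_table(rows)
        ann = _annotation({"a": {"T"}, "b": {"T"}, "c": {"T"}})
        rec = ds.enrich(events, ann, direction="gain", universe_mode="lost_only")
        assert (rec.N == 2).all()
        assert set(rec.ps_index) == {1, 2}

    def test_bh_scope_switch(self):
        events, ann = self._worked_inputs()
        joint = ds.enrich(events, ann, direction="gain", bh_scope="joint")
        per_term = ds.enrich(events, ann, direction="gain", bh_scope="per_term")
        assert (joint.p_adj >= joint.p_raw - 1e-15).all()
        assert (per_term.p_adj >= per_term.p_raw - 1e-15).all()
        # per-term pools are smaller, so the correction is never harsher
        merged = joint.merge(per_term, on=["term", "ps_index"], suffixes=("_j", "_t"))
        assert (merged.p_adj_t <= merged.p_adj_j + 1e-12).all()


class TestSummaries:
    def _records(self, sig_terms, all_terms):
        rows = []
        for t in all_terms:
            rows.append(
                {
                    "focal_species": "X",
                    "direction": "gain",
                    "term": t,
                    "ps_index": 2,
                    "significant": t in sig_terms,
                }
            )
        return pd.DataFrame(rows)

    def test_frequency_fraction(self):
        rec = self._records({"a"}, ["a", "b", "c"])
        freq = ds.enrichment_frequency(rec)
        assert freq.frequency_pct.iloc[0] == pytest.approx(100 / 3)

    def test_frequency_extremes(self):
        assert ds.enrichment_frequency(self._records(set(), ["a", "b"])).frequency_pct.iloc[0] == 0.0
        assert ds.enrichment_frequency(self._records({"a", "b"}, ["a", "b"])).frequency_pct.iloc[0] == 100.0

    def test_frequency_with_explicit_term_list(self):
        rec = self._records({"a"}, ["a", "b"])
        freq = ds.enrichment_frequency(rec, terms_tested=["a", "b", "c", "d"])
        assert freq.frequency_pct.iloc[0] == pytest.approx(25.0)

    def test_balance_ratio(self):
        g = self._records({f"t{i}" for i in range(10)}, [f"t{i}" for i in range(12)])
        l = self._records({f"t{i}" for i in range(4)}, [f"t{i}" for i in range(12)])
        out = ds.gain_loss_balance(g, l)
        assert out == {"gain_enriched_terms": 10, "loss_enriched_terms": 4, "ratio": 2.5}

    def test_balance_degenerate(self):
        empty = self._records(set(), ["a"])
        out = ds.gain_loss_balance(empty, empty)
        assert out["gain_enriched_terms"] == 0 and out["loss_enriched_terms"] == 0
        assert np.isnan(out["ratio"])

    def test_balance_identical_sets(self):
        g = self._records({"a", "b"}, ["a", "b", "c"])
        assert ds.gain_loss_balance(g, g.copy())["ratio"] == 1.0
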