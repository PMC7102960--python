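"""Motif enumeration and exact scanning against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_match_starts
from quadlock.reference import AGRO100, AT26
from quadlock.sequence_motifs import (MotifHit, MotifQuery, TractSpec,
                                      compile_query, decompose_tracts,
                                      enumerate_queries, reverse_complement,
                                      scan_sequence)


class TestDecomposeTracts:
    def test_at26_run_content(self):
        d = decompose_tracts(AT26)
        assert d.n_guanines == 16
        assert d.g_run_count(2) == 7
        assert d.g_run_count(1) == 2
        assert len(AT26) == 28

    @pytest.mark.parametrize(
        "seq, g_runs, other_runs",
        [("GGGG", (4,), 0), ("TTTT", (), 1), ("gGtTg", (2, 1), 1),
         ("NGN", (1,), 2)],
    )
    def test_maximal_runs(self, seq, g_runs, other_runs):
        d = decompose_tracts(seq)
        assert d.g_run_lengths == g_runs
        assert sum(1 for r in d.runs if r.base == "other") == other_runs

    def test_runs_tile_the_sequence(self):
        d = decompose_tracts("GGTTAGGGNAC")
        assert sum(r.length for r in d.runs) == 11
        assert all(
            a.start + a.length == b.start
            for a, b in zip(d.runs, d.runs[1:])
        )

    def test_errors_name_position(self):
        with pytest.raises(ValueError):
            decompose_tracts("")
        with pytest.raises(ValueError, match="position 2"):
            decompose_tracts("GGXGG")


class TestEnumerateQueries:
    def test_irregular_family_count(self):
        qs = enumerate_queries(9, 2, 1, 2)
        assert len(qs) == 36
        assert qs.family_name == "7G2+2G1"
        assert len({q.label for q in qs}) == 36

    def test_single_query_family(self):
        qs = enumerate_queries(8, 0, 1, 2)
        assert len(qs) == 1
        assert qs.family_name == "8G2"
        assert all(t.min_len == 2 for t in qs.queries[0].tracts)

    def test_binomial_identity_exhaustive(self):
        for n in range(2, 13):
            for m in range(0, n + 1):
                assert len(enumerate_queries(n, m, 1, 2)) == math.comb(n, m)

    def test_labels_sorted_lexicographically(self):
        labels = [q.label for q in enumerate_queries(9, 2, 1, 2)]
        assert labels == sorted(labels)

    @pytest.mark.parametrize(
        "args", [(1, 0, 1, 2), (8, 9, 1, 2), (8, 0, 2, 1), (8, 0, 0, 2)]
    )
    def test_invalid_bounds(self, args):
        with pytest.raises(ValueError):
            enumerate_queries(*args)


class TestCompileQuery:
    def test_open_ended_matches_constructed_instance(self):
        q = enumerate_queries(8, 0, 1, 2).queries[0]
        pat = compile_query(q)
        m = pat.match("GGTGGTGGTGGTGGTGGTGGTGG")
        assert m and m.end() == 23

    def test_isolated_g_interrupts_8_tract_run(self):
        q = enumerate_queries(8, 0, 1, 2).queries[0]
        hits = scan_sequence(AGRO100, enumerate_queries(8, 0, 1, 2),
                             "all_overlapping")
        assert hits == []
        assert brute_force_match_starts(
            AGRO100, tuple(t.min_len for t in q.tracts), 1, 2
        ) == set()

    def test_strict_rejects_long_tract(self):
        seq = "GGGTGGTGGTGGTGGTGGTGGTGGTT"
        qs = enumerate_queries(8, 0, 1, 2)
        assert scan_sequence(seq, qs, strict_tracts=True) == []
        assert len(scan_sequence(seq, qs)) == 1


class TestScanSequence:
    def test_at26_matches_exactly_one_irregular_query(self):
        qs = enumerate_queries(9, 2, 1, 2)
        hits = scan_sequence(AT26, qs, "all_overlapping", sequence_id="AT26")
        labels = {h.query_label for h in hits}
        # the only consistent placement puts the single guanines at tract
        # positions 5 and 9 (5'->3': GG,GG,GG,GG,G,GG,GG,GG,G)
        assert labels == {"7G2+2G1:05-09"}
        # confirmed by the brute-force substring oracle over all 36 queries
        for q in qs:
            minima = tuple(t.min_len for t in q.tracts)
            starts = brute_force_match_starts(AT26, minima, 1, 2)
            expected = {h.start for h in hits if h.query_label == q.label}
            assert starts == expected

    def test_hits_round_trip_through_their_query(self):
        qs = enumerate_queries(9, 2, 1, 2)
        by_label = {q.label: q for q in qs}
        for h in scan_sequence(AT26, qs, "all_overlapping"):
            pat = compile_query(by_label[h.query_label])
            assert pat.fullmatch(h.matched_text)

    def test_strand_symmetry(self):
        seq = "GGAGGAGGAGGAGGAGGAGGAGG"
        qs = enumerate_queries(8, 0, 1, 2)
        fwd = scan_sequence(seq, qs, strand="fwd")
        rev = scan_sequence(reverse_complement(seq), qs, strand="rev")
        assert len(fwd) == len(rev) == 1
        L = len(seq)
        assert {(L - h.end, L - h.start) for h in rev} == {
            (h.start, h.end) for h in fwd
        }

    def test_n_matches_nothing(self):
        qs = enumerate_queries(2, 0, 1, 2)
        assert scan_sequence("GGNGG", qs, "all_overlapping") == []
        assert len(scan_sequence("GGTGG", qs, "all_overlapping")) == 1

    def test_hit_ordering_and_invariants(self):
        qs = enumerate_queries(2, 1, 1, 2)
        hits = scan_sequence("GGTGGTACGTGGTG", qs, "all_overlapping")
        keys = [h.sort_key for h in hits]
        assert keys == sorted(keys)
        for h in hits:
            assert h.end - h.start == len(h.matched_text)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=120))
    def test_scanner_equals_brute_force_oracle(self, seq):
        qs = enumerate_queries(3, 1, 1, 2)
        hits = scan_sequence(seq, qs, "all_overlapping") if seq else []
        for q in qs:
            minima = tuple(t.min_len for t in q.tracts)
            expected = brute_force_match_starts(seq, minima, 1, 2)
            got = {h.start for h in hits if h.query_label == q.label}
            assert got == expected


class TestTypes:
    def test_tract_and_query_invariants(self):
        with pytest.raises(ValueError):
            TractSpec(0)
        with pytest.raises(ValueError):
            MotifQuery((TractSpec(2),), 1, 2, "x")
        with pytest.raises(ValueError):
            MotifHit("s", 5, 5, "+", "q", "")

    def test_queryset_round_trips_through_json_dict(self):
        qs = enumerate_queries(9, 2, 1, 2)
        from quadlock.sequence_motifs import QuerySet

        assert QuerySet.from_dict(qs.to_dict()) == qs
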