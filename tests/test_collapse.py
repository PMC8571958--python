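"""Collapsing, 5'-degradation flagging and the four-condition keep filter."""

import itertools

import networkx as nx
import pytest

from isopipe.collapse import (
    REASON_ANNOTATED,
    REASON_HIGH_PID,
    REASON_JUNCTIONS,
    REASON_MULTI_FLNC,
    apply_keep_filter,
    collapse_flnc,
    flag_5prime_degraded,
    splice_chain,
)
from isopipe.io_formats import JunctionSupportSet, ReferenceAnnotation

from conftest import make_isoform, make_read, make_transcript


class TestSpliceChain:
    @pytest.mark.parametrize(
        "exons,chain",
        [
            ([(100, 200), (300, 400)], ((200, 300),)),
            ([(100, 200)], ()),
            ([(100, 200), (300, 400), (500, 600)], ((200, 300), (400, 500))),
        ],
    )
    def test_chain(self, exons, chain):
        assert splice_chain(make_transcript("t", exons)) == chain


class TestCollapse:
    def test_shared_chain_merges_with_furthest_termini(self):
        reads = [
            make_read("a", [(120, 200), (300, 400)]),
            make_read("b", [(100, 200), (300, 420)]),
            make_read("c", [(150, 200), (300, 410)]),
        ]
        (iso,) = collapse_flnc(reads)
        assert iso.n_flnc == 3
        assert iso.model.exons == ((100, 200), (300, 420))
        assert iso.supporting_flnc_ids == ("a", "b", "c")

    def test_different_chains_stay_separate(self):
        reads = [
            make_read("a", [(100, 200), (300, 400)]),
            make_read("b", [(100, 200), (320, 400)]),
        ]
        assert len(collapse_flnc(reads)) == 2

    def test_single_exon_overlap_merges(self):
        reads = [make_read("a", [(100, 200)]), make_read("b", [(199, 300)])]
        (iso,) = collapse_flnc(reads)
        assert iso.model.exons == ((100, 300),)

    def test_single_exon_opposite_strands_stay_separate(self):
        reads = [
            make_read("a", [(100, 200)], strand="+"),
            make_read("b", [(150, 300)], strand="-"),
        ]
        assert len(collapse_flnc(reads)) == 2

    def test_order_invariant_and_conserves_support(self, rng):
        reads = []
        for i in range(60):
            s = int(rng.integers(0, 5_000))
            if rng.random() < 0.5:
                exons = [(s, s + 100), (s + 300, s + 400)]
            else:
                exons = [(s, s + int(rng.integers(50, 300)))]
            reads.append(make_read(f"r{i}", exons))
        base = collapse_flnc(reads)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        again = collapse_flnc(shuffled)
        key = lambda isos: sorted(
            (i.model.exons, i.supporting_flnc_ids) for i in isos
        )
        assert key(base) == key(again)
        assert sum(i.n_flnc for i in base) == len(reads)

    def test_idempotent(self, rng):
        reads = [
            make_read(f"r{i}", [(s, s + 80), (s + 200, s + 300)])
            for i, s in enumerate(rng.integers(0, 2_000, size=30))
        ]
        once = collapse_flnc(reads)
        again = collapse_flnc(
            [
                make_read(i.model.transcript_id, i.model.exons)
                for i in once
            ]
        )
        assert sorted(i.model.exons for i in again) == sorted(
            i.model.exons for i in once
        )

    def test_single_exon_grouping_matches_connected_components(self, rng):
        """Single-linkage sweep equals brute-force components of the
        overlap graph (oracle via networkx)."""
        for _ in range(30):
            n = int(rng.integers(2, 50))
            reads = []
            for i in range(n):
                s = int(rng.integers(0, 3_000))
                reads.append(make_read(f"r{i}", [(s, s + int(rng.integers(1, 500)))]))
            got = {
                frozenset(iso.supporting_flnc_ids) for iso in collapse_flnc(reads)
            }
            g = nx.Graph()
            g.add_nodes_from(r.read_id for r in reads)
            for a, b in itertools.combinations(reads, 2):
                if (
                    min(a.exons[0][1], b.exons[0][1])
                    > max(a.exons[0][0], b.exons[0][0])
                ):
                    g.add_edge(a.read_id, b.read_id)
            expected = {frozenset(c) for c in nx.connected_components(g)}
            assert got == expected


class TestDegradation:
    def test_3p_suffix_with_shared_tes_is_flagged(self):
        full = make_isoform(
            "B", [(0, 100), (200, 300), (400, 500), (600, 700)], n_flnc=3
        )
        frag = make_isoform("A", [(250, 300), (400, 500), (600, 700)])
        kept, degraded = flag_5prime_degraded([full, frag])
        assert [i.model.transcript_id for i in degraded] == ["A"]
        assert [i.model.transcript_id for i in kept] == ["B"]

    def test_5p_prefix_is_not_degradation_on_plus_strand(self):
        full = make_isoform("B", [(0, 100), (200, 300), (400, 500), (600, 700)])
        # shares the 5'-terminal introns but stops early: 3' truncation
        trunc = make_isoform("A", [(0, 100), (200, 300), (400, 450)])
        kept, degraded = flag_5prime_degraded([full, trunc])
        assert degraded == []
        assert len(kept) == 2

    def test_minus_strand_suffix_is_genomic_prefix(self):
        full = make_isoform(
            "B", [(0, 100), (200, 300), (400, 500), (600, 700)], strand="-"
        )
        frag = make_isoform("A", [(0, 100), (200, 300), (400, 450)], strand="-")
        kept, degraded = flag_5prime_degraded([full, frag])
        assert [i.model.transcript_id for i in degraded] == ["A"]

    def test_distant_tes_not_flagged(self):
        full = make_isoform("B", [(0, 100), (200, 300), (400, 500)])
        frag = make_isoform("A", [(250, 300), (400, 700)])  # 3' end 200 nt away
        kept, degraded = flag_5prime_degraded([full, frag], tes_tolerance=50)
        assert degraded == []

    def test_recredit_moves_support_to_parent(self):
        full = make_isoform("B", [(0, 100), (200, 300), (400, 500)], n_flnc=2)
        frag = make_isoform("A", [(250, 300), (400, 500)], n_flnc=2)
        kept, _ = flag_5prime_degraded([full, frag], recredit_support=True)
        (parent,) = kept
        assert parent.n_flnc == 4


def _annotation_with_intron(d, a):
    return ReferenceAnnotation(
        [make_transcript("rt", [(d - 100, d), (a, a + 100)], gene="g")]
    )


class TestKeepFilter:
    def test_two_flnc_kept_regardless_of_pid(self):
        iso = make_isoform("i", [(0, 100), (200, 300)], n_flnc=2, pid=90.0)
        kept, (dec,) = apply_keep_filter(
            [iso], JunctionSupportSet(), ReferenceAnnotation([])
        )
        assert kept and dec.reason == REASON_MULTI_FLNC

    def test_single_flnc_needs_pid_strictly_above_threshold(self):
        hi = make_isoform("hi", [(0, 100), (200, 300)], n_flnc=1, pid=99.5)
        at = make_isoform("at", [(0, 100), (200, 300)], n_flnc=1, pid=99.0)
        kept, decs = apply_keep_filter(
            [hi, at], JunctionSupportSet(), ReferenceAnnotation([])
        )
        assert [i.model.transcript_id for i in kept] == ["hi"]
        assert decs[0].reason == REASON_HIGH_PID
        assert not decs[1].kept

    def test_full_junction_support_rescues(self):
        iso = make_isoform("i", [(0, 100), (200, 300)], n_flnc=1, pid=95.0)
        jset = JunctionSupportSet()
        jset.add("1", "+", 100, 200, 3)
        kept, (dec,) = apply_keep_filter([iso], jset, ReferenceAnnotation([]))
        assert kept and dec.reason == REASON_JUNCTIONS

    def test_partial_junction_support_is_not_enough(self):
        iso = make_isoform(
            "i", [(0, 100), (200, 300), (400, 500)], n_flnc=1, pid=95.0
        )
        jset = JunctionSupportSet()
        jset.add("1", "+", 100, 200, 3)  # second intron unsupported
        kept, (dec,) = apply_keep_filter([iso], jset, ReferenceAnnotation([]))
        assert not kept and not dec.kept

    def test_annotated_junctions_rescue(self):
        iso = make_isoform("i", [(0, 100), (200, 300)], n_flnc=1, pid=95.0)
        kept, (dec,) = apply_keep_filter(
            [iso], JunctionSupportSet(), _annotation_with_intron(100, 200)
        )
        assert kept and dec.reason == REASON_ANNOTATED

    def test_all_conditions_fail_drops(self):
        iso = make_isoform("i", [(0, 100), (200, 300)], n_flnc=1, pid=98.0)
        kept, (dec,) = apply_keep_filter(
            [iso], JunctionSupportSet(), ReferenceAnnotation([])
        )
        assert kept == [] and dec.reason == "dropped"

    def test_mono_exon_vacuous_reason_is_audited(self):
        iso = make_isoform("i", [(0, 100)], n_flnc=1, pid=95.0)
        kept, (dec,) = apply_keep_filter(
            [iso], JunctionSupportSet(), ReferenceAnnotation([])
        )
        assert kept and dec.reason.endswith("_vacuous")

    def test_filter_monotone_in_support(self, rng):
        """Adding an FLNC to an isoform never flips kept -> dropped."""
        jset = JunctionSupportSet()
        ann = ReferenceAnnotation([])
        for _ in range(50):
            n = int(rng.integers(1, 4))
            pid = float(rng.uniform(95, 100))
            iso = make_isoform("i", [(0, 100), (200, 300)], n_flnc=n, pid=pid)
            more = make_isoform("i", [(0, 100), (200, 300)], n_flnc=n + 1, pid=pid)
            kept1, _ = apply_keep_filter([iso], jset, ann)
            kept2, _ = apply_keep_filter([more], jset, ann)
            if kept1:
                assert kept2
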