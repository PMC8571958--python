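"""Locus clustering (20%-overlap rule) and known/novel classification."""

import itertools

import networkx as nx
import pytest

from isopipe.loci import (
    KNOWN,
    KNOWN_ISOFORM,
    NOVEL,
    NOVEL_ISOFORM_KNOWN_GENE,
    NOVEL_ISOFORM_NOVEL_GENE,
    REASON_3P_SPLICE,
    REASON_NEW_EXON,
    REASON_NEW_INTRON,
    assign_isoform_ids,
    classify_isoforms,
    classify_loci,
    cluster_loci,
)

from conftest import make_isoform, make_transcript


def _spans(*spans, strand="+"):
    return [
        make_isoform(f"i{k}", [span], strand=strand) for k, span in enumerate(spans)
    ]


class TestClusterLoci:
    def test_half_overlap_joins(self):
        loci = cluster_loci(_spans((0, 1000), (500, 1500)))
        assert len(loci) == 1

    def test_ten_percent_overlap_splits(self):
        loci = cluster_loci(_spans((0, 1000), (900, 2000)))
        assert len(loci) == 2

    def test_exactly_twenty_percent_is_not_linked(self):
        # overlap 200 = exactly 20% of the shorter (1000): strict "over 20%"
        loci = cluster_loci(_spans((0, 1000), (800, 2000)))
        assert len(loci) == 2

    def test_opposite_strands_never_linked(self):
        isos = [
            make_isoform("a", [(0, 1000)], strand="+"),
            make_isoform("b", [(0, 1000)], strand="-"),
        ]
        assert len(cluster_loci(isos)) == 2

    def test_partition_property(self, rng):
        isos = [
            make_isoform(
                f"i{k}",
                [(s, s + int(rng.integers(100, 2000)))],
                strand="+" if rng.random() < 0.5 else "-",
            )
            for k, s in enumerate(rng.integers(0, 20_000, size=80))
        ]
        loci = cluster_loci(isos)
        members = [i.model.transcript_id for l in loci for i in l.isoforms]
        assert sorted(members) == sorted(i.model.transcript_id for i in isos)

    def test_matches_brute_force_connected_components(self, rng):
        for _ in range(30):
            isos = [
                make_isoform(
                    f"i{k}",
                    [(s, s + int(rng.integers(100, 3000)))],
                    strand="+" if rng.random() < 0.7 else "-",
                )
                for k, s in enumerate(rng.integers(0, 10_000, size=int(rng.integers(2, 40))))
            ]
            got = {
                frozenset(i.model.transcript_id for i in l.isoforms)
                for l in cluster_loci(isos)
            }
            g = nx.Graph()
            g.add_nodes_from(i.model.transcript_id for i in isos)
            for a, b in itertools.combinations(isos, 2):
                ma, mb = a.model, b.model
                if ma.strand != mb.strand:
                    continue
                inter = min(ma.end, mb.end) - max(ma.start, mb.start)
                shorter = min(ma.end - ma.start, mb.end - mb.start)
                if inter > 0.2 * shorter:
                    g.add_edge(ma.transcript_id, mb.transcript_id)
            expected = {frozenset(c) for c in nx.connected_components(g)}
            assert got == expected

    def test_locus_ids_run_along_chromosome(self):
        loci = cluster_loci(_spans((5000, 6000), (0, 1000)))
        assert [l.locus_id for l in loci] == ["1.1", "1.2"]
        assert loci[0].start == 0


class TestClassifyLoci:
    def test_locus_inside_known_gene_is_known(self, toy_annotation):
        loci = cluster_loci(_spans((120, 580)))
        classify_loci(loci, toy_annotation)
        assert loci[0].status == KNOWN
        assert loci[0].ref_gene_ids == ("GA",)

    def test_antisense_overlap_is_novel(self, toy_annotation):
        loci = cluster_loci(_spans((120, 580), strand="-"))
        classify_loci(loci, toy_annotation)
        assert loci[0].status == NOVEL

    def test_small_overlap_is_novel(self, toy_annotation):
        # locus span 5000, only 100 bp (2%) over gene GA
        loci = cluster_loci(_spans((500, 5500)))
        classify_loci(loci, toy_annotation)
        assert loci[0].status == NOVEL

    def test_known_plus_novel_counts_partition(self, toy_annotation):
        isos = _spans((120, 580), (10_000, 11_000))
        loci = cluster_loci(isos)
        classify_loci(loci, toy_annotation)
        n_known = sum(l.status == KNOWN for l in loci)
        n_novel = sum(l.status == NOVEL for l in loci)
        assert n_known + n_novel == len(loci) == 2


class TestClassifyIsoforms:
    def _classified(self, isoforms, annotation):
        loci = cluster_loci(isoforms)
        classify_loci(loci, annotation)
        assign_isoform_ids(loci)
        return loci, classify_isoforms(loci, annotation)

    def test_exact_chain_match_is_known(self, toy_annotation):
        iso = make_isoform("x", [(90, 200), (300, 400), (500, 610)])
        _, (cls,) = self._classified([iso], toy_annotation)
        assert cls.category == KNOWN_ISOFORM
        assert cls.matched_ref_transcript == "T1"

    def test_terminal_ends_are_not_compared(self, toy_annotation):
        iso = make_isoform("x", [(150, 200), (300, 400), (500, 900)])
        _, (cls,) = self._classified([iso], toy_annotation)
        assert cls.category == KNOWN_ISOFORM

    def test_extra_intron_inside_reference_exon(self, toy_annotation):
        # splits T2's first exon with a new intron
        iso = make_isoform("x", [(100, 140), (160, 200), (500, 600)])
        _, (cls,) = self._classified([iso], toy_annotation)
        assert cls.category == NOVEL_ISOFORM_KNOWN_GENE
        assert cls.novelty_reason == REASON_NEW_INTRON

    def test_new_exon_inside_reference_intron(self, toy_annotation):
        # T2's intron (200,500) gains an internal exon
        iso = make_isoform("x", [(100, 200), (320, 380), (500, 600)])
        _, (cls,) = self._classified([iso], toy_annotation)
        assert cls.category == NOVEL_ISOFORM_KNOWN_GENE
        assert cls.novelty_reason == REASON_NEW_EXON

    def test_changed_final_acceptor(self, toy_annotation):
        # T1 with the last intron's acceptor moved
        iso = make_isoform("x", [(100, 200), (300, 400), (530, 600)])
        _, (cls,) = self._classified([iso], toy_annotation)
        assert cls.category == NOVEL_ISOFORM_KNOWN_GENE
        assert cls.novelty_reason == REASON_3P_SPLICE

    def test_novel_locus_isoforms_are_novel_gene_class(self, toy_annotation):
        iso = make_isoform("x", [(20_000, 20_100), (20_300, 20_400)])
        loci, (cls,) = self._classified([iso], toy_annotation)
        assert loci[0].status == NOVEL
        assert cls.category == NOVEL_ISOFORM_NOVEL_GENE

    def test_assign_ids_use_chrom_locus_isoform_scheme(self, toy_annotation):
        isos = [
            make_isoform("b", [(90, 200), (300, 400), (500, 610)]),
            make_isoform("a", [(95, 200), (500, 615)]),
        ]
        loci = cluster_loci(isos)
        classify_loci(loci, toy_annotation)
        mapping = assign_isoform_ids(loci)
        assert sorted(mapping.values()) == ["1.1.1", "1.1.2"]
        assert all(iso.model.gene_id == "1.1" for iso in loci[0].isoforms)
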