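"""Generator determinism, ground-truth bookkeeping, and sampling checks."""

import numpy as np
import pytest

from isopipe.io_formats import write_annotation, write_flnc
from isopipe.stats import GroupSummary
from isopipe.synthetic import (
    SimulationConfig,
    simulate_expression,
    simulate_flnc,
    simulate_reference,
    simulate_traits,
)


def _clean_config(**kw):
    defaults = dict(
        n_genes=20,
        seed=11,
        degraded_5p_fraction=0.0,
        cleavage_jitter_sd=0.0,
        tss_jitter=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestReference:
    def test_deterministic_under_seed(self, tmp_path):
        files = []
        for run in (1, 2):
            cfg = SimulationConfig(n_genes=10, seed=1)
            ann, truth = simulate_reference(cfg)
            records, _ = simulate_flnc(truth, cfg)
            gff = tmp_path / f"run{run}.gff3"
            bed = tmp_path / f"run{run}.bed"
            write_annotation(ann.transcripts.values(), gff)
            write_flnc(records, bed)
            files.append((gff.read_bytes(), bed.read_bytes()))
        assert files[0] == files[1]

    def test_novel_gene_fraction_withholds_exact_count(self):
        cfg = _clean_config(n_genes=50, novel_gene_fraction=0.2)
        ann, truth = simulate_reference(cfg)
        novel_genes = {g for g, t in truth.genes.items() if t.novel}
        assert len(novel_genes) == 10
        known_in_ann = {t.gene_id for t in ann.transcripts.values()}
        assert known_in_ann.isdisjoint(novel_genes)
        assert len(truth.genes) == 50

    def test_genes_do_not_overlap(self):
        _, truth = simulate_reference(_clean_config(n_genes=40))
        spans = sorted(
            (
                min(t.model.start for t in truth.isoforms.values() if t.gene_id == g),
                max(t.model.end for t in truth.isoforms.values() if t.gene_id == g),
            )
            for g in truth.genes
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_isoform_chains_are_distinct_within_gene(self):
        _, truth = simulate_reference(_clean_config(isoforms_per_gene=(2, 4)))
        by_gene: dict[str, set] = {}
        for t in truth.isoforms.values():
            by_gene.setdefault(t.gene_id, set()).add(t.model.splice_chain)
        for gene, chains in by_gene.items():
            n_iso = sum(t.gene_id == gene for t in truth.isoforms.values())
            assert len(chains) == n_iso


class TestFlnc:
    def test_no_degradation_preserves_splice_chains(self):
        cfg = _clean_config()
        _, truth = simulate_reference(cfg)
        records, _ = simulate_flnc(truth, cfg)
        for r in records:
            source = truth.isoforms[truth.read_to_isoform[r.read_id]]
            assert r.splice_chain == source.model.splice_chain

    def test_constant_support_yields_exact_read_counts(self):
        cfg = _clean_config(flnc_per_isoform=3)
        _, truth = simulate_reference(cfg)
        records, _ = simulate_flnc(truth, cfg)
        counts: dict[str, int] = {}
        for r in records:
            counts[truth.read_to_isoform[r.read_id]] = (
                counts.get(truth.read_to_isoform[r.read_id], 0) + 1
            )
        assert set(counts) == set(truth.isoforms)
        assert all(c == 3 for c in counts.values())

    def test_polya_probability_one_tags_all_reads(self):
        cfg = _clean_config(polya_prob=1.0)
        _, truth = simulate_reference(cfg)
        records, _ = simulate_flnc(truth, cfg)
        assert all(r.polya for r in records)

    def test_degraded_reads_keep_3p_terminus(self):
        cfg = _clean_config(degraded_5p_fraction=1.0, flnc_per_isoform=1)
        _, truth = simulate_reference(cfg)
        records, _ = simulate_flnc(truth, cfg)
        multi = [
            r
            for r in records
            if len(truth.isoforms[truth.read_to_isoform[r.read_id]].model.exons) > 1
        ]
        assert multi
        for r in multi:
            source = truth.isoforms[truth.read_to_isoform[r.read_id]]
            assert len(r.exons) < len(source.model.exons)
            # the kept chain is the 3'-terminal sub-chain of the source
            chain, src = r.splice_chain, source.model.splice_chain
            if r.strand == "+":
                assert src[len(src) - len(chain):] == chain
            else:
                assert src[: len(chain)] == chain

    def test_full_junction_support_covers_every_truth_intron(self):
        cfg = _clean_config(junction_support_prob=1.0)
        _, truth = simulate_reference(cfg)
        _, junctions = simulate_flnc(truth, cfg)
        for t in truth.isoforms.values():
            for d, a in t.model.splice_chain:
                assert junctions.supports(t.model.chrom, t.model.strand, d, a)

    def test_single_isoform_genes_produce_no_as_events(self):
        from isopipe.pipeline import run_pipeline

        cfg = _clean_config(
            isoforms_per_gene=1, flnc_per_isoform=3, junction_support_prob=1.0,
            pid_mean=100.0, pid_sd=0.0,
        )
        ann, truth = simulate_reference(cfg)
        records, junctions = simulate_flnc(truth, cfg)
        result = run_pipeline(records, junctions, ann)
        assert result.as_summary.attrs["total_events"] == 0


class TestTraits:
    def test_table_shape_and_groups(self):
        df = simulate_traits(
            [GroupSummary("DHH", 3, 0.78, 0.21), GroupSummary("DDH", 3, 0.11, 0.03)],
            seed=1,
        )
        assert len(df) == 6
        assert df["group"].value_counts().to_dict() == {"DHH": 3, "DDH": 3}

    def test_zero_sd_gives_constant_values(self):
        df = simulate_traits([GroupSummary("g", 5, 2.5, 0.0)], seed=1)
        assert (df["value"] == 2.5).all()

    def test_large_n_moments_converge(self):
        df = simulate_traits([GroupSummary("g", 10_000, 40.8, 4.57)], seed=2)
        se = 4.57 / np.sqrt(10_000)
        assert abs(df["value"].mean() - 40.8) < 3 * se

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_traits([GroupSummary("g", 3, 1.0, -0.1)], seed=1)


class TestExpression:
    def test_block_correlation_recoverable(self):
        m = simulate_expression(2, 1_000, blocks=[(2, 0.9)], seed=3)
        r = np.corrcoef(np.log(m.to_numpy()))[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_identity_correlation_off_diagonal_small(self):
        m = simulate_expression(4, 2_000, seed=4)
        corr = np.corrcoef(np.log(m.to_numpy()))
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_fixed_seed_identical(self):
        a = simulate_expression(3, 10, blocks=[(2, 0.5)], seed=5)
        b = simulate_expression(3, 10, blocks=[(2, 0.5)], seed=5)
        assert a.equals(b)

    def test_invalid_block_matrix_rejected(self):
        with pytest.raises(ValueError, match="blocks exceed"):
            simulate_expression(2, 10, blocks=[(5, 0.5)], seed=1)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"novel_gene_fraction": 1.5},
            {"degraded_5p_fraction": -0.1},
            {"n_genes": 0},
            {"pid_sd": -1.0},
        ],
    )
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)
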