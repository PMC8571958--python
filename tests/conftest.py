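import numpy as np
import pytest

from isopipe.collapse import CollapsedIsoform
from isopipe.io_formats import FlncRecord, ReferenceAnnotation, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_transcript(tid, exons, strand="+", chrom="1", gene=None):
    return TranscriptModel(tid, chrom, strand, tuple(exons), gene_id=gene)


def make_read(rid, exons, strand="+", chrom="1", pid=100.0, polya=True):
    return FlncRecord(rid, chrom, strand, tuple(exons), pid, polya)


def make_isoform(tid, exons, strand="+", chrom="1", n_flnc=1, pid=100.0):
    model = make_transcript(tid, exons, strand, chrom)
    reads = tuple(f"{tid}.r{i}" for i in range(n_flnc))
    return CollapsedIsoform(model, reads, pid)


@pytest.fixture
def toy_annotation():
    """Two genes, three transcripts: one two-isoform + gene, one - gene."""
    return ReferenceAnnotation(
        [
            make_transcript(
                "T1", [(100, 200), (300, 400), (500, 600)], "+", gene="GA"
            ),
            make_transcript("T2", [(100, 200), (500, 600)], "+", gene="GA"),
            make_transcript("T3", [(5000, 5300), (5600, 5900)], "-", gene="GB"),
        ]
    )


@pytest.fixture
def toy_gff3(tmp_path, toy_annotation):
    from isopipe.io_formats import write_annotation

    path = tmp_path / "toy.gff3"
    write_annotation(toy_annotation.transcripts.values(), path)
    return path
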