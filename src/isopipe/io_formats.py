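"""Genomic data model and file I/O.

All internal coordinates are 0-based, half-open ``[start, end)``.  GFF3/GTF
files (1-based, inclusive) are converted at the read/write boundary; BED12
is already 0-based half-open and passes through unchanged.

The FLNC carrier format is "BED12+2": the twelve standard BED columns plus
alignment percent identity (0-100) and a poly(A)-tail flag (0/1).  It keeps
aligned long reads diff-able and download-free; a BAM ingest path is not
required by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


Exon = tuple[int, int]
Intron = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware exon chain on one chromosome.

    ``exons`` are sorted by start, non-overlapping, and all share
    ``chrom``/``strand``.  The splice chain (ordered intron coordinate
    pairs) is the identity used for collapsing and classification.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript with zero exons")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def splice_chain(self) -> tuple[Intron, ...]:
        """Ordered (donor-side, acceptor-side) intron pairs in genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """Strand-aware transcription start coordinate."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Strand-aware 3'-end (transcript end site) coordinate."""
        return self.end if self.strand == "+" else self.start

    def structure_key(self) -> tuple:
        """Hashable identity of the splice structure (chrom, strand, chain)."""
        return (self.chrom, self.strand, self.splice_chain)


@dataclass(frozen=True)
class FlncRecord:
    """One aligned full-length non-chimeric read."""

    read_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    percent_identity: float
    polya: bool

    def to_transcript_model(self) -> TranscriptModel:
        return TranscriptModel(self.read_id, self.chrom, self.strand, self.exons)

    @property
    def splice_chain(self) -> tuple[Intron, ...]:
        return self.to_transcript_model().splice_chain

    @property
    def tes(self) -> int:
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]


class ReferenceAnnotation:
    """Genes -> transcripts with an interval index for overlap queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.genes: dict[str, dict[str, TranscriptModel]] = {}
        self.transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.gene_id is None:
                raise AnnotationError(f"{t.transcript_id} has no gene_id")
            if t.transcript_id in self.transcripts:
                raise AnnotationError(f"duplicate transcript {t.transcript_id}")
            self.genes.setdefault(t.gene_id, {})[t.transcript_id] = t
            self.transcripts[t.transcript_id] = t
        self._index: dict[str, IntervalTree] = {}
        for t in self.transcripts.values():
            self._index.setdefault(t.chrom, IntervalTree()).addi(
                t.start, t.end, t.transcript_id
            )
        # intron catalogue, for "annotated by the reference" checks
        self._introns: set[tuple[str, str, int, int]] = set()
        for t in self.transcripts.values():
            for d, a in t.splice_chain:
                self._introns.add((t.chrom, t.strand, d, a))

    def __len__(self) -> int:
        return len(self.transcripts)

    def gene_span(self, gene_id: str) -> GenomicInterval:
        ts = list(self.genes[gene_id].values())
        return GenomicInterval(
            ts[0].chrom,
            min(t.start for t in ts),
            max(t.end for t in ts),
            ts[0].strand,
        )

    def overlapping_transcripts(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[TranscriptModel]:
        tree = self._index.get(chrom)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [t for t in hits if t.strand == strand]
        return sorted(hits, key=lambda t: (t.start, t.transcript_id))

    def overlapping_genes(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.overlapping_transcripts(chrom, start, end, strand):
            seen.setdefault(t.gene_id)  # type: ignore[arg-type]
        return list(seen)

    def has_intron(self, chrom: str, strand: str, donor: int, acceptor: int) -> bool:
        return (chrom, strand, donor, acceptor) in self._introns

    def chain_index(self) -> Mapping[tuple, list[TranscriptModel]]:
        idx: dict[tuple, list[TranscriptModel]] = {}
        for t in self.transcripts.values():
            idx.setdefault(t.structure_key(), []).append(t)
        return idx


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------


def _validate_gff_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise AnnotationError(
                    f"{path}: line {lineno}: start {start} > end {end}"
                )
            if fields[6] not in ("+", "-", ".", "?"):
                raise AnnotationError(
                    f"{path}: line {lineno}: bad strand {fields[6]!r}"
                )


def read_annotation(path: str | Path) -> ReferenceAnnotation:
    """Read a GFF3 or GTF annotation into the internal model.

    The dialect is auto-detected from column-9 syntax (gffutils).  File
    coordinates (1-based inclusive) are converted to 0-based half-open.
    A transcript without exon children is an error.
    """
    path = Path(path)
    _validate_gff_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    gtf = db.dialect.get("fmt") == "gtf"

    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str | None]] = {}  # tx -> chrom, strand, gene
    tx_parent: dict[str, str] = {}

    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype == "exon":
            if gtf:
                tx_ids = feat.attributes.get("transcript_id", [])
                gene = (feat.attributes.get("gene_id") or [None])[0]
            else:
                tx_ids = feat.attributes.get("Parent", [])
                gene = None
            if not tx_ids:
                raise AnnotationError(
                    f"{path}: exon without transcript parent at "
                    f"{feat.seqid}:{feat.start}-{feat.end}"
                )
            for tx in tx_ids:
                exons_by_tx.setdefault(tx, []).append((feat.start - 1, feat.end))
                meta.setdefault(tx, (feat.seqid, feat.strand, gene))
        elif ftype in ("transcript", "mrna"):
            tx = feat.id
            if gtf:
                tx = (feat.attributes.get("transcript_id") or [feat.id])[0]
                gene = (feat.attributes.get("gene_id") or [None])[0]
            else:
                gene = (feat.attributes.get("Parent") or [None])[0]
            if gene is not None:
                tx_parent[tx] = gene

    # transcript features with no exon children
    for tx in tx_parent:
        if tx not in exons_by_tx:
            raise AnnotationError(f"{path}: transcript {tx} has zero exons")
    if not exons_by_tx:
        raise AnnotationError(f"{path}: no exon features found")

    models = []
    for tx, exons in exons_by_tx.items():
        chrom, strand, gene = meta[tx]
        gene = tx_parent.get(tx, gene)
        if gene is None:
            raise AnnotationError(f"{path}: transcript {tx} has no gene parent")
        models.append(
            TranscriptModel(
                tx, chrom, strand, tuple(sorted(exons)), gene_id=gene
            )
        )
    return ReferenceAnnotation(models)


def write_annotation(
    models: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "isopipe",
    novel_gene_prefix: str = "NOVELG",
) -> None:
    """Write transcript models as a gene/transcript/exon GFF3 hierarchy.

    Models must carry a gene (locus) id; a missing id is an error.  The
    ``novel_gene_prefix`` is only cosmetic metadata for callers that
    pre-assigned novel ids and is not enforced here.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        if m.gene_id is None:
            raise AnnotationError(
                f"cannot write {m.transcript_id}: no locus/gene id assigned"
            )
        by_gene.setdefault(m.gene_id, []).append(m)

    def gene_sort_key(item: tuple[str, list[TranscriptModel]]):
        ts = item[1]
        return (ts[0].chrom, min(t.start for t in ts), item[0])

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, ts in sorted(by_gene.items(), key=gene_sort_key):
            chrom, strand = ts[0].chrom, ts[0].strand
            gs = min(t.start for t in ts)
            ge = max(t.end for t in ts)
            fh.write(
                f"{chrom}\t{source}\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for t in sorted(ts, key=lambda t: (t.start, t.transcript_id)):
                fh.write(
                    f"{chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{strand}\t.\tID={t.transcript_id};Parent={gene_id}\n"
                )
                for i, (s, e) in enumerate(t.exons, start=1):
                    fh.write(
                        f"{chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# FLNC BED12+2
# ---------------------------------------------------------------------------

_BED12P2_NCOL = 14


def read_flnc(path: str | Path) -> list[FlncRecord]:
    """Read aligned FLNC reads from a BED12+2 file (order preserved)."""
    records: list[FlncRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != _BED12P2_NCOL:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_BED12P2_NCOL} columns, "
                    f"got {len(f)}"
                )
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(
                    f"{path}: line {lineno}: blockCount={block_count} does not "
                    f"match blockSizes/blockStarts"
                )
            exons = tuple(
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            records.append(
                FlncRecord(
                    read_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    percent_identity=float(f[12]),
                    polya=bool(int(f[13])),
                )
            )
    return records


def write_flnc(records: Iterable[FlncRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            start = r.exons[0][0]
            end = r.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in r.exons)
            starts = ",".join(str(s - start) for s, _ in r.exons)
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(start),
                        str(end),
                        r.read_id,
                        "0",
                        r.strand,
                        str(start),
                        str(end),
                        "0,0,0",
                        str(len(r.exons)),
                        sizes,
                        starts,
                        f"{r.percent_identity:g}",
                        str(int(r.polya)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Short-read junction support
# ---------------------------------------------------------------------------


class JunctionSupportSet:
    """Short-read-supported splice junctions keyed by (chrom, strand, start, end).

    A junction stored with strand "." (unstranded short-read data) matches a
    query on either strand.
    """

    def __init__(self, counts: Mapping[tuple[str, str, int, int], int] | None = None):
        self._counts: dict[tuple[str, str, int, int], int] = dict(counts or {})

    def __len__(self) -> int:
        return len(self._counts)

    def __iter__(self) -> Iterator[tuple[str, str, int, int]]:
        return iter(self._counts)

    def add(self, chrom: str, strand: str, start: int, end: int, count: int) -> None:
        if count < 1:
            raise ValueError("junction read_count must be >= 1")
        key = (chrom, strand, start, end)
        self._counts[key] = self._counts.get(key, 0) + count

    def count(self, chrom: str, strand: str, start: int, end: int) -> int:
        n = self._counts.get((chrom, strand, start, end), 0)
        if strand in STRANDS:
            n += self._counts.get((chrom, ".", start, end), 0)
        return n

    def supports(self, chrom: str, strand: str, start: int, end: int) -> bool:
        return self.count(chrom, strand, start, end) > 0


def read_junctions(path: str | Path) -> JunctionSupportSet:
    """Read a junction support TSV (chrom, strand, intron_start, intron_end,
    read_count).  Duplicate rows are summed with a warning."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "strand", "intron_start", "intron_end", "read_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["read_count"] < 1).any():
        raise ValueError(f"{path}: read_count must be >= 1")
    keys = list(zip(df["chrom"], df["strand"], df["intron_start"], df["intron_end"]))
    if len(set(keys)) < len(keys):
        warnings.warn(f"{path}: duplicate junction rows summed", stacklevel=2)
    jset = JunctionSupportSet()
    for (chrom, strand, s, e), cnt in zip(keys, df["read_count"]):
        jset.add(str(chrom), str(strand), int(s), int(e), int(cnt))
    return jset


def write_junctions(jset: JunctionSupportSet, path: str | Path) -> None:
    rows = [
        {"chrom": c, "strand": st, "intron_start": s, "intron_end": e,
         "read_count": jset.count(c, st, s, e) if st not in STRANDS
         else jset._counts[(c, st, s, e)]}
        for (c, st, s, e) in sorted(jset)
    ]
    pd.DataFrame(
        rows, columns=["chrom", "strand", "intron_start", "intron_end", "read_count"]
    ).to_csv(path, sep="\t", index=False)
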