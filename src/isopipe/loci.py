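"""Gene-locus clustering and known/novel classification.

Isoforms overlapping more than 20% of their length on the same strand are
assigned to the same gene locus (single-linkage).  A locus is novel when no
same-strand reference gene covers at least 20% of the locus span; an
isoform at a known locus is a known isoform only when its splice chain
exactly matches a reference transcript of a linked gene.

"Length" is the genomic span by default, with the shorter element as the
denominator; an exonic-length mode is selectable (``mode="exonic"``).
Novel loci and isoforms are named ``chrom.locus.isoform`` (locus numbers
run 5'→3' along each chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .collapse import CollapsedIsoform
from .io_formats import ReferenceAnnotation, TranscriptModel

OverlapMode = Literal["span", "exonic"]

KNOWN = "known"
NOVEL = "novel"

KNOWN_ISOFORM = "known_isoform"
NOVEL_ISOFORM_KNOWN_GENE = "novel_isoform_known_gene"
NOVEL_ISOFORM_NOVEL_GENE = "novel_isoform_novel_gene"

REASON_3P_SPLICE = "changed_3p_terminal_splice_site"
REASON_NEW_INTRON = "new_intron"
REASON_NEW_EXON = "new_exon"
REASON_OTHER = "other_chain_difference"


@dataclass
class GeneLocus:
    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    isoforms: list[CollapsedIsoform]
    status: str | None = None
    ref_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for iso in self.isoforms:
            if iso.model.chrom != self.chrom or iso.model.strand != self.strand:
                raise ValueError(f"{self.locus_id}: member on wrong chrom/strand")

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IsoformClass:
    isoform_id: str
    locus_id: str
    category: str
    matched_ref_transcript: str | None = None
    novelty_reason: str | None = None


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _pair_linked(
    a: TranscriptModel, b: TranscriptModel, min_frac: float, mode: OverlapMode
) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if mode == "span":
        inter = max(0, min(a.end, b.end) - max(a.start, b.start))
        denom = min(a.end - a.start, b.end - b.start)
    else:
        inter = _exonic_overlap(a, b)
        denom = min(a.exonic_length, b.exonic_length)
    return inter > min_frac * denom  # strict: "over 20%"


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_loci(
    isoforms: list[CollapsedIsoform],
    min_frac: float = 0.2,
    mode: OverlapMode = "span",
) -> list[GeneLocus]:
    """Single-linkage clustering of isoforms into gene loci.

    Two isoforms are linked iff they share chrom and strand and their
    overlap exceeds ``min_frac`` of the shorter one (strict inequality).
    Locus ids are ``{chrom}.{k}`` with k counting loci along the
    chromosome in genomic order.
    """
    uf = _UnionFind(len(isoforms))
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, iso in enumerate(isoforms):
        by_key.setdefault((iso.model.chrom, iso.model.strand), []).append(i)
    for idxs in by_key.values():
        idxs = sorted(idxs, key=lambda i: isoforms[i].model.start)
        for pos, i in enumerate(idxs):
            mi = isoforms[i].model
            for j in idxs[pos + 1:]:
                mj = isoforms[j].model
                if mj.start >= mi.end:
                    break  # sorted by start; no span overlap possible
                if _pair_linked(mi, mj, min_frac, mode):
                    uf.union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(len(isoforms)):
        comps.setdefault(uf.find(i), []).append(i)

    raw = []
    for members in comps.values():
        isos = sorted(
            (isoforms[i] for i in members),
            key=lambda c: (c.model.start, c.model.end, c.model.transcript_id),
        )
        raw.append(
            GeneLocus(
                locus_id="",
                chrom=isos[0].model.chrom,
                strand=isos[0].model.strand,
                start=min(c.model.start for c in isos),
                end=max(c.model.end for c in isos),
                isoforms=isos,
            )
        )
    raw.sort(key=lambda l: (l.chrom, l.start, l.end, l.strand))
    counter: dict[str, int] = {}
    for locus in raw:
        counter[locus.chrom] = counter.get(locus.chrom, 0) + 1
        locus.locus_id = f"{locus.chrom}.{counter[locus.chrom]}"
    return raw


def classify_loci(
    loci: list[GeneLocus],
    annotation: ReferenceAnnotation,
    min_frac: float = 0.2,
    same_strand: bool = True,
) -> list[GeneLocus]:
    """Set known/novel status in place and return the loci.

    A locus is known iff some (same-strand) reference gene's span covers
    at least ``min_frac`` of the locus span; all qualifying genes are
    linked.  An antisense-only overlap leaves the locus novel.
    """
    for locus in loci:
        strand = locus.strand if same_strand else None
        linked = []
        for gene_id in annotation.overlapping_genes(
            locus.chrom, locus.start, locus.end, strand
        ):
            g = annotation.gene_span(gene_id)
            inter = max(0, min(locus.end, g.end) - max(locus.start, g.start))
            if inter >= min_frac * locus.span_length:
                linked.append(gene_id)
        locus.ref_gene_ids = tuple(sorted(linked))
        locus.status = KNOWN if linked else NOVEL
    return loci


def _novelty_reason(iso: TranscriptModel, refs: list[TranscriptModel]) -> str:
    """Describe how a novel isoform's chain departs from its gene's models."""
    chain = set(iso.splice_chain)
    if not refs:
        return REASON_OTHER
    best = max(
        refs, key=lambda r: (len(chain & set(r.splice_chain)), -len(r.splice_chain))
    )
    ref_chain = list(best.splice_chain)
    iso_chain = list(iso.splice_chain)

    # changed 3'-terminal splice site: chains identical except the final
    # intron in transcript orientation
    if len(iso_chain) == len(ref_chain) and iso_chain:
        idx = -1 if iso.strand == "+" else 0
        rest_iso = iso_chain[:idx] if idx == -1 else iso_chain[1:]
        rest_ref = ref_chain[:idx] if idx == -1 else ref_chain[1:]
        if rest_iso == rest_ref and iso_chain[idx] != ref_chain[idx]:
            return REASON_3P_SPLICE

    extra = [i for i in iso_chain if i not in ref_chain]
    if extra and all(i in iso_chain for i in ref_chain):
        # purely additional introns: new intron if inside a reference exon,
        # new exon if an isoform exon sits inside a reference intron
        if any(
            any(s <= d and a <= e for s, e in best.exons) for d, a in extra
        ):
            return REASON_NEW_INTRON
    if any(
        any(d <= s and e <= a for d, a in best.splice_chain)
        for s, e in iso.exons
    ):
        return REASON_NEW_EXON
    return REASON_OTHER


def classify_isoforms(
    loci: list[GeneLocus], annotation: ReferenceAnnotation
) -> list[IsoformClass]:
    """Classify each isoform as known / novel-at-known-gene / novel-gene.

    A known isoform requires exact splice-chain equality with a reference
    transcript of a linked gene; terminal exon end positions are not
    compared (they vary with degradation and library prep).
    """
    out: list[IsoformClass] = []
    for locus in loci:
        if locus.status is None:
            raise ValueError(f"{locus.locus_id}: classify_loci not run")
        ref_models = [
            t
            for g in locus.ref_gene_ids
            for t in annotation.genes[g].values()
        ]
        chains = {}
        for t in ref_models:
            chains.setdefault(t.structure_key(), t)
        for iso in locus.isoforms:
            iid = iso.model.transcript_id
            if locus.status == NOVEL:
                out.append(
                    IsoformClass(iid, locus.locus_id, NOVEL_ISOFORM_NOVEL_GENE)
                )
                continue
            match = chains.get(iso.model.structure_key())
            if match is not None:
                out.append(
                    IsoformClass(
                        iid, locus.locus_id, KNOWN_ISOFORM, match.transcript_id
                    )
                )
            else:
                out.append(
                    IsoformClass(
                        iid,
                        locus.locus_id,
                        NOVEL_ISOFORM_KNOWN_GENE,
                        novelty_reason=_novelty_reason(iso.model, ref_models),
                    )
                )
    return out


def assign_isoform_ids(loci: list[GeneLocus]) -> dict[str, str]:
    """Assign ``chrom.locus.isoform`` ids; returns old-id -> new-id map.

    Isoform numbers run 5'→3' in genomic order within each locus.  Models
    are renamed in place (gene_id set to the locus id).
    """
    from dataclasses import replace

    mapping: dict[str, str] = {}
    for locus in loci:
        for j, iso in enumerate(locus.isoforms, start=1):
            new_id = f"{locus.locus_id}.{j}"
            mapping[iso.model.transcript_id] = new_id
            iso.model = replace(
                iso.model, transcript_id=new_id, gene_id=locus.locus_id
            )
    return mapping
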