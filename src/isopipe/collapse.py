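"""Collapse aligned FLNC reads into isoforms and apply the keep filter.

The collapsing unit is the splice chain: multi-exon reads sharing the same
ordered intron list on the same chromosome and strand are merged into one
isoform whose terminal exons extend to the furthest observed 5'/3' ends.
Mono-exon reads, which have no splice chain, are grouped by single-linkage
genomic overlap on the same strand (any overlap >= 1 bp).

Two post-collapse filters mirror standard long-read practice:

* 5'-degradation: an isoform whose chain is a strict 3'-terminal sub-chain
  of a longer isoform at the same position, ending at (nearly) the same 3'
  terminus, is a 5'-degraded library artifact and is excluded.
* the four-condition keep filter: an isoform is kept if it has >= 2
  supporting FLNCs, OR a single FLNC with alignment identity above the PID
  threshold, OR every splice site short-read supported, OR every splice
  junction present in the reference annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io_formats import (
    FlncRecord,
    Intron,
    JunctionSupportSet,
    ReferenceAnnotation,
    TranscriptModel,
)


def splice_chain(model: TranscriptModel) -> tuple[Intron, ...]:
    """Ordered (donor-side, acceptor-side) introns; empty for mono-exon."""
    return model.splice_chain


@dataclass
class CollapsedIsoform:
    """An isoform merged from one or more FLNC reads."""

    model: TranscriptModel
    supporting_flnc_ids: tuple[str, ...]
    max_pid: float
    degraded_5p: bool = False

    def __post_init__(self) -> None:
        if not self.supporting_flnc_ids:
            raise ValueError("collapsed isoform with no supporting reads")
        if not 0.0 <= self.max_pid <= 100.0:
            raise ValueError(f"max_pid {self.max_pid} outside [0, 100]")

    @property
    def n_flnc(self) -> int:
        return len(self.supporting_flnc_ids)

    @property
    def chain(self) -> tuple[Intron, ...]:
        return self.model.splice_chain


def _merge_group(records: list[FlncRecord], iso_id: str) -> CollapsedIsoform:
    chrom = records[0].chrom
    strand = records[0].strand
    chain = records[0].splice_chain
    start = min(r.exons[0][0] for r in records)
    end = max(r.exons[-1][1] for r in records)
    if chain:
        exons = (
            (start, chain[0][0]),
            *((chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)),
            (chain[-1][1], end),
        )
    else:
        exons = ((start, end),)
    model = TranscriptModel(iso_id, chrom, strand, exons)
    ids = tuple(sorted(r.read_id for r in records))
    return CollapsedIsoform(model, ids, max(r.percent_identity for r in records))


def collapse_flnc(
    records: list[FlncRecord], id_prefix: str = "ISO"
) -> list[CollapsedIsoform]:
    """Collapse FLNC alignments into isoforms.

    Order-invariant: groups are keyed by splice structure (multi-exon) or
    by single-linkage overlap components (mono-exon), and the output is
    sorted genomically.
    """
    multi: dict[tuple, list[FlncRecord]] = {}
    mono: dict[tuple[str, str], list[FlncRecord]] = {}
    for r in records:
        if len(r.exons) > 1:
            multi.setdefault((r.chrom, r.strand, r.splice_chain), []).append(r)
        else:
            mono.setdefault((r.chrom, r.strand), []).append(r)

    groups: list[list[FlncRecord]] = list(multi.values())
    # mono-exon: sweep merge = single-linkage connected components on >=1 bp
    # overlap (intervals sorted by start; a gap breaks the component)
    for key in sorted(mono):
        reads = sorted(mono[key], key=lambda r: (r.exons[0][0], r.read_id))
        current: list[FlncRecord] = []
        reach = -1
        for r in reads:
            if current and r.exons[0][0] < reach:
                current.append(r)
                reach = max(reach, r.exons[0][1])
            else:
                if current:
                    groups.append(current)
                current = [r]
                reach = r.exons[0][1]
        if current:
            groups.append(current)

    merged = [_merge_group(g, "tmp") for g in groups]
    merged.sort(key=lambda c: (c.model.chrom, c.model.start, c.model.end,
                               c.model.strand, c.chain))
    out = []
    for i, c in enumerate(merged, start=1):
        out.append(replace(c, model=replace(c.model, transcript_id=f"{id_prefix}.{i}")))
    return out


def _is_strict_3p_suffix(
    short: tuple[Intron, ...], long: tuple[Intron, ...], strand: str
) -> bool:
    """Is ``short`` a strict 3'-terminal sub-chain of ``long``?

    Chains are in genomic order; the 3'-terminal end is the tail on the +
    strand and the head on the - strand.  The empty chain counts as a
    strict suffix of any non-empty chain (a mono-exon degradation
    fragment).
    """
    if len(short) >= len(long):
        return False
    if strand == "+":
        return long[len(long) - len(short):] == short
    return long[: len(short)] == short


def flag_5prime_degraded(
    isoforms: list[CollapsedIsoform],
    tes_tolerance: int = 50,
    recredit_support: bool = False,
) -> tuple[list[CollapsedIsoform], list[CollapsedIsoform]]:
    """Split isoforms into (kept, degraded).

    An isoform A is 5'-degraded iff some isoform B on the same chrom and
    strand has A's chain as a strict 3'-terminal sub-chain and A's 3'
    terminus within ``tes_tolerance`` nt of B's.  With
    ``recredit_support`` the degraded isoform's reads are credited to the
    closest such parent (fewest extra introns, then nearest 3' end).
    """
    by_pos: dict[tuple[str, str], list[CollapsedIsoform]] = {}
    for iso in isoforms:
        by_pos.setdefault((iso.model.chrom, iso.model.strand), []).append(iso)

    kept: list[CollapsedIsoform] = []
    degraded: list[CollapsedIsoform] = []
    credit: dict[int, list[str]] = {}  # index in `isoforms` of parent -> read ids
    index_of = {id(iso): i for i, iso in enumerate(isoforms)}

    for (chrom, strand), group in by_pos.items():
        for a in group:
            parents = [
                b
                for b in group
                if b is not a
                and _is_strict_3p_suffix(a.chain, b.chain, strand)
                and abs(a.model.tes - b.model.tes) <= tes_tolerance
            ]
            if parents:
                degraded.append(replace(a, degraded_5p=True))
                if recredit_support:
                    best = min(
                        parents,
                        key=lambda b: (
                            len(b.chain) - len(a.chain),
                            abs(a.model.tes - b.model.tes),
                            b.model.transcript_id,
                        ),
                    )
                    credit.setdefault(index_of[id(best)], []).extend(
                        a.supporting_flnc_ids
                    )
            else:
                kept.append(a)

    if recredit_support and credit:
        kept_out = []
        for iso in kept:
            extra = credit.get(index_of[id(iso)])
            if extra:
                iso = replace(
                    iso,
                    supporting_flnc_ids=tuple(
                        sorted(set(iso.supporting_flnc_ids) | set(extra))
                    ),
                )
            kept_out.append(iso)
        kept = kept_out
    return kept, degraded


# keep-filter reason codes, in priority order
REASON_MULTI_FLNC = "multi_flnc_support"
REASON_HIGH_PID = "single_flnc_high_pid"
REASON_JUNCTIONS = "short_read_junction_support"
REASON_ANNOTATED = "annotated_junctions"
REASON_DROPPED = "dropped"
VACUOUS_SUFFIX = "_vacuous"


@dataclass(frozen=True)
class FilterDecision:
    isoform_id: str
    kept: bool
    reason: str
    n_flnc: int
    max_pid: float


def apply_keep_filter(
    isoforms: list[CollapsedIsoform],
    junctions: JunctionSupportSet,
    annotation: ReferenceAnnotation,
    pid_threshold: float = 99.0,
    min_flnc: int = 2,
) -> tuple[list[CollapsedIsoform], list[FilterDecision]]:
    """Keep isoforms meeting any of the four support conditions.

    1. supported by >= ``min_flnc`` FLNCs;
    2. a single FLNC with PID strictly above ``pid_threshold``;
    3. every intron short-read supported;
    4. every intron present in the reference annotation.

    The reason code records the first satisfied condition.  A mono-exon
    isoform has no introns, so (3) and (4) hold vacuously; its reason code
    carries a ``_vacuous`` suffix so such keeps can be audited.
    """
    kept: list[CollapsedIsoform] = []
    decisions: list[FilterDecision] = []
    for iso in isoforms:
        m = iso.model
        chain = iso.chain
        vac = VACUOUS_SUFFIX if not chain else ""
        reason = None
        if iso.n_flnc >= min_flnc:
            reason = REASON_MULTI_FLNC
        elif iso.n_flnc == 1 and iso.max_pid > pid_threshold:
            reason = REASON_HIGH_PID
        elif all(junctions.supports(m.chrom, m.strand, d, a) for d, a in chain):
            reason = REASON_JUNCTIONS + vac
        elif all(annotation.has_intron(m.chrom, m.strand, d, a) for d, a in chain):
            reason = REASON_ANNOTATED + vac
        if reason is not None:
            kept.append(iso)
        decisions.append(
            FilterDecision(
                m.transcript_id,
                reason is not None,
                reason or REASON_DROPPED,
                iso.n_flnc,
                iso.max_pid,
            )
        )
    return kept, decisions
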