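"""Alternative-splicing event enumeration and typing.

For every pair of multi-exon isoforms at a locus, the two splice chains
are aligned on their shared splice-site coordinates.  Each maximal run of
sites private to one chain, flanked by shared sites (or the transcript
bounds), is one candidate event; events are de-duplicated across pairs by
a canonical signature, so the catalogue is a set of distinct local
splicing differences per locus, not a per-pair tally.

Typing is purely structural, from the signature:

* exon skipping     — two introns + an internal exon on one side vs one
                      intron with the same outer donor/acceptor;
* intron retention  — an intron on one side entirely contained in an exon
                      of the other, flanks shared;
* alt donor/acceptor — two introns sharing one boundary; which boundary is
                      the donor (5' splice site) depends on the strand;
* other             — anything else (complex, mutually exclusive or
                      terminal-exon differences).
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .io_formats import Intron, TranscriptModel
from .loci import GeneLocus

EXON_SKIPPING = "exon_skipping"
INTRON_RETENTION = "intron_retention"
ALT_DONOR = "alt_donor"
ALT_ACCEPTOR = "alt_acceptor"
OTHER = "other"

EVENT_TYPES = (EXON_SKIPPING, ALT_ACCEPTOR, INTRON_RETENTION, ALT_DONOR, OTHER)


@dataclass(frozen=True)
class ASEvent:
    event_type: str
    locus_id: str
    region: tuple[int, int]
    signature: tuple
    witnesses: tuple[str, str]


def _covered_by_exon(introns: tuple[Intron, ...], model: TranscriptModel) -> bool:
    return all(
        any(s <= d and a <= e for s, e in model.exons) for d, a in introns
    )


def _classify(
    side_a: tuple[Intron, ...],
    side_b: tuple[Intron, ...],
    model_a: TranscriptModel,
    model_b: TranscriptModel,
    strand: str,
) -> str:
    # orient: x has fewer or equal introns
    if len(side_a) <= len(side_b):
        x, y, mx = side_a, side_b, model_a
    else:
        x, y, mx = side_b, side_a, model_b
    if len(x) == 0 and len(y) == 1:
        return INTRON_RETENTION if _covered_by_exon(y, mx) else OTHER
    if len(x) == 1 and len(y) == 1:
        (d1, a1), (d2, a2) = x[0], y[0]
        if d1 == d2 and a1 != a2:
            return ALT_ACCEPTOR if strand == "+" else ALT_DONOR
        if a1 == a2 and d1 != d2:
            return ALT_DONOR if strand == "+" else ALT_ACCEPTOR
        return OTHER
    if len(x) == 1 and len(y) == 2:
        (d, a) = x[0]
        (d1, a1), (d2, a2) = y
        if d == d1 and a == a2 and a1 < d2:
            return EXON_SKIPPING
        return OTHER
    return OTHER


def _pair_events(
    t1: TranscriptModel, t2: TranscriptModel
) -> list[tuple[tuple[int, int], tuple, str]]:
    """Candidate events for one transcript pair.

    Returns (region, signature, event_type) triples; the signature is the
    canonicalised pair of private intron tuples, which identifies the
    event independently of pair order.
    """
    chain1, chain2 = t1.splice_chain, t2.splice_chain
    sites1 = {c for intron in chain1 for c in intron}
    sites2 = {c for intron in chain2 for c in intron}
    shared = sites1 & sites2
    private = sorted((sites1 | sites2) - shared)
    if not private:
        return []

    # maximal runs of private sites = groups between consecutive shared sites
    shared_sorted = sorted(shared)
    grouped: dict[tuple[int | None, int | None], list[int]] = {}
    for p in private:
        i = bisect.bisect_left(shared_sorted, p)
        left = shared_sorted[i - 1] if i > 0 else None
        right = shared_sorted[i] if i < len(shared_sorted) else None
        grouped.setdefault((left, right), []).append(p)

    events = []
    for (left, right), sites in grouped.items():
        lo = left if left is not None else min(sites) - 1
        hi = right if right is not None else max(sites) + 1
        in_region = lambda d, a: max(d, lo) < min(a, hi)  # open-interval overlap
        side1 = tuple(i for i in chain1 if in_region(*i))
        side2 = tuple(i for i in chain2 if in_region(*i))
        if side1 == side2:
            continue
        signature = tuple(sorted((side1, side2)))
        etype = _classify(side1, side2, t1, t2, t1.strand)
        events.append(((lo, hi), signature, etype))
    return events


def enumerate_events(locus: GeneLocus) -> list[ASEvent]:
    """Distinct AS events among the isoforms of one locus.

    Mono-exon isoforms participate: full retention of a transcript's only
    intron yields a mono-exon partner, which must still be seen as
    intron retention.  A pair with identical chains contributes nothing.
    """
    models = [iso.model for iso in locus.isoforms]
    seen: dict[tuple, ASEvent] = {}
    for t1, t2 in combinations(models, 2):
        for region, signature, etype in _pair_events(t1, t2):
            if signature not in seen:
                seen[signature] = ASEvent(
                    etype,
                    locus.locus_id,
                    region,
                    signature,
                    (t1.transcript_id, t2.transcript_id),
                )
    return sorted(seen.values(), key=lambda e: (e.region, e.signature))


def enumerate_all_events(loci: list[GeneLocus]) -> list[ASEvent]:
    out: list[ASEvent] = []
    for locus in loci:
        out.extend(enumerate_events(locus))
    return out


def summarize_events(events: list[ASEvent]) -> pd.DataFrame:
    """Counts and percentages per event type (fractions to two decimals).

    An empty catalogue yields zero counts and 0.00 fractions with the
    ``undefined_fractions`` attribute set on the frame.
    """
    counts = Counter(e.event_type for e in events)
    total = sum(counts.values())
    rows = []
    for etype in EVENT_TYPES:
        n = counts.get(etype, 0)
        pct = round(100.0 * n / total, 2) if total else 0.0
        rows.append({"event_type": etype, "count": n, "percent": pct})
    df = pd.DataFrame(rows)
    df.attrs["total_events"] = total
    df.attrs["undefined_fractions"] = total == 0
    return df
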