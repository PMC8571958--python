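"""lncRNA candidate filtering and ensemble coding-potential voting.

Novel isoforms longer than 200 nt (strict) with no hit in any protein
database enter the candidate set; the final lncRNA call requires a
unanimous "noncoding" verdict from every registered coding-potential
predictor (set intersection, mirroring a multi-tool Venn).

Predictors follow a minimal contract — a name plus a callable
``(transcript_id, sequence) -> "coding" | "noncoding"`` — so verdicts
produced by external tools can be plugged in from tables.  The built-in
ORF heuristic keeps the pipeline self-contained: a transcript is called
noncoding when its longest forward-frame ORF is under 100 codons AND
covers under 35% of the transcript.  Those thresholds are conventional
lncRNA-screen defaults, configurable per instance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

CODING = "coding"
NONCODING = "noncoding"

_STOPS = {"TAA", "TAG", "TGA"}
_VALID = set("ACGTN")


@dataclass(frozen=True)
class LncRNACandidate:
    isoform_id: str
    length: int
    db_hits: tuple[str, ...]  # databases with a protein hit (empty for candidates)


def prefilter_candidates(
    isoform_lengths: Mapping[str, int],
    annotation_hits: Mapping[str, Mapping[str, bool]],
    min_length: int = 200,
) -> list[LncRNACandidate]:
    """Length and protein-annotation prefilter.

    Keeps isoforms with transcript length strictly greater than
    ``min_length`` nt and no hit in any protein database.  An isoform
    absent from the hit table is treated as no-hit, with a warning.
    """
    missing = [i for i in isoform_lengths if i not in annotation_hits]
    if missing:
        warnings.warn(
            f"{len(missing)} isoform(s) absent from the annotation hit table; "
            "treated as no-hit",
            stacklevel=2,
        )
    out = []
    for iso_id, length in isoform_lengths.items():
        if length <= min_length:
            continue
        hits = tuple(
            sorted(db for db, hit in annotation_hits.get(iso_id, {}).items() if hit)
        )
        if hits:
            continue
        out.append(LncRNACandidate(iso_id, length, hits))
    return out


def longest_orf(sequence: str) -> tuple[int, float]:
    """(codons, coverage) of the longest forward-strand ORF.

    Scans the three forward frames for ATG..stop; an ATG with no in-frame
    stop extends to the last complete codon.  Codon count excludes the
    stop; coverage is codons*3 / transcript length.  Non-ACGTN characters
    are an error.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    n = len(seq)
    best = 0
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i : i + 3] == "ATG":
                codons = 0
                j = i
                while j + 3 <= n and seq[j : j + 3] not in _STOPS:
                    codons += 1
                    j += 3
                best = max(best, codons)
                i = j + 3  # restart after the stop (or end)
            else:
                i += 3
    coverage = best * 3 / n if n else 0.0
    return best, coverage


class OrfHeuristicPredictor:
    """Built-in length/coverage ORF rule (see module docstring)."""

    def __init__(
        self,
        name: str = "orf_heuristic",
        max_codons: int = 100,
        max_coverage: float = 0.35,
    ):
        self.name = name
        self.max_codons = max_codons
        self.max_coverage = max_coverage

    def __call__(self, transcript_id: str, sequence: str) -> str:
        codons, coverage = longest_orf(sequence)
        if codons < self.max_codons and coverage < self.max_coverage:
            return NONCODING
        return CODING


class TablePredictor:
    """Verdicts imported from an external tool's per-transcript table."""

    def __init__(self, name: str, verdicts: Mapping[str, str]):
        self.name = name
        bad = {v for v in verdicts.values()} - {CODING, NONCODING}
        if bad:
            raise ValueError(f"unknown verdicts {sorted(bad)}")
        self._verdicts = dict(verdicts)

    def __call__(self, transcript_id: str, sequence: str) -> str:
        return self._verdicts[transcript_id]


Predictor = Callable[[str, str], str]


def ensemble_vote(
    candidates: Iterable[LncRNACandidate],
    sequences: Mapping[str, str],
    predictors: list,
) -> tuple[set[str], dict[str, set[str]], set[str]]:
    """Unanimous-noncoding intersection over all predictors.

    Returns (final lncRNA ids, per-tool noncoding sets, failed candidate
    ids).  A predictor raising on a candidate excludes that candidate
    from the final set (logged via warning) but leaves the other tools'
    memberships intact.
    """
    if not predictors:
        raise ValueError("at least one predictor is required")
    per_tool: dict[str, set[str]] = {p.name: set() for p in predictors}
    failed: set[str] = set()
    for cand in candidates:
        seq = sequences.get(cand.isoform_id, "")
        for p in predictors:
            try:
                verdict = p(cand.isoform_id, seq)
            except Exception as exc:  # noqa: BLE001 - predictor contract
                failed.add(cand.isoform_id)
                warnings.warn(
                    f"predictor {p.name} failed on {cand.isoform_id}: {exc}",
                    stacklevel=2,
                )
                continue
            if verdict == NONCODING:
                per_tool[p.name].add(cand.isoform_id)
    final = set.intersection(*per_tool.values()) - failed if per_tool else set()
    return final, per_tool, failed


def length_stats(lengths: Iterable[int]) -> dict[str, float]:
    """min / max / mean transcript length of a non-empty lncRNA set."""
    values = list(lengths)
    if not values:
        raise ValueError("length_stats of an empty lncRNA set")
    return {
        "min": float(min(values)),
        "max": float(max(values)),
        "mean": float(sum(values) / len(values)),
    }
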