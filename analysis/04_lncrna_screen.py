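#!/usr/bin/env python
"""lncRNA screen over the novel isoforms of the simulated transcriptome.

Novel isoforms get synthetic transcript sequences (a third carry an
embedded long ORF, standing in for protein-coding novel transcripts) and
a synthetic protein-database hit table; the screen applies the >200 nt /
no-hit prefilter and an ensemble vote of two ORF-based predictors with
different stringency.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from isopipe.io_formats import read_annotation, read_flnc, read_junctions
from isopipe.lncrna import (
    OrfHeuristicPredictor,
    ensemble_vote,
    length_stats,
    prefilter_candidates,
)
from isopipe.pipeline import run_pipeline
from isopipe.synthetic import random_transcript_sequence

SEED = 20211104
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    result = run_pipeline(
        read_flnc(data / "flnc.bed"),
        read_junctions(data / "junctions.tsv"),
        read_annotation(data / "reference.gff3"),
    )
    novel_ids = {
        c.isoform_id for c in result.isoform_classes
        if c.category != "known_isoform"
    }
    lengths = {
        iso.model.transcript_id: iso.model.exonic_length
        for locus in result.loci
        for iso in locus.isoforms
        if iso.model.transcript_id in novel_ids
    }

    rng = np.random.default_rng(SEED)
    coding = {i for i in sorted(lengths) if rng.random() < 1 / 3}
    seqs = {
        i: random_transcript_sequence(
            max(length, 450),
            rng,
            orf_codons=140 if i in coding else None,
        )
        for i, length in sorted(lengths.items())
    }
    # coding isoforms also tend to hit the protein databases
    hits = {
        i: {"nr": i in coding and rng.random() < 0.7,
            "swissprot": i in coding and rng.random() < 0.5,
            "kog": False}
        for i in sorted(lengths)
    }

    seq_lengths = {i: len(s) for i, s in seqs.items()}
    candidates = prefilter_candidates(seq_lengths, hits)
    predictors = [
        OrfHeuristicPredictor("orf_strict", max_codons=100, max_coverage=0.35),
        OrfHeuristicPredictor("orf_lenient", max_codons=120, max_coverage=0.50),
    ]
    final, per_tool, failed = ensemble_vote(candidates, seqs, predictors)

    pd.DataFrame(
        [
            {
                "isoform_id": c.isoform_id,
                "length": c.length,
                **{p.name: c.isoform_id in per_tool[p.name] for p in predictors},
                "lncrna": c.isoform_id in final,
            }
            for c in candidates
        ]
    ).to_csv(ROOT / "lncrna_candidates.tsv", sep="\t", index=False)

    print(
        f"{len(lengths)} novel isoforms -> {len(candidates)} candidates after "
        f"length/annotation prefilter -> {len(final)} lncRNAs by unanimous vote"
    )
    for p in predictors:
        print(f"  {p.name}: {len(per_tool[p.name])} noncoding")
    if final:
        st = length_stats(seq_lengths[i] for i in final)
        print(
            f"lncRNA lengths: {st['min']:.0f}-{st['max']:.0f} nt, "
            f"mean {st['mean']:.0f} nt"
        )


if __name__ == "__main__":
    main()
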