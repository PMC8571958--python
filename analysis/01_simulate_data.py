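#!/usr/bin/env python
"""Generate the study dataset: a toy transcriptome with known truth.

Emits a "known" reference annotation (one fifth of gene loci withheld as
novel), aligned FLNC reads with realistic support/degradation/identity
structure, and a short-read junction support table, all under
``results/data/``.
"""

from pathlib import Path

import pandas as pd

from isopipe.io_formats import write_annotation, write_flnc, write_junctions
from isopipe.synthetic import SimulationConfig, simulate_flnc, simulate_reference

SEED = 20211103
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_genes=60, isoforms_per_gene=(1, 4), seed=SEED)
    annotation, truth = simulate_reference(cfg)
    records, junctions = simulate_flnc(truth, cfg)

    write_annotation(annotation.transcripts.values(), OUT / "reference.gff3")
    write_flnc(records, OUT / "flnc.bed")
    write_junctions(junctions, OUT / "junctions.tsv")
    pd.DataFrame(
        [
            {
                "isoform_id": t.isoform_id,
                "gene_id": t.gene_id,
                "novel_gene": t.novel_gene,
                "novel_isoform": t.novel_isoform,
                "polya_site": t.polya_site,
                "n_exons": len(t.model.exons),
            }
            for t in truth.isoforms.values()
        ]
    ).to_csv(OUT / "truth_isoforms.tsv", sep="\t", index=False)

    n_novel_genes = sum(g.novel for g in truth.genes.values())
    print(
        f"simulated {len(truth.genes)} gene loci ({n_novel_genes} withheld as "
        f"novel), {len(truth.isoforms)} isoforms, {len(records)} FLNC reads, "
        f"{len(junctions)} supported junctions -> {OUT}"
    )


if __name__ == "__main__":
    main()
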