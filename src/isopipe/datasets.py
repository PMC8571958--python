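"""Bundled example inputs: published summary numbers from a pooled
Iso-Seq survey of sheep tail fat (three thin-tailed vs three fat-tailed
crossbred rams).

These are *inputs*, not package results: the trait rows are the printed
``mean ± SD`` group summaries that feed the Welch tests, and the count
pairs are the printed category counts that feed the composition
percentages.  Everything derived from them is recomputed at run time.
"""

from __future__ import annotations

from .stats import GroupSummary

# trait -> (fat-tailed backcross DHH, thin-tailed grading-up DDH), n = 3 rams each
TRAIT_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "live_weight_kg": (
        GroupSummary("DHH", 3, 41.53, 0.95),
        GroupSummary("DDH", 3, 40.80, 4.57),
    ),
    "carcass_weight_kg": (
        GroupSummary("DHH", 3, 23.70, 0.64),
        GroupSummary("DDH", 3, 22.00, 2.27),
    ),
    "tail_fat_kg": (
        GroupSummary("DHH", 3, 0.78, 0.21),
        GroupSummary("DDH", 3, 0.11, 0.03),
    ),
}

# name -> (count, total): published category counts for composition stats
COMPOSITION_COUNTS: dict[str, tuple[int, int]] = {
    "multi_isoform_genes": (7_187, 20_041),      # genes with >= 2 isoforms
    "apa_genes": (1_662, 5_791),                 # >= 2 poly(A) sites among poly(A)+ genes
    "as_exon_skipping": (4_679, 17_834),
    "as_alt_acceptor": (2_728, 17_834),
    "as_intron_retention": (2_624, 17_834),
    "as_alt_donor": (1_409, 17_834),
}

# poly(A)-site accounting among polyadenylated gene loci
POLYA_GENES_TOTAL = 5_791
POLYA_GENES_MULTI = 1_662
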