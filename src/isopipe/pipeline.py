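"""End-to-end orchestration: reads in, characterized transcriptome out.

Order of operations: collapse FLNCs by splice chain -> drop 5'-degraded
models -> four-condition keep filter -> cluster kept isoforms into gene
loci -> classify loci and isoforms against the reference -> assign
``chrom.locus.isoform`` ids -> enumerate AS events per locus -> cluster
poly(A) sites per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import apa as apa_mod
from . import events as ev_mod
from .collapse import (
    CollapsedIsoform,
    FilterDecision,
    apply_keep_filter,
    collapse_flnc,
    flag_5prime_degraded,
)
from .io_formats import FlncRecord, JunctionSupportSet, ReferenceAnnotation
from .loci import (
    GeneLocus,
    IsoformClass,
    assign_isoform_ids,
    classify_isoforms,
    classify_loci,
    cluster_loci,
)


@dataclass
class PipelineResult:
    isoforms: list[CollapsedIsoform]
    degraded: list[CollapsedIsoform]
    filter_decisions: list[FilterDecision]
    loci: list[GeneLocus]
    isoform_classes: list[IsoformClass]
    as_events: list
    as_summary: pd.DataFrame
    apa_profiles: list
    apa_summary: dict
    id_map: dict[str, str] = field(default_factory=dict)

    @property
    def known_loci(self) -> list[GeneLocus]:
        return [l for l in self.loci if l.status == "known"]

    @property
    def novel_loci(self) -> list[GeneLocus]:
        return [l for l in self.loci if l.status == "novel"]

    def isoform_table(self) -> pd.DataFrame:
        cls = {c.isoform_id: c for c in self.isoform_classes}
        rows = []
        for locus in self.loci:
            for iso in locus.isoforms:
                c = cls[iso.model.transcript_id]
                rows.append(
                    {
                        "isoform_id": iso.model.transcript_id,
                        "locus_id": locus.locus_id,
                        "chrom": iso.model.chrom,
                        "strand": iso.model.strand,
                        "start": iso.model.start,
                        "end": iso.model.end,
                        "n_exons": len(iso.model.exons),
                        "n_flnc": iso.n_flnc,
                        "max_pid": iso.max_pid,
                        "category": c.category,
                        "matched_ref": c.matched_ref_transcript or "",
                        "novelty_reason": c.novelty_reason or "",
                    }
                )
        return pd.DataFrame(rows)

    def locus_table(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": l.locus_id,
                "chrom": l.chrom,
                "strand": l.strand,
                "start": l.start,
                "end": l.end,
                "n_isoforms": len(l.isoforms),
                "status": l.status,
                "ref_genes": ",".join(l.ref_gene_ids),
            }
            for l in self.loci
        ]
        return pd.DataFrame(rows)


def run_pipeline(
    records: list[FlncRecord],
    junctions: JunctionSupportSet,
    annotation: ReferenceAnnotation,
    pid_threshold: float = 99.0,
    min_flnc: int = 2,
    tes_tolerance: int = 50,
    recredit_support: bool = False,
    locus_min_frac: float = 0.2,
    apa_window: int = 30,
    apa_min_support: int = 2,
) -> PipelineResult:
    collapsed = collapse_flnc(records)
    surviving, degraded = flag_5prime_degraded(
        collapsed, tes_tolerance=tes_tolerance, recredit_support=recredit_support
    )
    kept, decisions = apply_keep_filter(
        surviving, junctions, annotation, pid_threshold, min_flnc
    )
    loci = cluster_loci(kept, min_frac=locus_min_frac)
    classify_loci(loci, annotation, min_frac=locus_min_frac)
    id_map = assign_isoform_ids(loci)
    classes = classify_isoforms(loci, annotation)

    as_events = ev_mod.enumerate_all_events(loci)
    as_summary = ev_mod.summarize_events(as_events)

    # read -> locus via the isoform each read supports
    read_to_locus: dict[str, str] = {}
    for locus in loci:
        for iso in locus.isoforms:
            for rid in iso.supporting_flnc_ids:
                read_to_locus[rid] = locus.locus_id
    positions, strands, _skipped = apa_mod.extract_tes(records, read_to_locus)
    profiles = apa_mod.profile_loci(
        positions, strands, window=apa_window, min_support=apa_min_support
    )
    summary = apa_mod.apa_summary(profiles)

    return PipelineResult(
        isoforms=kept,
        degraded=degraded,
        filter_decisions=decisions,
        loci=loci,
        isoform_classes=classes,
        as_events=as_events,
        as_summary=as_summary,
        apa_profiles=profiles,
        apa_summary=summary,
        id_map=id_map,
    )
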