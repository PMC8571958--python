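# isopipe

Long-read (PacBio Iso-Seq) transcriptome characterization for annotation-
poor genomes, built around the workflow used to survey sheep tail-fat
tissue: collapse aligned full-length non-chimeric (FLNC) reads into
isoforms, discover novel gene loci and novel isoforms against a reference
annotation, type alternative-splicing (AS) events, profile alternative
polyadenylation (APA), screen lncRNA candidates, and reproduce the study's
trait and correlation statistics. It is aimed at people analysing bulk
Iso-Seq data who want the characterization rules as a tested, scriptable
library rather than a chain of one-off tools.

## What it computes

* **Isoform collapse.** Multi-exon FLNCs sharing a splice chain — the
  ordered list of intron (donor, acceptor) pairs — are merged into one
  isoform whose terminal exons take the furthest observed 5′/3′ ends;
  mono-exon reads are grouped by single-linkage overlap on the same strand.
  Isoforms whose chain is a strict 3′-terminal sub-chain of a longer model
  ending at the same 3′ terminus are excluded as 5′-degradation artifacts.
* **Keep filter.** An isoform is kept iff it has ≥ 2 supporting FLNCs, or a
  single FLNC with alignment identity > 99%, or every splice site supported
  by short reads, or every junction present in the reference annotation.
* **Gene loci and novelty.** Isoforms overlapping > 20% of the shorter span
  on the same strand form one locus (single-linkage); a locus is novel when
  no same-strand reference gene covers ≥ 20% of its span; a known-locus
  isoform is novel unless its splice chain exactly matches a reference
  transcript. Novel models are named `chrom.locus.isoform`.
* **AS events.** Per locus, splice chains are pairwise aligned on shared
  splice sites; each maximal private run is one event, de-duplicated by
  signature and typed as exon skipping, intron retention, alternative donor
  / acceptor (strand-aware), or other.
* **APA.** Poly(A)-tagged read 3′ ends are clustered per locus by single
  linkage within a 30 nt window (support-weighted mode representative,
  ≥ 2-read support floor); loci with ≥ 2 sites exhibit APA.
* **lncRNA screen.** Novel isoforms > 200 nt with no protein-database hit
  are called lncRNA only by unanimous "noncoding" vote of all registered
  coding-potential predictors (a built-in ORF heuristic is included;
  external tool verdicts plug in from tables).
* **Statistics.** Welch unequal-variance t-tests recomputed directly from
  printed `mean ± SD` group summaries (t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂), with
  Welch–Satterthwaite df), exact composition percentages, and Pearson
  correlation grids with significance tiers.

A seeded synthetic-data generator (`isopipe.synthetic`) produces toy
annotations, FLNC alignments, junction tables, trait tables and expression
matrices with full ground truth, so the whole pipeline is testable offline.

## Worked example

```python
import isopipe as ip

cfg = ip.SimulationConfig(n_genes=60, seed=20211103)
annotation, truth = ip.simulate_reference(cfg)     # 12 of 60 loci withheld as novel
records, junctions = ip.simulate_flnc(truth, cfg)  # 536 aligned FLNC reads
result = ip.run_pipeline(records, junctions, annotation)
print(len(result.isoforms), len(result.loci), len(result.novel_loci))
print(result.as_summary)
```

prints `151 60 12` — 536 reads collapse to 151 kept isoforms (43
5′-degraded models excluded) in 60 loci of which the 12 simulated novel
loci are recovered — followed by the AS-event table, e.g.

```
         event_type  count  percent
0     exon_skipping     97    62.18
1      alt_acceptor      0     0.00
2  intron_retention      0     0.00
3         alt_donor      0     0.00
4             other     59    37.82
```

(the whole-transcriptome generator varies isoforms by exon skipping, so
skipping and complex events dominate; `simulate_as_locus` builds loci for
each of the four basic types individually). The same run drives the
numbered scripts in `analysis/`, which write the isoform/locus tables, the
AS/APA catalogues, the lncRNA screen and the trait statistics to
`results/`. The CLI mirrors them: `isopipe simulate|collapse|classify|
as-events|apa|lncrna|stats|run --help`.

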