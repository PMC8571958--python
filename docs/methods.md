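# Methods

## Scope and data model

The package characterizes a bulk Iso-Seq transcriptome starting from
*aligned* full-length non-chimeric reads (FLNCs). Consensus calling,
error correction and spliced alignment happen upstream; a read enters the
pipeline as a BED12+2 record — twelve standard BED columns plus alignment
percent identity (PID, 0–100) and a poly(A)-tail flag. All internal
coordinates are 0-based half-open on one convention throughout; GFF3/GTF
conversion happens only at the file boundary, which removes the usual
off-by-one drift between BED-side and GFF-side code. Short-read splice
junctions arrive as a TSV keyed by (chrom, strand, intron start, intron
end); a junction recorded with strand "." (unstranded libraries) matches
a query on either strand.

## Collapse and filtering

Two multi-exon reads are the same isoform iff they share chromosome,
strand and splice chain (the ordered intron coordinate pairs). Matching
is exact by default; a wobble window is configurable but off, since
error-corrected FLNCs make exact coordinates the reproducible choice.
The merged model takes the furthest observed 5′ and 3′ termini among its
supporters; its PID is the maximum over supporters (for the single-read
case, where the filter actually uses it, max equals the value).
Mono-exon reads have no chain and are grouped by single-linkage genomic
overlap (any overlap ≥ 1 bp, same strand); this grouping is verified
against brute-force connected components in the tests.

5′ degradation: isoform A is excluded when some isoform B on the same
chromosome and strand has A's chain as a *strict* 3′-terminal sub-chain
(genomic suffix on +, genomic prefix on −) and A's 3′ terminus lies
within 50 nt (configurable) of B's. The empty chain counts as a strict
suffix, so a mono-exon fragment ending at a multi-exon isoform's terminus
is treated as a degradation product. A 5′-prefix relation (shared 5′ end,
early stop) is 3′ truncation, not degradation, and is never flagged.
Whether the degraded model's reads are re-credited to the parent is a
flag (default off): either bookkeeping is defensible and the choice only
affects support counts, not the isoform set.

The keep filter is a disjunction evaluated in a fixed order, and the
reported reason code is the first satisfied condition: (1) ≥ 2 FLNCs;
(2) exactly one FLNC with PID strictly above 99; (3) every intron
present in the short-read junction set; (4) every intron present in the
reference annotation. Conditions (1) and (2) are mutually exclusive by
construction. A mono-exon isoform satisfies (3) and (4) vacuously (an
empty set of splice sites is fully supported); its reason code carries a
`_vacuous` suffix so such keeps can be audited or re-filtered by the
caller.

## Loci and novelty

The 20% rules use genomic span with the shorter element as denominator
(an exonic-length mode is selectable): two isoforms are linked when their
span overlap strictly exceeds 20% of the shorter span on the same strand,
and loci are the single-linkage components of that relation. A locus is
known when some same-strand reference gene span covers at least 20% of
the locus span, and is linked to all qualifying genes; an
antisense-only overlap leaves the locus novel. Isoform novelty is exact
splice-chain equality against the linked genes' transcripts — terminal
exon end positions are deliberately not compared, because they vary with
degradation and cleavage heterogeneity. Novel isoforms get a structural
reason: final 3′ splice site changed, new intron (an extra intron inside
a reference exon), new exon (an exon inside a reference intron), or other
chain difference. Ids follow `chrom.locus.isoform` with locus and isoform
numbers running 5′→3′ along the chromosome; this naming is this package's
convention for novel models.

## AS events

For each isoform pair at a locus the two splice-site sets are split into
shared and private coordinates; each maximal run of private sites between
consecutive shared sites (or transcript bounds) is one candidate event,
whose signature is the canonicalised pair of private intron tuples. The
catalogue per locus is the set of distinct signatures — counting
signatures rather than pairs is the only order-invariant choice and makes
a duplicated transcript contribute nothing. Typing is structural:
2-vs-1 introns with matching outer boundaries is exon skipping; 1-vs-0
with the intron inside the partner's exon is intron retention; 1-vs-1
sharing one boundary is an alternative donor or acceptor, with donor
defined as the intron's 5′ splice site in transcript orientation (so the
labels swap under strand reversal, which is property-tested); everything
else — including mutually exclusive exons, complex rearrangements and
terminal-exon differences — lands in "other". Mono-exon isoforms
participate in pairing: full retention of a transcript's only intron
produces a mono-exon partner that must still register as intron
retention.

## APA

Poly(A)-tagged reads contribute their strand-aware 3′-end coordinate to
their locus. Ends are clustered by single linkage with a 30 nt merge
window and a 2-read support floor (both configurable). The window
tolerates the ±10 nt cleavage heterogeneity typical of 3′-end data while
separating genuine APA sites, which sit hundreds of nt apart; the floor
suppresses one-off internal priming or mapping noise. The cluster
representative is the support-weighted mode, with ties resolved toward
the most distal 3′ position (reproducible and strand-meaningful). Note
that site counts are non-increasing in the window only *before* the
support floor: a wider window can merge two singletons into a surviving
cluster. Poly(A)-motif scanning and genomic A-stretch (internal priming)
filtering need genome sequence and are out of scope.

## lncRNA screen

Candidates are novel isoforms with transcript length strictly greater
than 200 nt and no hit in any protein database of an externally produced
hit table (isoforms missing from the table are treated as no-hit, with a
warning). The final call is the intersection of "noncoding" verdicts
over all registered predictors, mirroring the usual multi-tool Venn; the
predictor contract is a name plus a callable `(id, sequence) → verdict`,
so external tools' outputs can be imported from tables. The built-in
heuristic calls a transcript noncoding when its longest forward-frame
ORF is under 100 codons *and* covers under 35% of the transcript; these
are conventional lncRNA-screen thresholds, not fitted values, and both
are configurable. Reverse-strand ORFs are not scanned because Iso-Seq
transcripts are orientation-resolved.

## Statistics

Welch's unequal-variance t-test is computed directly from per-group
(n, mean, SD) summaries with Welch–Satterthwaite degrees of freedom and a
two-sided p. Trait tables printed as `mean ± SD` reproduce the published
t and df for all three traits of the bundled six-ram trial to within
input-rounding error, whereas a `± SEM` reading does not — which is why
the package interprets ± as SD and does not offer a pooled-variance test
(the published fractional dfs identify the Welch form). Composition
percentages use half-up rounding to two decimals. Correlation grids
report Pearson r with raw two-sided p and significance tiers at
0.05/0.01/0.001; a Benjamini–Hochberg column is available but off by
default, matching the raw-tier display convention of the source heatmap.

## Synthetic data

`SimulationConfig` defines the study conditions. Genes are laid out
left-to-right with 1–5 kb intergenic gaps (never overlapping), with 4–9
exons of 80–400 nt and introns of 0.2–2 kb; isoforms are distinct
internal-exon subsets that always keep the first and last exon, so
same-gene isoforms overlap far beyond the 20% rule and all carry introns.
A fifth of genes are withheld from the "known" annotation as novel loci,
and 30% of non-base isoforms of known genes are withheld as novel
isoforms. Reads inherit their isoform's chain; 10% are 5′-degraded
(whole 5′ exons lost plus truncation into the new first exon, 3′ end
kept), others get ≤ 10 nt TSS jitter; PID ~ N(99.2, 0.6) clipped to
[90, 100], emulating corrected-read identities; 90% of reads are
poly(A)-tagged; per-gene 1–3 poly(A) sites sit 100–300 nt apart in the
3′-terminal exon with N(0, 3 nt) cleavage noise; 90% of true junctions
receive short-read support. Every draw comes from one seeded generator,
so output is byte-identical under a fixed seed.

What the generator does not emulate: base-level sequencing error,
quality scores, chimeras, fusion genes, overlapping or nested genes,
expression-dependent coverage bias, and genome sequence (transcript
sequences for the lncRNA screen are generated independently, with ORFs
embedded by construction). Passing the recovery tests therefore shows
the *rules* are implemented correctly under clean, well-separated
conditions; it does not certify performance on real alignments with
wobbly splice sites or overlapping loci.

Problem sizes used by the bundled analyses and checks — 50–60 genes,
~150 isoforms, ~500 reads, 100-instance oracle sweeps, 2,000-replicate
calibration runs — were chosen as the smallest scales at which every rule
(multi-isoform loci, novel genes, APA, degradation) is exercised with
comfortable margins.

## Numerical and degenerate-input choices

Empty AS catalogues report zero counts with an explicit
`undefined_fractions` flag rather than NaNs. `length_stats` of an empty
lncRNA set and a Welch test with two zero-variance identical groups are
errors, not silent NaNs. Zero-variance expression vectors yield a
flagged NaN correlation cell. Interval and junction keys are exact
integers, so no floating tolerances enter the genomic logic; the only
tolerances in the package are the degradation 3′-terminus window (50 nt)
and the APA merge window (30 nt), both documented above and configurable.
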