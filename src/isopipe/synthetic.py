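"""Synthetic data with known ground truth.

Generates toy reference annotations, aligned FLNC reads, short-read
junction support, per-animal trait tables and expression matrices so that
every pipeline stage can be exercised and scored without any download.

The generator emits *alignments*, not sequences: real Iso-Seq reads would
pass through consensus calling, error correction and a spliced aligner
first, and the pipeline's contract starts where alignment ends.  What is
modeled per read: shared splice chains with controlled per-isoform
support, 5'-terminal degradation (loss of whole 5' exons plus truncation
into the new first exon, with the 3' terminus preserved), small TSS
jitter, alignment percent identity, poly(A) tagging, and per-gene
alternative 3'-end sites.  Base-level errors, quality scores and chimeric
reads are not modeled.

Every draw is taken from a generator seeded by ``SimulationConfig.seed``,
so any fixed config reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .collapse import CollapsedIsoform
from .io_formats import (
    FlncRecord,
    JunctionSupportSet,
    ReferenceAnnotation,
    TranscriptModel,
)
from .loci import GeneLocus
from .stats import GroupSummary

IntOrRange = int | tuple[int, int]


def _draw(rng: np.random.Generator, spec: IntOrRange) -> int:
    if isinstance(spec, tuple):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the toy transcriptome.

    Defaults sketch a small Iso-Seq-like experiment: multi-isoform genes
    on one pseudo-chromosome, a fifth of gene loci withheld from the
    "known" annotation, LoRDEC-corrected-grade alignment identities, and
    mostly poly(A)-tagged reads with per-gene APA structure.
    """

    n_genes: int = 50
    n_chromosomes: int = 1
    isoforms_per_gene: IntOrRange = (1, 4)
    exons_per_gene: IntOrRange = (4, 9)
    exon_length: IntOrRange = (80, 400)
    intron_length: IntOrRange = (200, 2000)
    intergenic_gap: IntOrRange = (1000, 5000)
    novel_gene_fraction: float = 0.2
    novel_isoform_fraction: float = 0.3
    degraded_5p_fraction: float = 0.1
    flnc_per_isoform: IntOrRange = (1, 6)
    pid_mean: float = 99.2
    pid_sd: float = 0.6
    pid_min: float = 90.0
    polya_prob: float = 0.9
    apa_sites_per_gene: IntOrRange = (1, 3)
    apa_site_spacing: IntOrRange = (100, 300)
    cleavage_jitter_sd: float = 3.0
    tss_jitter: int = 10
    junction_support_prob: float = 0.9
    junction_mean_reads: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "novel_gene_fraction",
            "novel_isoform_fraction",
            "degraded_5p_fraction",
            "polya_prob",
            "junction_support_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be >= 1")
        if self.pid_sd < 0 or self.cleavage_jitter_sd < 0 or self.tss_jitter < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass
class TruthIsoform:
    isoform_id: str
    gene_id: str
    model: TranscriptModel
    novel_gene: bool
    novel_isoform: bool
    polya_site: int


@dataclass
class TruthGene:
    gene_id: str
    chrom: str
    strand: str
    novel: bool
    polya_sites: tuple[int, ...]


@dataclass
class TruthSet:
    genes: dict[str, TruthGene] = field(default_factory=dict)
    isoforms: dict[str, TruthIsoform] = field(default_factory=dict)
    read_to_isoform: dict[str, str] = field(default_factory=dict)

    def structure_keys(self) -> set[tuple]:
        return {t.model.structure_key() for t in self.isoforms.values()}


def _gene_exons(
    rng: np.random.Generator, cfg: SimulationConfig, cursor: int
) -> tuple[tuple[tuple[int, int], ...], int]:
    n_exons = _draw(rng, cfg.exons_per_gene)
    exons = []
    pos = cursor
    for i in range(n_exons):
        if i:
            pos += _draw(rng, cfg.intron_length)
        length = _draw(rng, cfg.exon_length)
        exons.append((pos, pos + length))
        pos += length
    return tuple(exons), pos


def _isoform_exon_sets(
    rng: np.random.Generator, exons: tuple[tuple[int, int], ...], n_iso: int
) -> list[tuple[tuple[int, int], ...]]:
    """Distinct exon chains: the full model plus skip variants.

    Every isoform keeps the first and last exon, so same-gene isoforms
    overlap heavily and always carry at least one intron (when the gene
    is multi-exonic); distinct internal-exon subsets guarantee distinct
    splice chains.
    """
    n_internal = max(0, len(exons) - 2)
    max_iso = 2**n_internal
    n_iso = min(n_iso, max_iso)
    chosen: list[tuple[int, ...]] = [tuple(range(1, 1 + n_internal))]  # full model
    tries = 0
    while len(chosen) < n_iso and tries < 200 * n_iso:
        tries += 1
        mask = rng.random(n_internal) < 0.7  # each internal exon kept w.p. 0.7
        subset = tuple(i + 1 for i in range(n_internal) if mask[i])
        if subset not in chosen:
            chosen.append(subset)
    out = []
    for subset in chosen:
        keep = {0, len(exons) - 1} | set(subset)
        out.append(tuple(exons[i] for i in sorted(keep)))
    return out


def _gene_polya_sites(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    exons: tuple[tuple[int, int], ...],
    strand: str,
) -> tuple[int, ...]:
    """Distinct 3'-end sites: the annotated TES plus upstream sites
    inside the 3'-terminal exon, spaced by the configured offsets."""
    n_sites = _draw(rng, cfg.apa_sites_per_gene)
    if strand == "+":
        s, e = exons[-1]
        sites = [e]
        pos = e
        for _ in range(n_sites - 1):
            pos -= _draw(rng, cfg.apa_site_spacing)
            if pos <= s + 1:
                break
            sites.append(pos)
    else:
        s, e = exons[0]
        sites = [s]
        pos = s
        for _ in range(n_sites - 1):
            pos += _draw(rng, cfg.apa_site_spacing)
            if pos >= e - 1:
                break
            sites.append(pos)
    return tuple(sites)


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceAnnotation, TruthSet]:
    """Toy genome annotation plus the full ground truth.

    The returned annotation is the "known" reference: genes flagged novel
    and isoforms flagged novel are withheld from it but present in the
    truth set (their reads are still emitted by :func:`simulate_flnc`).
    Genes never overlap; an infeasible geometry (negative lengths from a
    bad config) raises.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    truth = TruthSet()
    known_models: list[TranscriptModel] = []

    n_novel = int(round(config.n_genes * config.novel_gene_fraction))
    novel_idx = set(
        rng.choice(config.n_genes, size=n_novel, replace=False).tolist()
    )

    cursors = {str(c + 1): 10_000 for c in range(config.n_chromosomes)}
    for g in range(config.n_genes):
        chrom = str(g % config.n_chromosomes + 1)
        cursors[chrom] += _draw(rng, config.intergenic_gap)
        exons, gene_end = _gene_exons(rng, config, cursors[chrom])
        cursors[chrom] = gene_end
        if exons[-1][1] <= exons[0][0]:
            raise ValueError("infeasible gene geometry from config")
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{g + 1:04d}"
        gene_novel = g in novel_idx

        n_iso = _draw(rng, config.isoforms_per_gene)
        exon_sets = _isoform_exon_sets(rng, exons, n_iso)
        sites = _gene_polya_sites(rng, config, exons, strand)
        truth.genes[gene_id] = TruthGene(gene_id, chrom, strand, gene_novel, sites)

        for i, iso_exons in enumerate(exon_sets):
            iso_id = f"{gene_id}.T{i + 1}"
            model = TranscriptModel(iso_id, chrom, strand, iso_exons, gene_id=gene_id)
            iso_novel = gene_novel or (
                i > 0 and rng.random() < config.novel_isoform_fraction
            )
            truth.isoforms[iso_id] = TruthIsoform(
                iso_id,
                gene_id,
                model,
                gene_novel,
                iso_novel,
                polya_site=sites[i % len(sites)],
            )
            if not iso_novel:
                known_models.append(model)

    return ReferenceAnnotation(known_models), truth


def _degrade_5p(
    rng: np.random.Generator, exons: list[tuple[int, int]], strand: str
) -> list[tuple[int, int]]:
    """Drop whole 5' exons and truncate into the new first exon; the 3'
    terminus is untouched (the Iso-Seq degradation artifact)."""
    k = int(rng.integers(1, len(exons)))  # 1 .. n-1 exons lost
    if strand == "+":
        exons = exons[k:]
        s, e = exons[0]
        trim = int(rng.integers(0, max(1, (e - s) // 2)))
        exons[0] = (s + trim, e)
    else:
        exons = exons[:-k]
        s, e = exons[-1]
        trim = int(rng.integers(0, max(1, (e - s) // 2)))
        exons[-1] = (s, e - trim)
    return exons


def simulate_flnc(
    truth: TruthSet, config: SimulationConfig
) -> tuple[list[FlncRecord], JunctionSupportSet]:
    """Aligned FLNC reads plus short-read junction support.

    Each read derives from exactly one truth isoform
    (``truth.read_to_isoform`` is filled in); junction support is emitted
    per intron of the truth transcriptome with the configured
    probability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records: list[FlncRecord] = []

    for iso_id in sorted(truth.isoforms):
        iso = truth.isoforms[iso_id]
        model = iso.model
        strand = model.strand
        n_reads = _draw(rng, config.flnc_per_isoform)
        for j in range(n_reads):
            exons = list(model.exons)
            degraded = (
                len(exons) >= 2 and rng.random() < config.degraded_5p_fraction
            )
            if degraded:
                exons = _degrade_5p(rng, exons, strand)
            elif config.tss_jitter > 0:
                trim = int(rng.integers(0, config.tss_jitter + 1))
                if strand == "+":
                    s, e = exons[0]
                    exons[0] = (min(s + trim, e - 1), e)
                else:
                    s, e = exons[-1]
                    exons[-1] = (s, max(e - trim, s + 1))

            # 3' end lands at the isoform's poly(A) site, with cleavage noise
            jitter = (
                int(round(rng.normal(0.0, config.cleavage_jitter_sd)))
                if config.cleavage_jitter_sd > 0
                else 0
            )
            if strand == "+":
                s, e = exons[-1]
                exons[-1] = (s, max(iso.polya_site + jitter, s + 1))
            else:
                s, e = exons[0]
                exons[0] = (min(max(iso.polya_site + jitter, 0), e - 1), e)

            pid = (
                float(np.clip(rng.normal(config.pid_mean, config.pid_sd),
                              config.pid_min, 100.0))
                if config.pid_sd > 0
                else float(min(config.pid_mean, 100.0))
            )
            read_id = f"{iso_id}.r{j + 1}"
            records.append(
                FlncRecord(
                    read_id=read_id,
                    chrom=model.chrom,
                    strand=strand,
                    exons=tuple(exons),
                    percent_identity=round(pid, 2),
                    polya=bool(rng.random() < config.polya_prob),
                )
            )
            truth.read_to_isoform[read_id] = iso_id

    junctions = JunctionSupportSet()
    introns = sorted(
        {
            (t.model.chrom, t.model.strand, d, a)
            for t in truth.isoforms.values()
            for d, a in t.model.splice_chain
        }
    )
    for chrom, strand, d, a in introns:
        if rng.random() < config.junction_support_prob:
            count = 1 + int(rng.poisson(config.junction_mean_reads))
            junctions.add(chrom, strand, d, a, count)
    return records, junctions


# ---------------------------------------------------------------------------
# AS-event grammar: loci built to contain exactly one known event
# ---------------------------------------------------------------------------


def simulate_as_locus(
    event_type: str,
    rng: np.random.Generator,
    locus_id: str = "sim.1",
    n_exons: int = 5,
) -> GeneLocus:
    """A two-isoform locus whose pair exhibits exactly one event of
    ``event_type`` (one of the four basic types).

    Only one internal intron is perturbed, so the splice-chain alignment
    yields a single differing region and hence a single event.
    """
    from .events import ALT_ACCEPTOR, ALT_DONOR, EXON_SKIPPING, INTRON_RETENTION

    strand = "+" if rng.random() < 0.5 else "-"
    chrom = "sim"
    exons = []
    pos = int(rng.integers(1_000, 50_000))
    for _ in range(n_exons):
        length = int(rng.integers(80, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(200, 800))
    exons_t = tuple(exons)
    base = TranscriptModel("T1", chrom, strand, exons_t)

    i = int(rng.integers(1, n_exons - 1))  # internal exon index
    var_exons: list[tuple[int, int]]
    if event_type == EXON_SKIPPING:
        var_exons = [e for k, e in enumerate(exons) if k != i]
    elif event_type == INTRON_RETENTION:
        var_exons = exons[: i - 1] + [(exons[i - 1][0], exons[i][1])] + exons[i + 1:]
    elif event_type in (ALT_DONOR, ALT_ACCEPTOR):
        delta = int(rng.integers(10, 60))
        var_exons = list(exons)
        # donor = 5' splice site of the intron between exon i-1 and i
        # (+ strand: end of exon i-1; - strand: start of exon i)
        move_donor = event_type == ALT_DONOR
        if (strand == "+") == move_donor:
            s, e = var_exons[i - 1]
            var_exons[i - 1] = (s, e - delta)
        else:
            s, e = var_exons[i]
            var_exons[i] = (s + delta, e)
    else:
        raise ValueError(f"unknown basic event type {event_type!r}")

    variant = TranscriptModel("T2", chrom, strand, tuple(var_exons))
    isoforms = [
        CollapsedIsoform(m, (f"{m.transcript_id}.r1",), 100.0)
        for m in (base, variant)
    ]
    return GeneLocus(
        locus_id,
        chrom,
        strand,
        min(base.start, variant.start),
        max(base.end, variant.end),
        isoforms,
    )


# ---------------------------------------------------------------------------
# Traits, expression, sequences
# ---------------------------------------------------------------------------


def simulate_traits(
    groups: list[GroupSummary], seed: int = 0
) -> pd.DataFrame:
    """Per-animal trait values drawn as N(mean, sd) per group.

    Returns a frame with columns (subject, group, value); sample moments
    converge to the specified ones as n grows.  ``sd < 0`` is rejected by
    :class:`GroupSummary`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        values = rng.normal(g.mean, g.sd, size=g.n)
        for i, v in enumerate(values, start=1):
            rows.append({"subject": f"{g.label}_{i}", "group": g.label,
                         "value": float(v)})
    return pd.DataFrame(rows)


def simulate_expression(
    n_transcripts: int,
    n_samples: int,
    blocks: list[tuple[int, float]] | None = None,
    seed: int = 0,
    log_mean: float = 2.0,
    log_sd: float = 1.0,
) -> pd.DataFrame:
    """Expression matrix (transcripts x samples) with block correlation.

    ``blocks`` lists (size, r) diagonal blocks on the log scale; leftover
    transcripts are independent.  Values are multivariate normal on the
    log scale and exponentiated, so the block correlations are
    recoverable from log-transformed samples.  A non-positive-semidefinite
    block matrix is rejected.
    """
    blocks = blocks or []
    corr = np.eye(n_transcripts)
    pos = 0
    for size, r in blocks:
        if pos + size > n_transcripts:
            raise ValueError("blocks exceed n_transcripts")
        corr[pos : pos + size, pos : pos + size] = r
        np.fill_diagonal(corr[pos : pos + size, pos : pos + size], 1.0)
        pos += size
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {eigmin:g})")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_transcripts))
    z = chol @ rng.standard_normal((n_transcripts, n_samples))
    values = np.exp(log_mean + log_sd * z)
    return pd.DataFrame(
        values,
        index=[f"t{i + 1:04d}" for i in range(n_transcripts)],
        columns=[f"s{j + 1:03d}" for j in range(n_samples)],
    )


_BASES = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}


def random_transcript_sequence(
    length: int, rng: np.random.Generator, orf_codons: int | None = None
) -> str:
    """Random nucleotide sequence, optionally with an embedded ORF of
    ``orf_codons`` sense codons (ATG ... stop) at a random in-bounds
    offset."""
    seq = list(rng.choice(_BASES, size=length))
    if orf_codons:
        need = 3 * (orf_codons + 1) + 3
        if need > length:
            raise ValueError("sequence too short for requested ORF")
        start = int(rng.integers(0, length - need + 1))
        codons = ["ATG"]
        while len(codons) < orf_codons + 1:
            c = "".join(rng.choice(_BASES, size=3))
            if c not in _STOP_CODONS:
                codons.append(c)
        codons.append("TAA")
        orf = "".join(codons)
        seq[start : start + len(orf)] = list(orf)
    return "".join(seq)
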