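"""Synthetic bacterial RNA-seq with planted A-to-I editing ground truth.

Generates a random bacterial-like genome with stranded CDS annotations,
rewrites chosen in-gene positions so the coding strand carries the
deaminase recognition motif YTACGAA (edited adenosine at motif position 3)
optionally embedded in a stem-loop, and simulates stranded single-end
replicate reads in which each read covering an edited adenosine carries G
independently with the site's designed editing level.  Strain-specific
SNPs (~100% allele frequency) and uniform sequencing errors exercise the
downstream frequency-ceiling and quality filters.

Everything is deterministic for a fixed ``SimConfig.seed``: the master
seed feeds fixed child streams (genome=0, planting=1, SNPs=2, replicate r
reads=10+r).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import AnnotatedGenome, Gene, Read, revcomp, write_fastq

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = np.array(list("ACGT"))

# 17-nt fold-window geometry: the edited A sits at 1-based window position 8
# (7 bases upstream, 9 downstream) and the 7-mer motif occupies 0-based
# window indices 5..11, leaving 5-base flanks on either side for the stem.
WINDOW_UP = 7
WINDOW_DOWN = 9
MOTIF_OFFSET_IN_WINDOW = 5  # 0-based start of the 7-mer within the window
MAX_STEM = 5


@dataclass
class SimConfig:
    """Conditions of a simulated editing study.

    Defaults are the reference conditions used throughout the test-suite
    and acceptance runs: 30 sites at uniform 10-60% levels, 50x coverage,
    3 replicates, 0.1% error, constant Q37, stranded library, 5 strain
    SNPs, on a 50 kb genome with 40 CDS.
    """

    genome_length: int = 50_000
    gc_content: float = 0.5
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (300, 900)  # bases, multiples of 3
    n_edit_sites: int = 30
    level_distribution: tuple[float, float] | list[float] = (0.10, 0.60)
    hairpin_fraction: float = 1.0
    hairpin_stem_length: int = 5
    read_length: int = 100
    mean_coverage: float = 50.0
    error_rate: float = 1e-3
    base_quality: int = 37
    low_quality_tail: int = 0  # trailing bases forced to Q2, exercises trimming
    n_replicates: int = 3
    stranded: bool = True
    n_strain_snps: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3:
            raise ValueError("gene lengths must be multiples of 3 (CDS)")
        if lo < 2 * self.read_length + 2 * (WINDOW_DOWN + 1):
            raise ValueError(
                "minimum gene length must leave read_length margin on both "
                "sides of a planted site"
            )
        if self.n_edit_sites > self.n_genes:
            raise ValueError("one editing site per gene: n_edit_sites <= n_genes")
        if not 1 <= self.hairpin_stem_length <= MAX_STEM:
            raise ValueError(f"hairpin_stem_length must be in [1, {MAX_STEM}]")
        if isinstance(self.level_distribution, tuple):
            lo, hi = self.level_distribution
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError("level range must satisfy 0 <= lo <= hi <= 1")
        else:
            if any(not 0.0 <= x <= 1.0 for x in self.level_distribution):
                raise ValueError("levels must be in [0, 1]")
        if self.n_genes * self.gene_length_range[1] > self.genome_length:
            raise ValueError(
                "capacity error: n_genes x max gene length exceeds genome_length"
            )


@dataclass(frozen=True)
class TruthRecord:
    """A planted editing site, the ground truth for recovery tests."""

    contig: str
    position: int  # 0-based coordinate of the edited A on the forward strand
    gene_id: str
    gene_strand: str
    designed_level: float
    context7: str  # 7-mer on the coding strand, edited A at offset 3 (1-based)
    in_hairpin: bool


@dataclass(frozen=True)
class SnpRecord:
    """A planted strain-specific SNP (present in ~100% of reads)."""

    contig: str
    position: int  # 0-based forward-strand coordinate
    gene_id: str
    ref: str  # forward-strand reference base
    alt: str  # forward-strand strain base


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: AnnotatedGenome
    truth: list[TruthRecord]
    snps: list[SnpRecord]
    reads: dict[str, list[Read]]  # sample name -> reads


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(stream)])


# ---------------------------------------------------------------------------
# Genome generation


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + stop-free internal codons + one stop codon."""
    n_internal = length // 3 - 2
    codons = []
    while len(codons) < n_internal:
        chunk = _random_bases(rng, 3 * (n_internal - len(codons)), gc)
        for i in range(0, len(chunk), 3):
            codon = "".join(chunk[i : i + 3])
            if codon not in STOP_CODONS:
                codons.append(codon)
    stop = rng.choice(np.array(STOP_CODONS))
    return "ATG" + "".join(codons) + str(stop)


def generate_genome(config: SimConfig) -> AnnotatedGenome:
    """Random genome with non-overlapping, stop-free CDS on both strands."""
    config.validate()
    rng = _rng(config, 0)
    seq = _random_bases(rng, config.genome_length, config.gc_content)

    lo, hi = config.gene_length_range
    lengths = (rng.integers(lo // 3, hi // 3 + 1, size=config.n_genes) * 3).tolist()
    slack = config.genome_length - sum(lengths)
    if slack < config.n_genes + 1:
        raise ValueError("capacity error: genes do not fit in the genome")
    # random inter-gene gaps that always sum to the available slack
    cuts = np.sort(rng.choice(slack, size=config.n_genes, replace=False))
    gaps = np.diff(np.concatenate([[0], cuts]))

    genes = []
    pos = 0
    for i, (length, gap) in enumerate(zip(lengths, gaps)):
        pos += int(gap)
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _random_cds(rng, length, config.gc_content)
        forward = cds if strand == "+" else revcomp(cds)
        seq[pos : pos + length] = list(forward)
        genes.append(Gene(f"gene{i:04d}", "chr", pos, pos + length, strand, "CDS"))
        pos += length
    return AnnotatedGenome({"chr": "".join(seq)}, genes)


# ---------------------------------------------------------------------------
# Editing-site planting


def _has_frame_stop(cds: str, start: int, end: int) -> bool:
    """Any stop codon in the codons covering [start, end) of a CDS?"""
    first = (start // 3) * 3
    last = -(-end // 3) * 3
    for i in range(first, min(last, len(cds) - 3), 3):  # never the real stop
        if cds[i : i + 3] in STOP_CODONS:
            return True
    return False


def _gc_fraction(s: str) -> float:
    return sum(c in "GC" for c in s) / len(s)


def plant_editing_sites(
    genome: AnnotatedGenome, config: SimConfig
) -> tuple[AnnotatedGenome, list[TruthRecord]]:
    """Rewrite gene-internal loci to YTACGAA motifs, optionally in hairpins.

    The local coding-strand sequence becomes Y T A C G A A with the edited
    A at 7-mer offset 3 (1-based).  For hairpin sites the 3' flank of the
    17-nt window is rewritten to the reverse complement of the 5' flank's
    first ``hairpin_stem_length`` bases, leaving the 7-mer in the loop; the
    5' stem is resampled to be GC-biased so the stem is thermodynamically
    stable.  Codon frame is preserved: placements that would introduce an
    in-frame stop (in the reference or the edited sequence) are retried.
    """
    config.validate()
    rng = _rng(config, 1)
    sequences = {k: list(v) for k, v in genome.sequences.items()}

    margin = max(config.read_length, WINDOW_DOWN + 1)
    eligible = [
        g for g in genome.genes
        if g.feature_type == "CDS" and g.length >= 2 * margin + 2 * (WINDOW_DOWN + 1)
    ]
    if len(eligible) < config.n_edit_sites:
        raise ValueError("genome lacks enough eligible genes for n_edit_sites")
    chosen = rng.choice(len(eligible), size=config.n_edit_sites, replace=False)

    levels = config.level_distribution
    fixed_levels = None if isinstance(levels, tuple) else list(levels)

    truth: list[TruthRecord] = []
    for k, gi in enumerate(sorted(chosen.tolist())):
        gene = eligible[gi]
        cds = list(genome.coding_sequence(gene))
        in_hairpin = bool(rng.random() < config.hairpin_fraction)
        stem = config.hairpin_stem_length

        placed = False
        for _attempt in range(200):
            # p: 0-based position of the edited A within the coding sequence
            p = int(rng.integers(margin, gene.length - margin))
            trial = cds.copy()
            y = "C" if rng.random() < 0.5 else "T"
            trial[p - 2 : p + 5] = list(y + "TACGAA")
            if in_hairpin:
                w0 = p - WINDOW_UP
                five = _random_bases(rng, stem, 0.75)
                while _gc_fraction("".join(five)) < 0.6:
                    five = _random_bases(rng, stem, 0.75)
                trial[w0 : w0 + stem] = list(five)
                three = revcomp("".join(five))
                trial[w0 + 17 - stem : w0 + 17] = list(three)
            lo, hi_ = p - WINDOW_UP, p + WINDOW_DOWN + 1
            s = "".join(trial)
            if _has_frame_stop(s, lo, hi_):
                continue
            edited = s[:p] + "G" + s[p + 1 :]
            if _has_frame_stop(edited, lo, hi_):
                continue
            cds = trial
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place editing site in {gene.gene_id}")

        # write the (possibly reverse-complemented) coding sequence back
        forward = "".join(cds) if gene.strand == "+" else revcomp("".join(cds))
        sequences[gene.contig][gene.start : gene.end] = list(forward)

        fwd_pos = gene.start + p if gene.strand == "+" else gene.end - 1 - p
        if fixed_levels is not None:
            level = float(fixed_levels[k % len(fixed_levels)])
        else:
            level = float(rng.uniform(*levels))
        truth.append(
            TruthRecord(
                contig=gene.contig,
                position=fwd_pos,
                gene_id=gene.gene_id,
                gene_strand=gene.strand,
                designed_level=level,
                context7="".join(cds[p - 2 : p + 5]),
                in_hairpin=in_hairpin,
            )
        )

    new_genome = genome.with_sequences({k: "".join(v) for k, v in sequences.items()})
    truth.sort(key=lambda t: (t.contig, t.position))
    return new_genome, truth


def place_strain_snps(
    genome: AnnotatedGenome, truth: list[TruthRecord], config: SimConfig
) -> list[SnpRecord]:
    """Pick non-edited, in-gene coding-strand A positions as strain A>G SNPs.

    These appear in every read (frequency ~100%) and must be removed by the
    <=98% frequency ceiling downstream.
    """
    rng = _rng(config, 2)
    forbidden = {(t.contig, t.position) for t in truth}
    margin = config.read_length
    candidates = []
    for g in genome.genes:
        cds = genome.coding_sequence(g)
        for p in range(margin, g.length - margin):
            if cds[p] != "A":
                continue
            fwd = g.start + p if g.strand == "+" else g.end - 1 - p
            if (g.contig, fwd) in forbidden:
                continue
            if any(t.gene_id == g.gene_id and abs(fwd - t.position) <= WINDOW_DOWN
                   for t in truth):
                continue
            candidates.append((g, fwd))
    if len(candidates) < config.n_strain_snps:
        raise ValueError("not enough candidate positions for strain SNPs")
    idx = rng.choice(len(candidates), size=config.n_strain_snps, replace=False)
    snps = []
    for i in sorted(idx.tolist()):
        g, fwd = candidates[i]
        ref = genome.sequences[g.contig][fwd]  # A (+) or T (-)
        alt = "G" if g.strand == "+" else "C"
        snps.append(SnpRecord(g.contig, fwd, g.gene_id, ref, alt))
    return snps


# ---------------------------------------------------------------------------
# Read simulation

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def simulate_reads(
    genome: AnnotatedGenome,
    truth: list[TruthRecord],
    config: SimConfig,
    snps: list[SnpRecord] | None = None,
) -> dict[str, list[Read]]:
    """Per-replicate FASTQ-ready reads with binomial per-read editing.

    Reads are drawn uniformly from gene bodies on the transcribed strand
    (or a random strand when unstranded).  Each read overlapping an edited
    A carries G with probability ``designed_level``, independently of every
    other read and replicate; strain SNPs are substituted into all reads;
    sequencing errors are applied after editing.
    """
    config.validate()
    snps = snps or []
    strain = {k: list(v) for k, v in genome.sequences.items()}
    for s in snps:
        strain[s.contig][s.position] = s.alt
    strain_seq = {k: "".join(v) for k, v in strain.items()}

    sites_by_gene: dict[str, list[TruthRecord]] = {}
    for t in truth:
        sites_by_gene.setdefault(t.gene_id, []).append(t)

    rl = config.read_length
    out: dict[str, list[Read]] = {}
    for rep in range(config.n_replicates):
        rng = _rng(config, 10 + rep)
        sample = f"rep{rep + 1}"
        reads: list[Read] = []
        for g in genome.genes:
            if g.length < rl:
                continue
            span = g.length - rl + 1
            n_reads = int(round(config.mean_coverage * span / rl))
            starts = rng.integers(g.start, g.start + span, size=n_reads)
            for j, start in enumerate(starts.tolist()):
                fwd = strain_seq[g.contig][start : start + rl]
                coding = fwd if g.strand == "+" else revcomp(fwd)
                bases = list(coding)
                for t in sites_by_gene.get(g.gene_id, ()):
                    if start <= t.position < start + rl:
                        if rng.random() < t.designed_level:
                            idx = (t.position - start if g.strand == "+"
                                   else start + rl - 1 - t.position)
                            bases[idx] = "G"  # coding-strand A -> G
                if config.error_rate > 0:
                    err = np.flatnonzero(rng.random(rl) < config.error_rate)
                    for i in err.tolist():
                        shift = int(rng.integers(1, 4))
                        bases[i] = "ACGT"[(_BASE_IDX[bases[i]] + shift) % 4]
                seq = "".join(bases)
                if not config.stranded and rng.random() < 0.5:
                    seq = revcomp(seq)
                quals = np.full(rl, config.base_quality, dtype=np.int16)
                if config.low_quality_tail:
                    quals[-config.low_quality_tail :] = 2
                # wgsim-style id encodes the origin so truth checks need no mapping
                reads.append(Read(f"{sample}:{g.gene_id}:{start}:{j}", seq, quals))
        out[sample] = reads
    return out


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full generator run: genome -> planted sites -> SNPs -> reads."""
    genome = generate_genome(config)
    genome, truth = plant_editing_sites(genome, config)
    snps = place_strain_snps(genome, truth, config) if config.n_strain_snps else []
    reads = simulate_reads(genome, truth, config, snps)
    return SimulatedDataset(config, genome, truth, snps, reads)


# ---------------------------------------------------------------------------
# On-disk output


def write_truth_table(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos_1based\tstrand\tgene_id\tlevel\tcontext7\tin_hairpin\n")
        for t in truth:
            fh.write(
                f"{t.contig}\t{t.position + 1}\t{t.gene_strand}\t{t.gene_id}"
                f"\t{t.designed_level:.6g}\t{t.context7}\t{int(t.in_hairpin)}\n"
            )


def write_snp_table(snps: list[SnpRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos_1based\tgene_id\tref\talt\n")
        for s in snps:
            fh.write(f"{s.contig}\t{s.position + 1}\t{s.gene_id}\t{s.ref}\t{s.alt}\n")


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.genome.write_fasta(outdir / "genome.fasta")
    ds.genome.write_gff3(outdir / "genes.gff3")
    write_truth_table(ds.truth, outdir / "truth.tsv")
    write_snp_table(ds.snps, outdir / "strain_snps.tsv")
    for sample, reads in ds.reads.items():
        write_fastq(reads, outdir / f"{sample}.fastq")
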