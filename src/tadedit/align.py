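"""Read trimming, a built-in ungapped mapper, and SAM pass-through.

Trimming follows the modified-Mott error-probability criterion: with
per-base error probability p_i = 10^(-Q_i/10), each base scores
(limit - p_i) and the retained segment is the maximal-sum contiguous run.
Reads with more than ``max_ambiguous`` N's or shorter than ``min_length``
after trimming are dropped.

The built-in mapper is a seed-and-extend scan for the simulator's
indel-free reads: exact 14-mer seeds sampled every 2 bases guarantee (by
pigeonhole over mismatch runs) that every full-length placement at >=95%
identity of a read >=50 nt contains a clean sampled seed, so the reported
placements equal a brute-force scan over all (position, strand) pairs.
Reads with two or more equal-best placements are discarded entirely
(nonspecific-match handling "ignore").  Gapped alignments enter only via
the SAM pass-through for externally aligned data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .io import AnnotatedGenome, Read, revcomp

SEED_K = 14
SEED_STRIDE = 2


@dataclass
class Alignment:
    """An aligned read in reference orientation.

    ``seq``/``quals`` are the read bases written along the forward
    reference strand (reverse-complemented for minus-strand placements).
    ``ref_positions`` is None for contiguous (ungapped) alignments, else an
    explicit per-column array of 0-based reference positions.
    """

    read_id: str
    contig: str
    start: int  # 0-based leftmost
    end: int  # exclusive rightmost
    strand: str
    aligned_fraction: float
    identity: float
    seq: str
    quals: np.ndarray
    ref_positions: np.ndarray | None = None

    def columns(self):
        """Yield (ref_pos, read_base, read_qual) per aligned column."""
        pos = (range(self.start, self.end) if self.ref_positions is None
               else self.ref_positions)
        for p, b, q in zip(pos, self.seq, self.quals):
            yield int(p), b, int(q)


# ---------------------------------------------------------------------------
# Trimming


def trim_read(read: Read, quality_limit: float = 0.05,
              max_ambiguous: int = 2, min_length: int = 50) -> Read | None:
    """Modified-Mott trim of one read; None if it should be dropped."""
    p = np.power(10.0, -read.qualities / 10.0)
    score = quality_limit - p
    # maximal-sum contiguous subsegment (leftmost maximal run)
    best, best_lo, best_hi = 0.0, 0, 0
    run, lo = 0.0, 0
    for i, s in enumerate(score):
        run += s
        if run <= 0:
            run, lo = 0.0, i + 1
        elif run > best:
            best, best_lo, best_hi = run, lo, i + 1
    if best_hi - best_lo < min_length:
        return None
    seq = read.sequence[best_lo:best_hi]
    if seq.count("N") > max_ambiguous:
        return None
    return Read(read.id, seq, read.qualities[best_lo:best_hi])


def trim_reads(reads, quality_limit: float = 0.05,
               max_ambiguous: int = 2, min_length: int = 50) -> list[Read]:
    out = []
    for r in reads:
        t = trim_read(r, quality_limit, max_ambiguous, min_length)
        if t is not None:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# Built-in mapper

_ENC = np.zeros(256, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
_ENC[ord("N")] = 4


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


class GenomeIndex:
    """Exact k-mer seed table over the forward strand of every contig."""

    def __init__(self, genome: AnnotatedGenome, k: int = SEED_K):
        self.genome = genome
        self.k = k
        self.encoded = {name: _encode(seq) for name, seq in genome.sequences.items()}
        self.table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                self.table.setdefault(seq[i : i + k], []).append((name, i))

    def candidates(self, seq: str, stride: int = SEED_STRIDE):
        """Candidate (contig, read_offset->ref) placements for one strand."""
        k = self.k
        hits = set()
        offsets = list(range(0, len(seq) - k + 1, stride))
        if offsets and offsets[-1] != len(seq) - k:
            offsets.append(len(seq) - k)
        for off in offsets:
            for contig, pos in self.table.get(seq[off : off + k], ()):
                hits.add((contig, pos - off))
        return hits


def map_read(read: Read, index: GenomeIndex,
             length_fraction: float = 0.95,
             similarity_fraction: float = 0.95) -> Alignment | None:
    """Best full-length ungapped placement, or None (unmapped/nonspecific)."""
    L = len(read)
    if L < index.k:
        return None
    oriented = {
        "+": (read.sequence, read.qualities),
        "-": (revcomp(read.sequence), read.qualities[::-1]),
    }
    placements = []
    best = -1
    for strand, (seq, quals) in oriented.items():
        enc = _encode(seq)
        for contig, start in index.candidates(seq):
            ref = index.encoded[contig]
            if start < 0 or start + L > len(ref):
                continue  # overhanging placements are not reported
            matches = int(np.count_nonzero(ref[start : start + L] == enc))
            if matches / L < similarity_fraction:
                continue
            # aligned_fraction is 1.0 by construction (full-length ungapped)
            placements.append((matches, contig, start, strand, seq, quals))
            best = max(best, matches)
    top = [p for p in placements if p[0] == best]
    if len(top) != 1:
        return None  # unmapped, or equal-best ties -> "ignore"
    matches, contig, start, strand, seq, quals = top[0]
    return Alignment(
        read_id=read.id, contig=contig, start=start, end=start + L,
        strand=strand, aligned_fraction=1.0, identity=matches / L,
        seq=seq, quals=np.asarray(quals),
    )


def map_reads(reads, genome: AnnotatedGenome,
              length_fraction: float = 0.95,
              similarity_fraction: float = 0.95,
              index: GenomeIndex | None = None) -> list[Alignment]:
    if not genome.sequences or all(len(s) == 0 for s in genome.sequences.values()):
        raise ValueError("empty genome")
    index = index or GenomeIndex(genome)
    out = []
    for r in reads:
        a = map_read(r, index, length_fraction, similarity_fraction)
        if a is not None:
            out.append(a)
    return out


def sample_qc(n_mapped: int, n_input_reads: int,
              min_mapped_fraction: float = 0.5) -> tuple[bool, float]:
    """Mapped-fraction QC gate; >= is inclusive ('at least 50%')."""
    if n_input_reads <= 0:
        raise ValueError("n_input_reads must be positive")
    frac = n_mapped / n_input_reads
    return frac >= min_mapped_fraction, frac


# ---------------------------------------------------------------------------
# SAM


def write_sam(alignments, genome: AnnotatedGenome, path) -> None:
    """Write ungapped alignments as plain-text SAM (CIGAR <len>M)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genome.sequences.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            qual = "".join(chr(int(q) + 33) for q in a.quals)
            fh.write(
                f"{a.read_id}\t{flag}\t{a.contig}\t{a.start + 1}\t60"
                f"\t{len(a.seq)}M\t*\t0\t0\t{a.seq}\t{qual}\n"
            )


def read_sam(path, genome: AnnotatedGenome) -> list[Alignment]:
    """Ingest externally aligned reads from a (headered) SAM file.

    Identity is recomputed against the supplied genome over aligned
    columns; insertions/soft-clips reduce ``aligned_fraction``, deleted
    reference bases contribute no columns.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            contig = rec.reference_name
            if contig not in genome.sequences:
                raise ValueError(f"alignment references unknown contig {contig}")
            seq = rec.query_sequence.upper()
            quals = (np.array(rec.query_qualities, dtype=np.int16)
                     if rec.query_qualities is not None
                     else np.full(len(seq), 30, dtype=np.int16))
            pairs = [(q, r) for q, r in rec.get_aligned_pairs()
                     if q is not None and r is not None]
            if not pairs:
                continue
            ref = genome.sequences[contig]
            bases = "".join(seq[q] for q, _ in pairs)
            ref_pos = np.array([r for _, r in pairs])
            matches = sum(b == ref[r] for b, (_, r) in zip(bases, pairs))
            contiguous = bool(np.all(np.diff(ref_pos) == 1)) and len(pairs) == len(seq)
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    contig=contig,
                    start=int(ref_pos[0]),
                    end=int(ref_pos[-1]) + 1,
                    strand="-" if rec.is_reverse else "+",
                    aligned_fraction=len(pairs) / len(seq),
                    identity=matches / len(pairs),
                    seq=bases,
                    quals=np.array([quals[q] for q, _ in pairs], dtype=np.int16),
                    ref_positions=None if contiguous else ref_pos,
                )
            )
    return out
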