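"""Flat-file formats and core sequence containers.

The pipeline exchanges data through plain-text standards only: FASTA for
genomes, GFF3 for gene features, FASTQ (Phred+33) for reads, SAM for
externally aligned reads, and TSV for variant/site tables.  FASTA/FASTQ go
through Biopython; GFF3 features (flat lists of CDS/tRNA/rRNA intervals,
which is all a bacterial annotation needs here) are parsed directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTNRYacgtnry", "TGCANYRtgcanyr")

GENE_FEATURE_TYPES = ("CDS", "tRNA", "rRNA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC Y/R aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A typed gene feature on a contig.

    Coordinates are 0-based, end-exclusive, on the forward strand.
    ``feature_type`` is one of CDS / tRNA / rRNA.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad coordinates for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: np.ndarray  # int array, same length as sequence

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


class AnnotatedGenome:
    """Reference sequences plus typed gene features.

    This is the coordinate frame for everything downstream: variant
    positions, editing-site contexts and fold windows are all expressed
    against these forward-strand sequences, with gene strand deciding the
    coding orientation.
    """

    def __init__(self, sequences: dict[str, str], genes: Iterable[Gene] = ()):
        self.sequences = {name: str(seq).upper() for name, seq in sequences.items()}
        self.genes: list[Gene] = list(genes)
        for g in self.genes:
            if g.contig not in self.sequences:
                raise ValueError(f"gene {g.gene_id} on unknown contig {g.contig}")
            if g.end > len(self.sequences[g.contig]):
                raise ValueError(f"gene {g.gene_id} extends past contig end")
        self._trees: dict[str, IntervalTree] | None = None

    # -- lookups ---------------------------------------------------------

    def _tree(self, contig: str) -> IntervalTree:
        if self._trees is None:
            self._trees = {}
            for g in self.genes:
                self._trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)
        return self._trees.get(contig, IntervalTree())

    def genes_at(self, contig: str, position: int) -> list[Gene]:
        """All gene features overlapping a 0-based position."""
        return sorted(
            (iv.data for iv in self._tree(contig)[position]),
            key=lambda g: (g.start, g.gene_id),
        )

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def slice(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Forward-strand slice, reverse-complemented when strand is '-'."""
        s = self.sequences[contig][max(start, 0) : end]
        return revcomp(s) if strand == "-" else s

    def coding_sequence(self, gene: Gene) -> str:
        return self.slice(gene.contig, gene.start, gene.end, gene.strand)

    def with_sequences(self, sequences: dict[str, str]) -> "AnnotatedGenome":
        """Copy carrying replacement sequences (same annotations)."""
        return AnnotatedGenome(sequences, self.genes)

    # -- FASTA -----------------------------------------------------------

    @classmethod
    def from_files(cls, fasta_path, gff_path=None) -> "AnnotatedGenome":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        genes = read_gff3(gff_path) if gff_path else []
        return cls(sequences, genes)

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path) -> None:
        write_gff3(self.genes, path)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[Gene]:
    """Parse CDS/tRNA/rRNA features from a GFF3 file.

    Only the fields the pipeline uses are retained (type, coordinates,
    strand, ID attribute); other feature types and attributes are ignored.
    """
    genes: list[Gene] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in GENE_FEATURE_TYPES:
                continue
            gene_id = None
            for item in attrs.split(";"):
                key, _, value = item.partition("=")
                if key.strip() == "ID":
                    gene_id = value.strip()
            if gene_id is None:
                raise ValueError(f"GFF3 feature without ID attribute: {line!r}")
            genes.append(Gene(gene_id, contig, int(start) - 1, int(end), strand, ftype))
    return genes


def write_gff3(genes: Iterable[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            phase = "0" if g.feature_type == "CDS" else "."
            fh.write(
                f"{g.contig}\ttadedit\t{g.feature_type}\t{g.start + 1}\t{g.end}"
                f"\t.\t{g.strand}\t{phase}\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path) -> list[Read]:
    """Read a Phred+33 FASTQ file into Read objects.

    A malformed record raises a parse error naming the offending record.
    """
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                Read(rec.id, str(rec.seq).upper(),
                     np.array(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as exc:
        last = reads[-1].id if reads else "<first record>"
        raise ValueError(f"malformed FASTQ record after {last}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def iter_fastq(path) -> Iterator[Read]:
    yield from read_fastq(path)
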