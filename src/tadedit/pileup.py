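"""Quality-filtered pileups and initial variant calling.

A read base contributes to a position only if its own quality passes the
central threshold AND every base within ``neighborhood_radius`` positions
on the read (truncated at read boundaries) passes the neighborhood
threshold.  Coverage counts qualified bases only, so the reported variant
frequency (100 x count / coverage) doubles as the editing level.

Calls are substitution-only: one call per (position, alt base) with
coverage in [min_coverage, max_coverage], alt count >= min_count and
frequency >= min_frequency_pct.  Per-allele unique start/end coordinate
counts (PCR/positional-artifact guards) and the number of alleles observed
at min_count support accompany each call for the downstream cascade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .align import Alignment
from .io import AnnotatedGenome

_BASES = "ACGT"
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i

CALL_COLUMNS = [
    "contig", "pos", "ref", "alt", "count", "coverage", "freq_pct",
    "unique_starts", "unique_ends", "n_alleles",
    "count_fwd", "count_rev", "cov_fwd", "cov_rev", "sample_id",
]


@dataclass
class SitePileup:
    """Per-position allele counts after quality filtering."""

    contig: str
    position: int
    ref_base: str
    counts: dict[str, int]
    coverage: int
    counts_fwd: dict[str, int]
    counts_rev: dict[str, int]
    unique_starts: dict[str, int]  # non-reference alleles only
    unique_ends: dict[str, int]


class Pileups:
    """Dense qualified base counts per contig, plus mismatch provenance.

    ``counts[contig]`` has shape (2 strands, 4 bases, contig length).
    Start/end coordinates of supporting reads are tracked for mismatch
    bases only (that is all the uniqueness filters consume).
    """

    def __init__(self, genome: AnnotatedGenome):
        self.genome = genome
        self.counts = {
            name: np.zeros((2, 4, len(seq)), dtype=np.int32)
            for name, seq in genome.sequences.items()
        }
        self._ref = {name: _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
                     for name, seq in genome.sequences.items()}
        self.mismatches = pd.DataFrame(
            columns=["contig", "pos", "base", "start", "end", "strand"]
        )

    def coverage(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=(0, 1))

    def base_counts(self, contig: str) -> np.ndarray:
        """(4, L) qualified counts summed over strands."""
        return self.counts[contig].sum(axis=0)

    def at(self, contig: str, position: int) -> SitePileup:
        c = self.counts[contig][:, :, position]
        mm = self.mismatches
        mm = mm[(mm["contig"] == contig) & (mm["pos"] == position)]
        ustarts = mm.groupby("base")["start"].nunique().to_dict()
        uends = mm.groupby("base")["end"].nunique().to_dict()
        return SitePileup(
            contig=contig,
            position=position,
            ref_base=self.genome.sequences[contig][position],
            counts={b: int(c[:, i].sum()) for i, b in enumerate(_BASES)},
            coverage=int(c.sum()),
            counts_fwd={b: int(c[0, i]) for i, b in enumerate(_BASES)},
            counts_rev={b: int(c[1, i]) for i, b in enumerate(_BASES)},
            unique_starts=ustarts,
            unique_ends=uends,
        )

    def allele_level(self, contig: str, position: int, allele: str,
                     strand: str | None = None) -> tuple[int, int]:
        """(allele count, coverage) at a position, optionally one strand."""
        c = self.counts[contig][:, :, position]
        if strand is None:
            return int(c[:, _BASES.index(allele)].sum()), int(c.sum())
        s = 0 if strand == "+" else 1
        return int(c[s, _BASES.index(allele)]), int(c[s].sum())


def build_pileup(
    alignments: list[Alignment],
    genome: AnnotatedGenome,
    neighborhood_radius: int = 2,
    min_central_quality: int = 30,
    min_neighborhood_quality: int = 30,
) -> Pileups:
    """Accumulate qualified bases from alignments into per-contig counts."""
    piles = Pileups(genome)
    mm_rows = {k: [] for k in ("contig", "pos", "base", "start", "end", "strand")}
    size = 2 * neighborhood_radius + 1
    for a in alignments:
        if a.contig not in piles.counts:
            raise ValueError(f"alignment references unknown contig {a.contig}")
        quals = np.asarray(a.quals, dtype=np.int16)
        # min over the read-local neighborhood, truncated at boundaries
        neigh = minimum_filter1d(quals, size=size, mode="constant", cval=np.int16(127))
        codes = _ENC[np.frombuffer(a.seq.encode(), dtype=np.uint8)]
        ok = (quals >= min_central_quality) & (neigh >= min_neighborhood_quality) \
            & (codes < 4)
        pos = (np.arange(a.start, a.end) if a.ref_positions is None
               else np.asarray(a.ref_positions))
        sidx = 0 if a.strand == "+" else 1
        np.add.at(piles.counts[a.contig][sidx], (codes[ok], pos[ok]), 1)
        ref = piles._ref[a.contig]
        mm = ok & (codes != ref[pos])
        if mm.any():
            n = int(mm.sum())
            mm_rows["contig"].extend([a.contig] * n)
            mm_rows["pos"].extend(pos[mm].tolist())
            mm_rows["base"].extend(_BASES[c] for c in codes[mm])
            mm_rows["start"].extend([a.start] * n)
            mm_rows["end"].extend([a.end] * n)
            mm_rows["strand"].extend([a.strand] * n)
    piles.mismatches = pd.DataFrame(mm_rows)
    return piles


def call_variants(
    piles: Pileups,
    min_coverage: int = 20,
    min_count: int = 3,
    min_frequency_pct: float = 1.0,
    max_coverage: float = 1_000_000,
    sample_id: str = "",
) -> pd.DataFrame:
    """Initial variant calls from a pileup; one row per (position, alt)."""
    rows = []
    for contig in piles.counts:
        counts = piles.base_counts(contig)  # (4, L)
        cov = counts.sum(axis=0)
        ref = piles._ref[contig]
        usable = (cov >= min_coverage) & (cov <= max_coverage)
        alt_any = (counts >= min_count) & usable[None, :]
        alt_any[ref[None, :] == np.arange(4)[:, None]] = False
        cand = np.flatnonzero(alt_any.any(axis=0))
        if len(cand) == 0:
            continue
        mm = piles.mismatches
        mm = mm[mm["contig"] == contig]
        grouped = mm.groupby(["pos", "base"]).agg(
            ustarts=("start", "nunique"), uends=("end", "nunique")
        )
        per_strand = piles.counts[contig]
        for p in cand.tolist():
            n_alleles = int((counts[:, p] >= min_count).sum())
            for b in np.flatnonzero(alt_any[:, p]).tolist():
                count = int(counts[b, p])
                freq = 100.0 * count / cov[p]
                if freq < min_frequency_pct:
                    continue
                base = _BASES[b]
                try:
                    u = grouped.loc[(p, base)]
                    ustarts, uends = int(u["ustarts"]), int(u["uends"])
                except KeyError:
                    ustarts = uends = 0
                rows.append({
                    "contig": contig, "pos": p, "ref": _BASES[ref[p]],
                    "alt": base, "count": count, "coverage": int(cov[p]),
                    "freq_pct": freq, "unique_starts": ustarts,
                    "unique_ends": uends, "n_alleles": n_alleles,
                    "count_fwd": int(per_strand[0, b, p]),
                    "count_rev": int(per_strand[1, b, p]),
                    "cov_fwd": int(per_strand[0, :, p].sum()),
                    "cov_rev": int(per_strand[1, :, p].sum()),
                    "sample_id": sample_id,
                })
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out.insert(1, "POS", out.pop("pos") + 1)
    out.rename(
        columns={"contig": "CHROM", "ref": "REF", "alt": "ALT", "count": "COUNT",
                 "coverage": "COV", "freq_pct": "FREQ_PCT",
                 "unique_starts": "USTARTS", "unique_ends": "UENDS",
                 "sample_id": "SAMPLE"},
        inplace=True,
    )
    out.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df.pop("POS") - 1
    df.rename(
        columns={"CHROM": "contig", "REF": "ref", "ALT": "alt", "COUNT": "count",
                 "COV": "coverage", "FREQ_PCT": "freq_pct",
                 "USTARTS": "unique_starts", "UENDS": "unique_ends",
                 "SAMPLE": "sample_id"},
        inplace=True,
    )
    return df
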