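"""End-to-end convenience: FASTQ/SAM samples -> final editing-site table."""

from __future__ import annotations

import logging

import pandas as pd

from .align import GenomeIndex, map_reads, read_sam, sample_qc, trim_reads
from .discovery import (DiscoveryProfile, CROSS_SPECIES, EditingSite,
                        run_discovery, sites_table)
from .io import AnnotatedGenome, Read
from .pileup import Pileups, build_pileup, call_variants

logger = logging.getLogger(__name__)


def align_sample(reads: list[Read], genome: AnnotatedGenome,
                 index: GenomeIndex | None = None,
                 min_mapped_fraction: float = 0.5):
    """Trim, map and QC one sample; returns alignments or None on QC fail."""
    trimmed = trim_reads(reads)
    alignments = map_reads(trimmed, genome, index=index)
    ok, frac = sample_qc(len(alignments), len(reads),
                         min_mapped_fraction=min_mapped_fraction)
    logger.info("sample QC: %.1f%% of input reads mapped (%s)",
                100 * frac, "pass" if ok else "FAIL")
    return alignments if ok else None


def discover(
    genome: AnnotatedGenome,
    reads_by_sample: dict[str, list[Read]] | None = None,
    alignments_by_sample: dict[str, list] | None = None,
    profile: DiscoveryProfile = CROSS_SPECIES,
    experiments: dict[str, str] | None = None,
    dna_variants=None,
) -> tuple[list[EditingSite], pd.DataFrame, dict[str, Pileups]]:
    """Full discovery cascade from reads (or pre-aligned samples).

    Samples failing the >=50%-mapped QC gate are excluded from all
    downstream stages.  Returns the site objects, the final table and the
    per-sample pileups (for rescue re-use by callers).
    """
    if alignments_by_sample is None:
        if reads_by_sample is None:
            raise ValueError("need reads_by_sample or alignments_by_sample")
        index = GenomeIndex(genome)
        alignments_by_sample = {}
        for sample, reads in reads_by_sample.items():
            aln = align_sample(reads, genome, index=index)
            if aln is None:
                logger.warning("sample %s failed mapping QC; excluded", sample)
                continue
            alignments_by_sample[sample] = aln

    pileups = {s: build_pileup(a, genome) for s, a in alignments_by_sample.items()}
    calls = {s: call_variants(p, sample_id=s) for s, p in pileups.items()}
    sites = run_discovery(genome, calls, pileups, profile=profile,
                          experiments=experiments, dna_variants=dna_variants)
    return sites, sites_table(sites), pileups
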