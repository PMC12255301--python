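"""Post-call filter cascade producing the final editing-site table.

Order of operations (mirroring the discovery pipeline):

1. per-sample variant filtering (uniqueness, frequency band, allele count)
2. replicate intersection within each experiment (all, or at-least-k)
3. union of surviving keys across experiments
4. orientation to the coding strand and restriction to annotated genes
   (forward T>C inside a minus-strand gene becomes a coding-strand A>G;
   everything that is not A>G on the coding strand is dropped)
5. optional strand-specific support filter (stranded libraries)
6. optional subtraction of DNA-seq variants
7. frequency rescue: for every final site and every sample, the editing
   level (percent) and coverage are re-extracted from the pileups with no
   count/uniqueness thresholds, so samples where the variant fell below
   the calling thresholds still report their observed sub-threshold level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AnnotatedGenome, Gene
from .pileup import Pileups

logger = logging.getLogger(__name__)

RNA_CLASS = {"CDS": "mRNA", "tRNA": "tRNA", "rRNA": "rRNA"}


@dataclass(frozen=True)
class DiscoveryProfile:
    """Thresholds and switches of the filter cascade."""

    min_unique_starts: int = 3
    min_unique_ends: int = 3
    min_freq_pct: float = 5.0
    max_freq_pct: float = 98.0
    max_alleles: int = 2
    replicate_rule: tuple = ("all",)  # or ("at_least_k", k)
    restrict_to_genes: bool = True
    stranded_filtering: bool = False
    dna_variant_subtraction: bool = False

    def __post_init__(self):
        if not 0 < self.min_freq_pct < self.max_freq_pct <= 100:
            raise ValueError("need 0 < min_freq_pct < max_freq_pct <= 100")


#: Cross-species screen: >=5% level, shared by all replicates.
CROSS_SPECIES = DiscoveryProfile()

#: A. baylyi strain comparison: >=1% level, 3-of-4 replicates,
#: strand-specific filtering and DNA-variant subtraction.
ABAYLYI = DiscoveryProfile(
    min_freq_pct=1.0,
    replicate_rule=("at_least_k", 3),
    stranded_filtering=True,
    dna_variant_subtraction=True,
)

PROFILES = {"cross_species": CROSS_SPECIES, "abaylyi": ABAYLYI}


@dataclass
class EditingSite:
    """An oriented A>G editing site on a gene's coding strand."""

    contig: str
    position: int  # 0-based forward-strand coordinate of the edited A
    gene_id: str
    gene_strand: str
    rna_class: str
    context21: str  # coding strand, edited A at center (index 10)
    context7: str  # context21[8:15]
    per_sample_levels: dict[str, float | None] = field(default_factory=dict)
    per_sample_coverage: dict[str, int] = field(default_factory=dict)

    @property
    def forward_alt(self) -> str:
        """The alt base as seen on the forward genome strand."""
        return "G" if self.gene_strand == "+" else "C"

    def mean_level(self) -> float:
        vals = [v for v in self.per_sample_levels.values() if v is not None]
        return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Cascade stages


def filter_variants(calls: pd.DataFrame, profile: DiscoveryProfile) -> pd.DataFrame:
    """Uniqueness / frequency-band / hyper-allelic filters (all inclusive)."""
    if calls.empty:
        return calls
    mask = (
        (calls["unique_starts"] >= profile.min_unique_starts)
        & (calls["unique_ends"] >= profile.min_unique_ends)
        & (calls["freq_pct"] >= profile.min_freq_pct)
        & (calls["freq_pct"] <= profile.max_freq_pct)
        & (calls["n_alleles"] <= profile.max_alleles)
    )
    return calls[mask].reset_index(drop=True)


def intersect_replicates(
    per_sample_calls: dict[str, pd.DataFrame], rule: tuple = ("all",)
) -> set[tuple]:
    """(contig, pos, ref, alt) keys present in enough replicates."""
    n = len(per_sample_calls)
    if n < 2:
        raise ValueError("replicate intersection needs >=2 samples per experiment")
    if rule[0] == "all":
        needed = n
    elif rule[0] == "at_least_k":
        needed = int(rule[1])
        if needed > n:
            raise ValueError(f"at_least_k={needed} exceeds {n} samples")
    else:
        raise ValueError(f"unknown replicate rule {rule!r}")
    tally: dict[tuple, int] = {}
    for calls in per_sample_calls.values():
        keys = set(zip(calls["contig"], calls["pos"], calls["ref"], calls["alt"]))
        for k in keys:
            tally[k] = tally.get(k, 0) + 1
    return {k for k, c in tally.items() if c >= needed}


def orient_and_restrict(
    keys: set[tuple], genome: AnnotatedGenome
) -> list[EditingSite]:
    """Keep in-gene keys that are A>G on the coding strand; build sites."""
    sites = []
    for contig, pos, ref, alt in sorted(keys):
        genes = genome.genes_at(contig, pos)
        if not genes:
            continue
        strands = {g.strand for g in genes}
        if len(strands) > 1:
            logger.warning(
                "site %s:%d inside overlapping genes on both strands; dropped",
                contig, pos + 1,
            )
            continue
        gene = genes[0]
        if gene.strand == "+" and (ref, alt) != ("A", "G"):
            continue
        if gene.strand == "-" and (ref, alt) != ("T", "C"):
            continue
        if pos - 10 < 0 or pos + 11 > len(genome.sequences[contig]):
            logger.warning("site %s:%d too close to contig end; dropped",
                           contig, pos + 1)
            continue
        context21 = genome.slice(contig, pos - 10, pos + 11, gene.strand)
        sites.append(
            EditingSite(
                contig=contig,
                position=pos,
                gene_id=gene.gene_id,
                gene_strand=gene.strand,
                rna_class=RNA_CLASS.get(gene.feature_type, "mRNA"),
                context21=context21,
                context7=context21[8:15],
            )
        )
    return sites


def stranded_filter(
    sites: list[EditingSite], pileups_by_sample: dict[str, Pileups],
    library_stranded: bool = True,
) -> list[EditingSite]:
    """Keep sites whose alt support comes from sense-strand reads.

    In a stranded single-end library a read's alignment strand is the
    transcriptional strand, so alt reads must align on the host gene's
    strand.  Sites with zero sense-strand alt support across all samples
    are dropped; level re-extraction afterwards counts sense reads only.
    """
    if not library_stranded:
        raise ValueError("stranded_filtering requires a stranded library")
    kept = []
    for s in sites:
        sense = 0
        for piles in pileups_by_sample.values():
            cnt, _ = piles.allele_level(s.contig, s.position, s.forward_alt,
                                        strand=s.gene_strand)
            sense += cnt
        if sense > 0:
            kept.append(s)
        else:
            logger.info("site %s:%d has antisense-only support; dropped",
                        s.contig, s.position + 1)
    return kept


def subtract_dna_variants(
    sites: list[EditingSite], dna_variants
) -> list[EditingSite]:
    """Remove sites matching a DNA-seq variant (contig, 0-based pos, alt)."""
    dna = {(c, int(p), a) for c, p, a in dna_variants}
    return [s for s in sites if (s.contig, s.position, s.forward_alt) not in dna]


def rescue_frequencies(
    sites: list[EditingSite],
    pileups_by_sample: dict[str, Pileups],
    stranded: bool = False,
    floor_pct: float = 1.0,
) -> list[EditingSite]:
    """Fill per-sample levels/coverage with no thresholds applied.

    Samples with zero qualified coverage report a missing level (None),
    never zero.  Levels below ``floor_pct`` are reported as observed (the
    flag lives in the output table, not the value).
    """
    for s in sites:
        for sample, piles in pileups_by_sample.items():
            strand = s.gene_strand if stranded else None
            cnt, cov = piles.allele_level(s.contig, s.position, s.forward_alt,
                                          strand=strand)
            s.per_sample_coverage[sample] = cov
            s.per_sample_levels[sample] = (100.0 * cnt / cov) if cov > 0 else None
    return sites


# ---------------------------------------------------------------------------
# End-to-end cascade


def run_discovery(
    genome: AnnotatedGenome,
    per_sample_calls: dict[str, pd.DataFrame],
    pileups_by_sample: dict[str, Pileups],
    profile: DiscoveryProfile = CROSS_SPECIES,
    experiments: dict[str, str] | None = None,
    dna_variants=None,
) -> list[EditingSite]:
    """Filter cascade from per-sample calls to the final site list.

    ``experiments`` maps sample -> experiment id; replicate intersection
    runs within each experiment and surviving keys are unioned across
    experiments.  All samples contribute to the level rescue.
    """
    experiments = experiments or {s: "exp1" for s in per_sample_calls}
    filtered = {s: filter_variants(c, profile) for s, c in per_sample_calls.items()}

    keys: set[tuple] = set()
    for exp in sorted(set(experiments.values())):
        group = {s: filtered[s] for s, e in experiments.items() if e == exp}
        keys |= intersect_replicates(group, profile.replicate_rule)

    sites = orient_and_restrict(keys, genome) if profile.restrict_to_genes else []
    if profile.stranded_filtering:
        sites = stranded_filter(sites, pileups_by_sample)
    if profile.dna_variant_subtraction and dna_variants is not None:
        sites = subtract_dna_variants(sites, dna_variants)
    return rescue_frequencies(sites, pileups_by_sample,
                              stranded=profile.stranded_filtering)


def sites_table(sites: list[EditingSite]) -> pd.DataFrame:
    """Final site table: one LEVEL_<sample> column per sample."""
    samples = sorted({s for site in sites for s in site.per_sample_levels})
    rows = []
    for s in sites:
        row = {
            "CHROM": s.contig, "POS": s.position + 1, "GENE": s.gene_id,
            "STRAND": s.gene_strand, "RNA_CLASS": s.rna_class,
            "CONTEXT21": s.context21, "CONTEXT7": s.context7,
        }
        for sample in samples:
            v = s.per_sample_levels.get(sample)
            row[f"LEVEL_{sample}"] = np.nan if v is None else v
        rows.append(row)
    cols = ["CHROM", "POS", "GENE", "STRAND", "RNA_CLASS", "CONTEXT21", "CONTEXT7"]
    cols += [f"LEVEL_{s}" for s in samples]
    return pd.DataFrame(rows, columns=cols)


def read_dna_variants(path) -> list[tuple]:
    """DNA-seq variant TSV (contig, pos_1based, ref, alt) -> 0-based tuples."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    return [
        (row[cols["contig"]], int(row[cols["pos_1based"]]) - 1, row[cols["alt"]])
        for _, row in df.iterrows()
    ]
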