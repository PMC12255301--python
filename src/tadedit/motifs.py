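"""Motif enrichment, 7-mer classification, logo matrix, codon recoding.

The motif statistic compares the observed distribution of the 4-mer
(-1, A, +1, +2) around edited adenosines against a genome-sampled null:
for each species, the frequency of every X A Y Z 4-mer over both strands
of its genome, combined across species weighted by that species' site
count.  Enrichment is a chi-square goodness-of-fit test over the 64
categories (df = 63).

The 7-base consensus YTACGAA (Y = C or T, edited A at position 3) is the
deaminase recognition motif; sites are classed by Hamming distance to it.
Recoding effects come from translating the reference and A->G-edited
codons with the bacterial genetic code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .discovery import EditingSite
from .io import AnnotatedGenome, Gene, revcomp

CONSENSUS7 = "YTACGAA"
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "Y": "CT", "R": "AG", "N": "ACGT"}

FOURMERS = ["".join(x) for x in itertools.product("ACGT", "A", "ACGT", "ACGT")]


@dataclass(frozen=True)
class SevenMerClass:
    context7: str
    hamming_to_consensus: int
    mismatch_offsets: tuple[int, ...]  # 1-based offsets within the 7-mer


@dataclass(frozen=True)
class CodonEffect:
    codon_ref: str
    codon_edited: str
    codon_position: int  # 1 | 2 | 3
    aa_ref: str
    aa_edited: str
    effect: str  # synonymous | nonsynonymous | stop_gain | stop_loss


# ---------------------------------------------------------------------------
# 4-mer observed / expected


def site_fourmer(site: EditingSite) -> str | None:
    """The (-1, A, +1, +2) 4-mer on the coding strand, or None near ends."""
    ctx = site.context21
    mer = ctx[9:13]
    if len(mer) < 4 or any(b not in "ACGT" for b in mer):
        return None
    return mer


def count_observed_motifs(sites: list[EditingSite]) -> pd.Series:
    """Observed counts over the 64 X-A-Y-Z categories."""
    counts = pd.Series(0, index=FOURMERS, dtype=int)
    for s in sites:
        mer = site_fourmer(s)
        if mer is None:
            continue
        counts[mer] += 1
    return counts


def genome_fourmer_frequencies(genome: AnnotatedGenome) -> pd.Series:
    """Frequencies of A-at-offset-1 4-mers over both strands of a genome."""
    counts = pd.Series(0, index=FOURMERS, dtype=int)
    for seq in genome.sequences.values():
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - 3):
                if strand_seq[i + 1] == "A":
                    mer = strand_seq[i : i + 4]
                    if mer in counts.index:
                        counts[mer] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("genome contains no A-centred 4-mers")
    return counts / total


def genomic_motif_null(
    genomes: dict[str, AnnotatedGenome], per_species_site_counts: dict[str, int]
) -> pd.Series:
    """Expected 4-mer counts: sum over species of n_sites x genome freq."""
    expected = pd.Series(0.0, index=FOURMERS)
    for species, n in per_species_site_counts.items():
        if species not in genomes:
            raise ValueError(f"species {species} has sites but no genome")
        expected += n * genome_fourmer_frequencies(genomes[species])
    return expected


def chi_square_gof(
    observed, expected, pool_threshold: float = 1.0
) -> tuple[float, int, float]:
    """Goodness-of-fit statistic sum (O-E)^2/E, df = categories - 1.

    Categories with expected < ``pool_threshold`` are pooled into a rest
    class (df reduced accordingly); whole-genome nulls never trigger this.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed/expected category mismatch")
    small = exp < pool_threshold
    if small.any() and small.sum() < len(exp):
        obs = np.append(obs[~small], obs[small].sum())
        exp = np.append(exp[~small], exp[small].sum())
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# 7-mer classification


def classify_seven_mer(context7: str) -> SevenMerClass:
    """Hamming distance of a 7-mer to the YTACGAA consensus."""
    if len(context7) != 7:
        raise ValueError("context must be exactly 7 bases")
    offsets = []
    for i, (base, cons) in enumerate(zip(context7.upper(), CONSENSUS7)):
        if base not in "ACGT":
            raise ValueError(f"non-ACGT character {base!r} in 7-mer")
        if base not in _IUPAC[cons]:
            offsets.append(i + 1)
    return SevenMerClass(context7.upper(), len(offsets), tuple(offsets))


def seven_mer_summary(sites: list[EditingSite]) -> pd.Series:
    """Fractions of sites at Hamming distance 0 / 1 / >=2 to the consensus."""
    dists = [classify_seven_mer(s.context7).hamming_to_consensus for s in sites]
    n = len(dists)
    return pd.Series({
        "exact": sum(d == 0 for d in dists) / n,
        "one_off": sum(d == 1 for d in dists) / n,
        "two_plus": sum(d >= 2 for d in dists) / n,
    })


# ---------------------------------------------------------------------------
# Position frequency matrix (sequence-logo matrix)


def position_frequency_matrix(contexts21: list[str]) -> pd.DataFrame:
    """PFM over 21-base contexts plus per-position information content.

    IC_i = 2 - H_i - e_n with the small-sample correction
    e_n = 3 / (2 ln2 n); columns A/C/G/T sum to 1 at every position.
    """
    lengths = {len(c) for c in contexts21}
    if lengths != {21}:
        raise ValueError("all contexts must be exactly 21 bases")
    n = len(contexts21)
    counts = np.zeros((21, 4))
    idx = {b: i for i, b in enumerate("ACGT")}
    for ctx in contexts21:
        for i, b in enumerate(ctx.upper()):
            counts[i, idx[b]] += 1
    freqs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(freqs > 0, freqs * np.log2(freqs), 0.0), axis=1)
    e_n = 3.0 / (2.0 * np.log(2) * n)
    ic = 2.0 - h - e_n
    out = pd.DataFrame(freqs, columns=list("ACGT"))
    out["IC"] = ic
    out.index = range(-10, 11)
    out.index.name = "offset"
    return out


# ---------------------------------------------------------------------------
# Codon effects

_TABLE = 11  # bacterial code; identical to the standard code mid-gene


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=_TABLE))


def codon_effect_from_codon(codon: str, in_codon_offset: int) -> CodonEffect:
    """Effect of editing the A at ``in_codon_offset`` (0-based) of a codon."""
    codon = codon.upper()
    if codon[in_codon_offset] != "A":
        raise ValueError(f"codon {codon} has no A at offset {in_codon_offset}")
    edited = codon[:in_codon_offset] + "G" + codon[in_codon_offset + 1 :]
    aa_ref, aa_edited = _translate(codon), _translate(edited)
    if aa_ref == aa_edited:
        effect = "synonymous"
    elif aa_edited == "*":
        effect = "stop_gain"
    elif aa_ref == "*":
        effect = "stop_loss"
    else:
        effect = "nonsynonymous"
    return CodonEffect(codon, edited, in_codon_offset + 1, aa_ref, aa_edited, effect)


def annotate_codon_effect(
    site: EditingSite, genome: AnnotatedGenome
) -> CodonEffect | None:
    """CodonEffect for a CDS site; None for tRNA/rRNA sites."""
    if site.rna_class != "mRNA":
        return None
    gene = genome.gene_by_id(site.gene_id)
    cds = genome.coding_sequence(gene)
    p = (site.position - gene.start if gene.strand == "+"
         else gene.end - 1 - site.position)
    frame = p % 3
    codon = cds[p - frame : p - frame + 3]
    return codon_effect_from_codon(codon, frame)


def codon_effect_table(sites, genome) -> pd.DataFrame:
    rows = []
    for s in sites:
        eff = annotate_codon_effect(s, genome)
        rows.append({
            "CHROM": s.contig, "POS": s.position + 1, "GENE": s.gene_id,
            "RNA_CLASS": s.rna_class,
            "CODON_REF": eff.codon_ref if eff else "",
            "CODON_EDITED": eff.codon_edited if eff else "",
            "CODON_POSITION": eff.codon_position if eff else np.nan,
            "AA_REF": eff.aa_ref if eff else "",
            "AA_EDITED": eff.aa_edited if eff else "",
            "EFFECT": eff.effect if eff else "",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expected codon-position / effect distributions


def tacg_cds_adenosines(genome: AnnotatedGenome):
    """All CDS adenosines in a TACG coding-strand context.

    Yields (gene, cds_offset, codon_position 1-3, CodonEffect).  The null
    conditions on the TACG context because the deaminase requires it.
    """
    for gene in genome.genes:
        if gene.feature_type != "CDS":
            continue
        cds = genome.coding_sequence(gene)
        i = cds.find("TACG")
        while i != -1:
            p = i + 1  # the A of TACG
            frame = p % 3
            codon = cds[p - frame : p - frame + 3]
            if len(codon) == 3:
                yield gene, p, frame + 1, codon_effect_from_codon(codon, frame)
            i = cds.find("TACG", i + 1)


def codon_expected_distributions(
    genomes: dict[str, AnnotatedGenome],
    per_species_site_counts: dict[str, int],
) -> tuple[pd.Series, pd.Series]:
    """Expected codon-position and effect counts under the TACG-CDS null.

    Per species the null is the empirical distribution over all
    TACG-context CDS adenosines; species are combined weighted by their
    observed site counts, so totals equal the observed N.
    """
    positions = pd.Series(0.0, index=[1, 2, 3])
    effects = pd.Series(
        0.0, index=["synonymous", "nonsynonymous", "stop_gain", "stop_loss"]
    )
    for species, n in per_species_site_counts.items():
        pos_counts = pd.Series(0, index=[1, 2, 3], dtype=float)
        eff_counts = effects.copy() * 0
        for _, _, cpos, eff in tacg_cds_adenosines(genomes[species]):
            pos_counts[cpos] += 1
            eff_counts[eff.effect] += 1
        total = pos_counts.sum()
        if total == 0:
            raise ValueError(f"genome of {species} has no TACG CDS adenosines")
        positions += n * pos_counts / total
        effects += n * eff_counts / total
    return positions, effects


def observed_codon_distributions(
    sites, genome
) -> tuple[pd.Series, pd.Series]:
    positions = pd.Series(0, index=[1, 2, 3], dtype=float)
    effects = pd.Series(
        0.0, index=["synonymous", "nonsynonymous", "stop_gain", "stop_loss"]
    )
    for s in sites:
        eff = annotate_codon_effect(s, genome)
        if eff is None:
            continue
        positions[eff.codon_position] += 1
        effects[eff.effect] += 1
    return positions, effects
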