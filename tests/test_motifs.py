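"""Motif counting, genome-sampled null, chi-square GOF, 7-mer classes,
PFM/information content, and codon recoding effects."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import GENETIC_CODE, revcomp as rc
from tadedit.discovery import EditingSite
from tadedit.io import AnnotatedGenome, Gene
from tadedit.motifs import (FOURMERS, chi_square_gof, classify_seven_mer,
                            codon_effect_from_codon, codon_expected_distributions,
                            count_observed_motifs, genome_fourmer_frequencies,
                            genomic_motif_null, observed_codon_distributions,
                            position_frequency_matrix, seven_mer_summary,
                            tacg_cds_adenosines, annotate_codon_effect)


def _site(context21, **kw):
    base = dict(contig="c", position=50, gene_id="g", gene_strand="+",
                rna_class="mRNA", context21=context21,
                context7=context21[8:15])
    base.update(kw)
    return EditingSite(**base)


# ---------------------------------------------------------------------------
# Observed 4-mers


def test_fourmer_category_is_minus1_A_plus1_plus2():
    s = _site("G" * 9 + "TACG" + "G" * 8)  # ...T[A]CG...
    counts = count_observed_motifs([s])
    assert counts["TACG"] == 1 and counts.sum() == 1
    s2 = _site("G" * 9 + "CAAA" + "G" * 8)
    assert count_observed_motifs([s2])["CAAA"] == 1


def test_fourmer_totals_equal_usable_sites(discovery_run):
    sites, _, _ = discovery_run
    counts = count_observed_motifs(sites)
    assert counts.sum() == len(sites)
    assert len(counts) == 64


# ---------------------------------------------------------------------------
# Genomic null


def test_toy_genome_aaaa_yields_single_category():
    freqs = genome_fourmer_frequencies(AnnotatedGenome({"c": "AAAA"}))
    assert freqs["AAAA"] == 1.0 and freqs.sum() == pytest.approx(1.0)


def test_genome_frequencies_match_exhaustive_enumeration():
    rng = np.random.default_rng(41)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    freqs = genome_fourmer_frequencies(AnnotatedGenome({"c": seq}))
    expected = {m: 0 for m in FOURMERS}
    for s in (seq, rc(seq)):
        for i in range(len(s) - 3):
            if s[i + 1] == "A":
                expected[s[i : i + 4]] += 1
    total = sum(expected.values())
    for m in FOURMERS:
        assert freqs[m] == pytest.approx(expected[m] / total)


def test_two_species_null_is_weighted_average():
    g1 = AnnotatedGenome({"c": "TACGTACG"})
    g2 = AnnotatedGenome({"c": "CAAACAAA"})
    f1 = genome_fourmer_frequencies(g1)
    f2 = genome_fourmer_frequencies(g2)
    expected = genomic_motif_null({"a": g1, "b": g2}, {"a": 1, "b": 1})
    assert np.allclose(expected.values, (f1 + f2).values)
    assert expected.sum() == pytest.approx(2.0)


def test_missing_genome_for_species_with_sites_raises():
    with pytest.raises(ValueError, match="no genome"):
        genomic_motif_null({}, {"sp": 5})


# ---------------------------------------------------------------------------
# Chi-square GOF


def test_chi_square_statistic_from_direct_formula():
    stat, df, p = chi_square_gof([30, 10], [20, 20])
    assert stat == pytest.approx(10.0) and df == 1
    assert p == pytest.approx(stats.chi2.sf(10.0, 1))


def test_chi_square_of_perfect_fit_is_zero():
    stat, df, p = chi_square_gof([10, 20, 30], [10, 20, 30])
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_chi_square_df_is_63_for_64_categories():
    obs = np.ones(64)
    exp = np.ones(64)
    _, df, _ = chi_square_gof(obs, exp)
    assert df == 63


def test_small_expected_categories_are_pooled():
    obs = [10, 10, 1, 0]
    exp = [10.5, 10.0, 0.3, 0.2]
    _, df, _ = chi_square_gof(obs, exp)
    assert df == 2  # the two sub-threshold categories pool into one


# ---------------------------------------------------------------------------
# 7-mer classes


def test_sevenmer_consensus_variants():
    assert classify_seven_mer("CTACGAA").hamming_to_consensus == 0
    assert classify_seven_mer("TTACGAA").hamming_to_consensus == 0
    cls = classify_seven_mer("GTACGAA")
    assert cls.hamming_to_consensus == 1 and cls.mismatch_offsets == (1,)
    with pytest.raises(ValueError):
        classify_seven_mer("CTACGA")
    with pytest.raises(ValueError):
        classify_seven_mer("CTACGAN")


def test_sevenmer_classification_over_all_16384_seven_mers():
    consensus = "YTACGAA"
    allowed = {"Y": "CT", "A": "A", "C": "C", "G": "G", "T": "T"}
    for mer in itertools.product("ACGT", repeat=7):
        mer = "".join(mer)
        expected = sum(b not in allowed[c] for b, c in zip(mer, consensus))
        got = classify_seven_mer(mer)
        assert got.hamming_to_consensus == expected
        assert len(got.mismatch_offsets) == expected


def test_sevenmer_summary_partitions_sites(discovery_run):
    sites, _, _ = discovery_run
    summary = seven_mer_summary(sites)
    assert summary.sum() == pytest.approx(1.0)
    assert summary["exact"] == 1.0  # planted sites match the motif exactly


# ---------------------------------------------------------------------------
# PFM / information content


def test_identical_contexts_reach_maximal_information():
    n = 50
    ctx = "ACGTACGTAC" + "A" + "GTACGTACGT"
    pfm = position_frequency_matrix([ctx] * n)
    e_n = 3 / (2 * np.log(2) * n)
    assert np.allclose(pfm["IC"], 2 - e_n)
    assert np.allclose(pfm[list("ACGT")].sum(axis=1), 1.0)


def test_random_contexts_have_near_zero_information_off_center():
    rng = np.random.default_rng(47)
    n = 4000
    contexts = ["".join(rng.choice(list("ACGT"), size=10)) + "A"
                + "".join(rng.choice(list("ACGT"), size=10)) for _ in range(n)]
    pfm = position_frequency_matrix(contexts)
    off_center = pfm.drop(index=0)
    assert np.abs(off_center["IC"]).max() < 0.05
    assert pfm.loc[0, "A"] == 1.0
    assert pfm.loc[0, "IC"] == pytest.approx(2 - 3 / (2 * np.log(2) * n))


def test_heterogeneous_context_lengths_raise():
    with pytest.raises(ValueError):
        position_frequency_matrix(["A" * 21, "A" * 20])


# ---------------------------------------------------------------------------
# Codon effects


@pytest.mark.parametrize("codon,offset,edited,aa_ref,aa_edited,effect", [
    ("TAC", 1, "TGC", "Y", "C", "nonsynonymous"),  # UAC -> UGC, Tyr->Cys
    ("ACG", 0, "GCG", "T", "A", "nonsynonymous"),  # ACG -> GCG, Thr->Ala
    ("GTA", 2, "GTG", "V", "V", "synonymous"),     # GUA -> GUG, Val
    ("TTA", 2, "TTG", "L", "L", "synonymous"),     # UUA -> UUG, Leu
    ("TGA", 2, "TGG", "*", "W", "stop_loss"),
])
def test_codon_effect_fixtures(codon, offset, edited, aa_ref, aa_edited, effect):
    eff = codon_effect_from_codon(codon, offset)
    assert (eff.codon_edited, eff.aa_ref, eff.aa_edited, eff.effect) == \
        (edited, aa_ref, aa_edited, effect)
    assert eff.codon_position == offset + 1


def test_codon_effects_agree_with_hand_written_code_table():
    """All 64 codons x up to 3 editable positions against a literal
    genetic-code dictionary."""
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        for offset in range(3):
            if codon[offset] != "A":
                with pytest.raises(ValueError):
                    codon_effect_from_codon(codon, offset)
                continue
            eff = codon_effect_from_codon(codon, offset)
            edited = codon[:offset] + "G" + codon[offset + 1:]
            aa_ref, aa_ed = GENETIC_CODE[codon], GENETIC_CODE[edited]
            assert (eff.aa_ref, eff.aa_edited) == (aa_ref, aa_ed)
            if aa_ref == aa_ed:
                assert eff.effect == "synonymous"
            elif aa_ed == "*":
                assert eff.effect == "stop_gain"
            elif aa_ref == "*":
                assert eff.effect == "stop_loss"
            else:
                assert eff.effect == "nonsynonymous"


def test_trna_sites_have_no_codon_effect():
    genome = AnnotatedGenome({"c": "A" * 100},
                             [Gene("t", "c", 10, 86, "+", "tRNA")])
    s = _site("A" * 21, gene_id="t", rna_class="tRNA")
    assert annotate_codon_effect(s, genome) is None


# ---------------------------------------------------------------------------
# Expected codon-position / effect distributions


def test_toy_cds_tacg_adenosine_sits_at_codon_position_two():
    genome = AnnotatedGenome({"c": "ATGTACGAATAA"},
                             [Gene("g", "c", 0, 12, "+", "CDS")])
    entries = list(tacg_cds_adenosines(genome))
    assert len(entries) == 1
    _, offset, codon_pos, eff = entries[0]
    assert offset == 4 and codon_pos == 2
    assert (eff.aa_ref, eff.aa_edited) == ("Y", "C")


def test_null_concentrated_at_position_two_gives_that_distribution():
    genome = AnnotatedGenome({"c": "ATGTACGAATAA"},
                             [Gene("g", "c", 0, 12, "+", "CDS")])
    positions, effects = codon_expected_distributions({"sp": genome}, {"sp": 7})
    assert positions.tolist() == [0.0, 7.0, 0.0]
    assert effects["nonsynonymous"] == 7.0


def test_observed_equals_expected_gives_p_near_one(discovery_run, dataset):
    sites, _, _ = discovery_run
    obs_pos, _ = observed_codon_distributions(sites, dataset.genome)
    _, df, p = chi_square_gof(obs_pos, obs_pos)
    assert df == 2 and p == pytest.approx(1.0)
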