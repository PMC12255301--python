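"""Filter cascade: variant filters, replicate intersection, orientation,
DNA subtraction, stranded filtering, rescue, and full parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from tadedit.align import Alignment
from tadedit.discovery import (ABAYLYI, CROSS_SPECIES, DiscoveryProfile,
                               filter_variants, intersect_replicates,
                               orient_and_restrict, rescue_frequencies,
                               run_discovery, stranded_filter,
                               subtract_dna_variants)
from tadedit.io import AnnotatedGenome, Gene
from tadedit.pileup import build_pileup, call_variants


def _call_row(**kw):
    base = dict(contig="chr", pos=100, ref="A", alt="G", count=10, coverage=100,
                freq_pct=10.0, unique_starts=5, unique_ends=5, n_alleles=2,
                count_fwd=10, count_rev=0, cov_fwd=100, cov_rev=0,
                sample_id="s1")
    base.update(kw)
    return base


def _calls(*rows):
    return pd.DataFrame([_call_row(**r) for r in rows])


# ---------------------------------------------------------------------------
# filter_variants


def test_frequency_band_is_inclusive_98():
    calls = _calls(dict(pos=1, freq_pct=99.0), dict(pos=2, freq_pct=98.0),
                   dict(pos=3, freq_pct=5.0), dict(pos=4, freq_pct=4.9))
    out = filter_variants(calls, CROSS_SPECIES)
    assert out["pos"].tolist() == [2, 3]


def test_uniqueness_and_allele_filters():
    calls = _calls(dict(pos=1, unique_starts=2), dict(pos=2, unique_ends=2),
                   dict(pos=3, n_alleles=3), dict(pos=4))
    out = filter_variants(calls, CROSS_SPECIES)
    assert out["pos"].tolist() == [4]


def test_commuting_filters_are_order_insensitive():
    rng = np.random.default_rng(3)
    calls = _calls(*[
        dict(pos=i, freq_pct=float(rng.uniform(0, 100)),
             unique_starts=int(rng.integers(1, 6)),
             unique_ends=int(rng.integers(1, 6)))
        for i in range(50)
    ])
    freq_only = DiscoveryProfile(min_unique_starts=0, min_unique_ends=0)
    uniq_only = DiscoveryProfile(min_freq_pct=0.001, max_freq_pct=100.0)
    a = filter_variants(filter_variants(calls, freq_only), uniq_only)
    b = filter_variants(filter_variants(calls, uniq_only), freq_only)
    assert a["pos"].tolist() == b["pos"].tolist()


# ---------------------------------------------------------------------------
# intersect_replicates


def test_all_rule_requires_every_replicate():
    per_sample = {"s1": _calls(dict(pos=1)), "s2": _calls(dict(pos=1)),
                  "s3": _calls(dict(pos=2))}
    assert intersect_replicates(per_sample, ("all",)) == set()


def test_three_of_four_rule():
    per_sample = {f"s{i}": _calls(dict(pos=1)) for i in range(3)}
    per_sample["s3"] = _calls(dict(pos=2))
    keys = intersect_replicates(per_sample, ("at_least_k", 3))
    assert keys == {("chr", 1, "A", "G")}


def test_single_sample_experiment_is_a_config_error():
    with pytest.raises(ValueError, match=">=2 samples"):
        intersect_replicates({"s1": _calls(dict(pos=1))}, ("all",))
    with pytest.raises(ValueError, match="exceeds"):
        intersect_replicates({"s1": _calls(), "s2": _calls()},
                             ("at_least_k", 3))


# ---------------------------------------------------------------------------
# orientation / restriction


@pytest.fixture(scope="module")
def oriented_genome():
    rng = np.random.default_rng(9)
    seq = list(rng.choice(list("ACGT"), size=600))
    seq[120] = "A"  # inside plus gene
    seq[220] = "T"  # inside minus gene (coding A)
    seq[430] = "T"  # inside minus-strand tRNA (coding A)
    genes = [Gene("plus", "c", 100, 160, "+"), Gene("minus", "c", 200, 260, "-"),
             Gene("ovlA", "c", 300, 360, "+"), Gene("ovlB", "c", 330, 390, "-"),
             Gene("trn", "c", 400, 476, "-", "tRNA")]
    return AnnotatedGenome({"c": "".join(seq)}, genes)


def test_forward_t_to_c_in_minus_gene_becomes_coding_a_to_g(oriented_genome):
    sites = orient_and_restrict({("c", 220, "T", "C")}, oriented_genome)
    (s,) = sites
    assert (s.gene_id, s.gene_strand, s.rna_class) == ("minus", "-", "mRNA")
    assert s.context21[10] == "A" and s.context7 == s.context21[8:15]
    assert s.context7[2] == "A"


def test_intergenic_and_wrong_substitutions_are_dropped(oriented_genome):
    keys = {("c", 50, "A", "G"),   # intergenic
            ("c", 120, "C", "T"),  # wrong substitution in plus gene
            ("c", 120, "T", "C"),  # T>C inside a plus gene is antisense
            ("c", 220, "A", "G")}  # A>G inside a minus gene is antisense
    assert orient_and_restrict(keys, oriented_genome) == []


def test_overlapping_genes_on_both_strands_are_dropped(oriented_genome):
    assert orient_and_restrict({("c", 340, "A", "G")}, oriented_genome) == []


def test_rna_class_follows_feature_type(oriented_genome):
    sites = orient_and_restrict({("c", 430, "T", "C")}, oriented_genome)
    assert len(sites) == 1 and sites[0].rna_class == "tRNA"


# ---------------------------------------------------------------------------
# DNA subtraction


def test_dna_variant_subtraction(oriented_genome):
    sites = orient_and_restrict({("c", 220, "T", "C"), ("c", 120, "A", "G")},
                                oriented_genome)
    assert len(sites) == 2
    # matching position+allele removed; forward alt for the minus gene is C
    out = subtract_dna_variants(sites, [("c", 220, "C")])
    assert [s.position for s in out] == [120]
    # absent from the list -> kept; empty list -> identity
    assert subtract_dna_variants(sites, [("c", 220, "G")]) == sites
    assert subtract_dna_variants(sites, []) == sites


# ---------------------------------------------------------------------------
# stranded filtering and rescue


def _aln(seq, start, strand, rid, contig="c"):
    return Alignment(rid, contig, start, start + len(seq), strand, 1.0, 1.0,
                     seq, np.full(len(seq), 37))


@pytest.fixture()
def stranded_case(oriented_genome):
    """Plus-strand gene site at 120 with sense+antisense support mixtures."""
    seq = oriented_genome.sequences["c"]
    ref = seq[100:160]
    alt = ref[:20] + "G" + ref[21:]  # G at position 120
    sense = [_aln(alt, 100, "+", f"se{i}") for i in range(4)]
    sense += [_aln(ref, 100, "+", f"sr{i}") for i in range(6)]
    anti = [_aln(alt, 100, "-", f"ae{i}") for i in range(8)]
    return oriented_genome, sense, anti


def test_antisense_only_support_is_dropped(stranded_case):
    genome, _sense, anti = stranded_case
    piles = {"s1": build_pileup(anti, genome)}
    sites = orient_and_restrict({("c", 120, "A", "G")}, genome)
    assert stranded_filter(sites, piles) == []


def test_sense_support_is_kept_and_mixed_support_counts_sense_only(stranded_case):
    genome, sense, anti = stranded_case
    piles = {"s1": build_pileup(sense + anti, genome)}
    sites = orient_and_restrict({("c", 120, "A", "G")}, genome)
    kept = stranded_filter(sites, piles)
    assert len(kept) == 1
    rescue_frequencies(kept, piles, stranded=True)
    # 4 edited / 10 sense reads; the 8 antisense alt reads are ignored
    assert kept[0].per_sample_levels["s1"] == pytest.approx(40.0)


def test_unstranded_library_with_stranded_filter_is_an_error(stranded_case):
    genome, sense, _ = stranded_case
    sites = orient_and_restrict({("c", 120, "A", "G")}, genome)
    with pytest.raises(ValueError, match="stranded"):
        stranded_filter(sites, {"s1": build_pileup(sense, genome)},
                        library_stranded=False)


def test_rescue_reports_subthreshold_levels_and_missing_coverage(stranded_case):
    genome, sense, _anti = stranded_case
    seq = genome.sequences["c"]
    ref = seq[100:160]
    alt = ref[:20] + "G" + ref[21:]
    # second sample: 2/100 edited reads (below the 5% calling floor)
    weak = [_aln(alt, 100, "+", f"we{i}") for i in range(2)]
    weak += [_aln(ref, 100, "+", f"wr{i}") for i in range(98)]
    piles = {"s1": build_pileup(sense, genome),
             "s2": build_pileup(weak, genome),
             "s3": build_pileup([_aln(ref[:30], 130, "+", "far")], genome)}
    sites = orient_and_restrict({("c", 120, "A", "G")}, genome)
    rescue_frequencies(sites, piles)
    levels = sites[0].per_sample_levels
    assert levels["s2"] == pytest.approx(2.0)
    assert levels["s3"] is None  # no coverage -> missing, not zero
    assert sites[0].per_sample_coverage["s3"] == 0


def test_rescued_level_matches_call_frequency(discovery_run):
    sites, _, pileups = discovery_run
    sample = sorted(pileups)[0]
    calls = call_variants(pileups[sample], sample_id=sample)
    by_key = {(r["contig"], r["pos"]): r["freq_pct"] for _, r in calls.iterrows()}
    checked = 0
    for s in sites:
        if (s.contig, s.position) in by_key and s.gene_strand == "+":
            assert s.per_sample_levels[sample] == pytest.approx(
                by_key[(s.contig, s.position)])
            checked += 1
    assert checked >= 5


# ---------------------------------------------------------------------------
# Full cascade on the reference simulation


def test_cascade_recovers_planted_sites(dataset, discovery_run):
    sites, table, _ = discovery_run
    truth = {(t.contig, t.position): t for t in dataset.truth}
    found = {(s.contig, s.position) for s in sites}
    sensitivity = len(found & set(truth)) / len(truth)
    assert sensitivity >= 0.9
    assert not found - set(truth), "false positive sites"
    assert len(table) == len(sites)


def test_strain_snps_never_reach_the_final_table(dataset, discovery_run):
    sites, _, _ = discovery_run
    snp_pos = {(s.contig, s.position) for s in dataset.snps}
    assert not snp_pos & {(s.contig, s.position) for s in sites}


def test_recovered_levels_match_designed_levels(dataset, discovery_run):
    """Pooled level estimates fall inside the 95% binomial interval of the
    designed level for >=90% of recovered sites."""
    sites, _, pileups = discovery_run
    truth = {(t.contig, t.position): t for t in dataset.truth}
    n_ok = n_tot = 0
    for s in sites:
        t = truth.get((s.contig, s.position))
        if t is None:
            continue
        cnt = cov = 0
        for piles in pileups.values():
            c, n = piles.allele_level(s.contig, s.position, s.forward_alt)
            cnt += c
            cov += n
        p_hat = cnt / cov
        half = 1.96 * np.sqrt(t.designed_level * (1 - t.designed_level) / cov)
        n_tot += 1
        n_ok += abs(p_hat - t.designed_level) <= half
    assert n_tot >= 0.9 * len(dataset.truth)
    assert n_ok / n_tot >= 0.9
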