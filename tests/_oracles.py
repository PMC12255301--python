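"""Independent oracles: brute-force / closed-form routes that the tests
compare against the package implementations.  Nothing here imports the
code paths it checks."""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Mapper: exhaustive placement scan


def brute_force_map(read_seq: str, genome: dict[str, str],
                    similarity: float = 0.95):
    """Best full-length ungapped placement over all (contig, pos, strand).

    Returns (contig, start, strand, matches) or None for unmapped /
    equal-best ties, mirroring nonspecific-match 'ignore'.
    """
    L = len(read_seq)
    placements = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        for contig, ref in genome.items():
            for start in range(len(ref) - L + 1):
                matches = sum(a == b for a, b in zip(ref[start : start + L], seq))
                if matches / L >= similarity:
                    placements.append((matches, contig, start, strand))
    if not placements:
        return None
    best = max(p[0] for p in placements)
    top = [p for p in placements if p[0] == best]
    if len(top) != 1:
        return None
    m, contig, start, strand = top[0]
    return contig, start, strand, m


# ---------------------------------------------------------------------------
# Pileup: literal per-position recount


def brute_force_pileup(alignments, genome: dict[str, str], radius=2,
                       min_central=30, min_neighbor=30):
    """counts[(contig, pos)][base] recomputed directly from the rule."""
    counts: dict[tuple, dict[str, int]] = {}
    for a in alignments:
        quals = list(map(int, a.quals))
        for i, (pos, base, q) in enumerate(a.columns()):
            if base == "N" or q < min_central:
                continue
            lo, hi = max(0, i - radius), min(len(quals), i + radius + 1)
            if any(quals[j] < min_neighbor for j in range(lo, hi)):
                continue
            counts.setdefault((a.contig, pos), {b: 0 for b in "ACGT"})[base] += 1
    return counts


# ---------------------------------------------------------------------------
# Nussinov: alternative recursion (pair-first decomposition)


def max_nested_pairs(seq: str, min_loop: int = 3) -> int:
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
             ("G", "U"), ("U", "G")}
    s = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = f(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in pairs:
                best = max(best, 1 + f(i + 1, k - 1) + f(k + 1, j))
        return best

    return f(0, len(s) - 1)


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (Eulerian-trail resampling, Hierholzer walk)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(seq) - 1
    while True:
        stacks = {k: [v[i] for i in rng.permutation(len(v))]
                  for k, v in edges.items()}
        stack, trail = [seq[0]], []
        while stack:
            v = stack[-1]
            if stacks.get(v):
                stack.append(stacks[v].pop())
            else:
                trail.append(stack.pop())
        if len(trail) == n_edges + 1:
            return "".join(reversed(trail))


# ---------------------------------------------------------------------------
# t statistics from the textbook formulas


def welch_formula(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def student_formula(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


# ---------------------------------------------------------------------------
# BH step-up, literal definition


def bh_literal(pvalues):
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    sorted_p = p[order]
    q = np.empty(m)
    for i in range(m):
        r = ranks[i]
        q[i] = min(min(sorted_p[j - 1] * m / j for j in range(r, m + 1)), 1.0)
    return q


# ---------------------------------------------------------------------------
# Standard genetic code (hand-written table, not derived from Biopython)

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
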