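"""17-nt MFE sliding windows around editing sites, with motif controls.

Window geometry follows the tRNA-Arg2 anticodon arm: 17 nucleotides with
the edited adenosine at 1-based position 8 (NNNNNYT[A]CGAANNNNN).  Offset
0 centres the site at that arm position; offset d shifts the window d
bases downstream along the coding strand; windows slide in 1-nt steps.

Folding goes through a pluggable engine adapter: "vienna" uses the
ViennaRNA nearest-neighbor thermodynamic model at 37 C (default parameter
set); "fallback" is a built-in Nussinov base-pair maximisation scorer
(-1 per pair, minimum hairpin loop 3) that is NOT thermodynamic and
exists so relative structure comparisons work without ViennaRNA.
"auto" prefers vienna and falls back.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import EditingSite
from .io import AnnotatedGenome, revcomp

WINDOW = 17
UPSTREAM = 7  # bases upstream of the edited A at offset 0
DOWNSTREAM = 9

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


# ---------------------------------------------------------------------------
# Folding engines


def _vienna_mfe(seq: str) -> float:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - env without bindings
        raise RuntimeError(
            "ViennaRNA python bindings unavailable; use engine='fallback'"
        ) from exc
    _, mfe = RNA.fold(seq)
    return float(mfe)


@lru_cache(maxsize=200_000)
def _nussinov_pairs(seq: str) -> int:
    """Maximum nested base pairs with minimum hairpin loop of 3."""
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    for span in range(4, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            if (seq[i], seq[j]) in _PAIRS:
                inner = dp[i + 1][j - 1] if i + 1 <= j - 1 else 0
                best = max(best, inner + 1)
            for k in range(i, j):
                best = max(best, dp[i][k] + dp[k + 1][j])
            dp[i][j] = best
    return dp[0][n - 1] if n else 0


def fold_mfe(sequence: str, engine: str = "auto") -> float:
    """MFE (kcal/mol for vienna; -pairs for the fallback scorer)."""
    seq = sequence.upper().replace("T", "U")
    if len(seq) < 3:
        raise ValueError("sequence too short to fold")
    if engine == "vienna":
        return _vienna_mfe(seq)
    if engine == "fallback":
        return float(-_nussinov_pairs(seq))
    if engine == "auto":
        try:
            return _vienna_mfe(seq)
        except RuntimeError:
            return float(-_nussinov_pairs(seq))
    raise ValueError(f"unknown folding engine {engine!r}")


# ---------------------------------------------------------------------------
# Windows


def extract_window(
    site_position: int,
    strand: str,
    genome: AnnotatedGenome,
    contig: str,
    offset: int = 0,
    length: int = WINDOW,
) -> str | None:
    """RNA window at the given offset, or None if it runs off the contig.

    At offset 0 the window spans coding-strand positions
    [site-7, site+9]; positive offsets move downstream on the coding
    strand (towards 3' of the transcript).
    """
    up = UPSTREAM + (length - WINDOW)  # keep A at arm position for len 17
    if strand == "+":
        start = site_position - up + offset
        end = start + length
    else:
        end = site_position + up + 1 - offset
        start = end - length
    if start < 0 or end > len(genome.sequences[contig]):
        return None
    return genome.slice(contig, start, end, strand).replace("T", "U")


def window_for_site(site: EditingSite, genome: AnnotatedGenome,
                    offset: int = 0) -> str | None:
    return extract_window(site.position, site.gene_strand, genome,
                          site.contig, offset)


def mfe_profile(
    windows_by_offset: dict[int, list[str]], engine: str = "auto"
) -> pd.DataFrame:
    """Per-offset mean MFE, standard error and n over site windows."""
    rows = []
    for offset in sorted(windows_by_offset):
        vals = np.array([fold_mfe(w, engine) for w in windows_by_offset[offset]])
        n = len(vals)
        rows.append({
            "offset": offset,
            "mean_mfe": float(vals.mean()) if n else np.nan,
            "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "n": n,
        })
    return pd.DataFrame(rows)


def profile_for_sites(
    sites: list[EditingSite],
    genome: AnnotatedGenome,
    offsets=range(-30, 31),
    engine: str = "auto",
) -> pd.DataFrame:
    windows = {
        off: [w for s in sites if (w := window_for_site(s, genome, off)) is not None]
        for off in offsets
    }
    return mfe_profile(windows, engine)


# ---------------------------------------------------------------------------
# Controls


def _iupac_match(seq: str, pattern: str) -> bool:
    from .motifs import _IUPAC
    return all(b in _IUPAC[p] for b, p in zip(seq, pattern))


def locate_control_sites(
    genome: AnnotatedGenome,
    pattern: str = "YTACGAA",
    exclude: set[tuple[str, int]] = frozenset(),
    anchor_offset: int = 2,
) -> list[tuple[str, int, str]]:
    """All motif occurrences on either strand, minus real editing sites.

    Returns (contig, forward-strand position of the would-be edited A,
    strand).  On the reverse strand the anchor maps to the complementary
    A's forward coordinate.
    """
    k = len(pattern)
    hits = []
    for contig, seq in genome.sequences.items():
        for i in range(len(seq) - k + 1):
            if _iupac_match(seq[i : i + k], pattern):
                anchor = i + anchor_offset
                if (contig, anchor) not in exclude:
                    hits.append((contig, anchor, "+"))
        rc = revcomp(seq)
        L = len(seq)
        for i in range(len(rc) - k + 1):
            if _iupac_match(rc[i : i + k], pattern):
                anchor = L - 1 - (i + anchor_offset)
                if (contig, anchor) not in exclude:
                    hits.append((contig, anchor, "-"))
    return hits


def control_windows(
    genome: AnnotatedGenome,
    controls: list[tuple[str, int, str]],
    offset: int = 0,
) -> list[str]:
    out = []
    for contig, pos, strand in controls:
        w = extract_window(pos, strand, genome, contig, offset)
        if w is not None:
            out.append(w)
    return out


def shuffled_flank_windows(
    windows: list[str], n_per_window: int, rng: np.random.Generator
) -> list[str]:
    """Controls made by permuting the 5-base flanks of each 17-nt window.

    The central 7-mer (indices 5..11) is preserved, so the controls carry
    the recognition motif but lose the stem pairing.
    """
    out = []
    for w in windows:
        flank_idx = list(range(0, 5)) + list(range(12, 17))
        for _ in range(n_per_window):
            perm = rng.permutation(flank_idx)
            chars = list(w)
            for src, dst in zip(perm.tolist(), flank_idx):
                chars[dst] = w[src]
            out.append("".join(chars))
    return out


# ---------------------------------------------------------------------------
# Welch's t


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Unequal-variance t with Welch-Satterthwaite df; two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t needs n >= 2 in each group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_site_vs_control_mfe(
    site_windows: list[str], control_windows: list[str], engine: str = "auto"
) -> tuple[float, float, float]:
    """Welch's t on offset-0 MFEs of sites vs controls."""
    mfe_a = [fold_mfe(w, engine) for w in site_windows]
    mfe_b = [fold_mfe(w, engine) for w in control_windows]
    return welch_t(mfe_a, mfe_b)
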