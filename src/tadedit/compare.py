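"""Differential editing between strains and conservation of editing events.

Per-site differential editing uses the classic pooled-variance two-sample
(Student's) t-test on per-replicate editing levels, followed by
Benjamini-Hochberg FDR correction across sites.  Group-level comparisons
of per-site mean levels (e.g. overexpression vs control site sets) use
Welch's t.  Conservation classes partition editing events by whether the
same protein is recoded at the same position and substitution in >=2
species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy import stats

from .structure import welch_t

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Multiple testing


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over j >= rank(i) of p_(j) * m / j, capped at 1, returned in
    the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Differential editing


def student_t(levels_a, levels_b) -> tuple[float, float]:
    """Pooled-variance two-sided t-test; p = 1 when both groups constant."""
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Student's t needs >=2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.info("all-identical values in both groups; p = 1 by convention")
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def differential_editing(
    levels_a: dict[str, list[float]], levels_b: dict[str, list[float]]
) -> pd.DataFrame:
    """Per-site Student's t with BH correction across the site set.

    ``levels_a``/``levels_b`` map site id -> per-replicate editing levels
    (percent) in the two conditions; only sites present in both are
    tested.  ``relative_change`` is (mean_b - mean_a) / mean_a, missing
    when mean_a is 0.
    """
    site_ids = [s for s in levels_a if s in levels_b]
    rows = []
    for sid in site_ids:
        a = np.asarray(levels_a[sid], dtype=float)
        b = np.asarray(levels_b[sid], dtype=float)
        t, p = student_t(a, b)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        rel = (mean_b - mean_a) / mean_a if mean_a != 0 else np.nan
        rows.append({"site": sid, "mean_a": mean_a, "mean_b": mean_b,
                     "t": t, "p": p, "relative_change": rel})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = []
    return df


def group_comparison(site_means_a, site_means_b) -> tuple[float, float, float]:
    """Welch's t on two vectors of per-site mean levels."""
    if len(site_means_a) < 2 or len(site_means_b) < 2:
        raise ValueError("group comparison needs >=2 sites per group")
    return welch_t(site_means_a, site_means_b)


# ---------------------------------------------------------------------------
# Conservation classes


@dataclass(frozen=True)
class ConservationRecord:
    species: str
    protein_key: str
    protein_position: int
    substitution: str
    conservation_class: str  # unique | partially_conserved | conserved


def classify_conservation(table: pd.DataFrame) -> pd.DataFrame:
    """Classify editing events by cross-species conservation.

    Input columns: species, protein_key, protein_position, substitution.
    An event is *conserved* when >=2 species recode the same protein at
    the same position with the same substitution; *partially_conserved*
    when >=2 species share the protein key but this event's exact
    (position, substitution) is not shared; *unique* when the protein key
    occurs in a single species.  Every input row lands in exactly one
    class.
    """
    required = {"species", "protein_key", "protein_position", "substitution"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    df = table.copy()
    species_per_protein = df.groupby("protein_key")["species"].nunique()
    species_per_event = df.groupby(
        ["protein_key", "protein_position", "substitution"]
    )["species"].nunique()

    def classify(row):
        if species_per_protein[row["protein_key"]] < 2:
            return "unique"
        key = (row["protein_key"], row["protein_position"], row["substitution"])
        if species_per_event[key] >= 2:
            return "conserved"
        return "partially_conserved"

    df["conservation_class"] = df.apply(classify, axis=1)
    return df


# ---------------------------------------------------------------------------
# Alignment-column identity


def alignment_column_identity(
    msa_path, ref_id: str, ref_position: int, exclusions: set[str] = frozenset()
) -> dict[str, float]:
    """Residue frequencies at the MSA column matching a reference position.

    ``ref_position`` is 1-based in the ungapped reference sequence.
    Sequences in ``exclusions`` (partial/uncultured/hypothetical entries,
    per upstream metadata) do not count toward the frequencies; gap
    characters tally as '-'.
    """
    alignment = AlignIO.read(str(msa_path), "fasta")
    ref = next((rec for rec in alignment if rec.id == ref_id), None)
    if ref is None:
        raise ValueError(f"reference {ref_id} not present in the alignment")
    ungapped = 0
    column = None
    for col, char in enumerate(str(ref.seq)):
        if char != "-":
            ungapped += 1
            if ungapped == ref_position:
                column = col
                break
    if column is None:
        raise ValueError(
            f"position {ref_position} beyond ungapped length of {ref_id}"
        )
    counts: dict[str, int] = {}
    n = 0
    for rec in alignment:
        if rec.id in exclusions:
            continue
        residue = str(rec.seq)[column].upper()
        counts[residue] = counts.get(residue, 0) + 1
        n += 1
    return {res: c / n for res, c in sorted(counts.items())}
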