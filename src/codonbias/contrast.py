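"""Axis-1 extreme-group contrast: calling over-represented (optimal) codons.

With no expression data for phage genes, the genes at the two extremes of
CA axis 1 stand in for putatively highly and lowly expressed classes. Codon
counts are pooled within each group and every codon of a degenerate family
is tested with a 2x2 Pearson chi-square (codon vs rest of family, left pool
vs right pool; df = 1, no continuity correction). A codon is called
over-represented in a group when P < .01 and its RSCU is larger there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Optional

import pandas as pd
from scipy import stats

from .codon_metrics import CodonCountTable, rscu
from .correspondence import CAResult
from .genetic_code import ALL_CODONS, CODON_TO_AA3, STOP_CODONS, SYNONYMOUS_FAMILIES, rna

OVER_LEFT = "OVER_LEFT"
OVER_RIGHT = "OVER_RIGHT"
NS = "NS"

DEFAULT_ALPHA = 0.01
DEFAULT_FRACTION = 0.10


def extreme_groups(
    ca_result: CAResult, fraction: float = DEFAULT_FRACTION
) -> tuple[list[str], list[str]]:
    """Gene ids at the two extremes of axis 1.

    Each group holds ``max(1, floor(fraction * n_genes))`` genes; "left" is
    the most negative axis-1 coordinates (the biased, putatively highly
    expressed side under the Nc-based orientation). Ties at a group
    boundary are broken by lexicographic gene id, making the groups
    deterministic.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    coords = ca_result.axis(1)
    n = len(coords)
    if n < 2:
        raise ValueError("extreme_groups requires at least 2 genes")
    size = max(1, math.floor(fraction * n))
    order = sorted(coords.index, key=lambda g: (coords[g], g))
    return order[:size], order[-size:][::-1]


@dataclass
class ContrastResult:
    """Per-codon chi-square contrast between two pooled count tables."""

    table: pd.DataFrame  # indexed by codon (DNA)
    alpha: float

    def called(self, call: str = OVER_LEFT) -> list[str]:
        return list(self.table.index[self.table["call"] == call])


def _stop_rscu(pool: CodonCountTable) -> dict[str, float]:
    # Stop codons displayed as an ordinary 3-member family in contrast
    # tables (unlike the pooled-table convention that prints them as 0).
    total = sum(pool.counts[c] for c in STOP_CODONS)
    if total == 0:
        return {c: 0.0 for c in STOP_CODONS}
    return {c: pool.counts[c] * 3 / total for c in STOP_CODONS}


def codon_chi_square(
    pool_left: CodonCountTable,
    pool_right: CodonCountTable,
    alpha: float = DEFAULT_ALPHA,
) -> ContrastResult:
    """Per-codon 2x2 chi-square between two pooled codon count tables.

    For codon c in a family f the table is
    ``[[n_c^left, n_f^left - n_c^left], [n_c^right, n_f^right - n_c^right]]``.
    Codons of single-codon families are reported untested; a codon whose
    2x2 table has a zero margin (family absent from a pool, or codon absent
    and family monomorphic) gets chi2 = NaN and call = NS. Stop codons are
    tabulated for display but never tested or called.
    """
    rscu_left = rscu(pool_left)
    rscu_right = rscu(pool_right)
    rscu_left.update(_stop_rscu(pool_left))
    rscu_right.update(_stop_rscu(pool_right))

    codon_aa = {c: aa for aa, cs in SYNONYMOUS_FAMILIES.items() for c in cs}
    rows = []
    for codon in ALL_CODONS:
        na, nb = pool_left.counts[codon], pool_right.counts[codon]
        chi2 = p = math.nan
        call = NS
        aa = codon_aa.get(codon)
        if aa is not None:
            fa = pool_left.family_total(aa)
            fb = pool_right.family_total(aa)
            table = [[na, fa - na], [nb, fb - nb]]
            if min(na + nb, (fa - na) + (fb - nb)) > 0 and fa > 0 and fb > 0:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                if p < alpha:
                    if rscu_left[codon] > rscu_right[codon]:
                        call = OVER_LEFT
                    elif rscu_right[codon] > rscu_left[codon]:
                        call = OVER_RIGHT
        rows.append(
            {
                "codon": codon,
                "aa": CODON_TO_AA3.get(codon, "Ter"),
                "rscu_left": rscu_left[codon],
                "n_left": na,
                "rscu_right": rscu_right[codon],
                "n_right": nb,
                "chi2": chi2,
                "p": p,
                "call": call,
            }
        )
    return ContrastResult(pd.DataFrame(rows).set_index("codon"), alpha)


def overrepresentation_summary(
    result: ContrastResult, call: str = OVER_LEFT
) -> dict[str, int]:
    """Tally of called codons by third base, e.g. ``{'C': 16, 'G': 5, ...}``."""
    tally = {b: 0 for b in "ACGT"}
    for codon in result.called(call):
        tally[codon[2]] += 1
    return tally


def write_contrast_tsv(
    result: ContrastResult, handle: IO[str], group_note: Optional[str] = None
) -> None:
    """Contrast table in the printed two-group layout (RNA codons, 2 dp)."""
    if group_note:
        handle.write(f"# {group_note}\n")
    df = result.table.reset_index()
    df["codon"] = df["codon"].map(rna)
    df["rscu_left"] = df["rscu_left"].round(2)
    df["rscu_right"] = df["rscu_right"].round(2)
    df.to_csv(handle, sep="\t", index=False, float_format="%.4g")
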