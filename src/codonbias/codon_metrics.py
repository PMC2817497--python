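"""Per-gene and pooled codon-usage indices.

The central quantities:

* RSCU — relative synonymous codon usage, the observed count of a codon
  divided by the count expected if all synonyms of its amino acid were used
  equally: ``RSCU(c) = n_c * k / n_family`` for a family of degeneracy k.
* Nc — Wright's effective number of codons, built from within-family
  "homozygosity" estimates F-hat = (n * sum(p_i^2) - 1) / (n - 1) averaged
  over degeneracy classes: Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, ranging from
  20 (one codon per amino acid) to 61 (all synonyms equally used).
* Positional base composition — GC overall and at codon positions 1/2, and
  A3s/T3s/G3s/C3s/GC3s over the third positions of synonymously variable
  sense codons only.
* GRAVY (mean Kyte-Doolittle hydropathy) and aromaticity (Phe+Tyr+Trp
  fraction) of the encoded protein.

Undefined quantities (e.g. Nc of a gene missing whole degeneracy classes)
are returned as NaN and logged, never raised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .gene_io import GeneRecord
from .genetic_code import (
    ALL_CODONS,
    CODON_TO_AA1,
    CODON_TO_AA3,
    DEGENERACY_CLASS_SIZES,
    SINGLE_CODON_AA,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    rna,
)

logger = logging.getLogger(__name__)

AROMATIC = frozenset("FYW")


@dataclass
class CodonCountTable:
    """Histogram over the 64 codons for one gene or a pooled gene set."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in ALL_CODONS}
    )

    @classmethod
    def from_gene(cls, gene: GeneRecord) -> "CodonCountTable":
        table = cls()
        for codon in gene.codons:
            table.counts[codon] += 1
        return table

    @classmethod
    def from_genes(cls, genes: Iterable[GeneRecord]) -> "CodonCountTable":
        table = cls()
        for gene in genes:
            for codon in gene.codons:
                table.counts[codon] += 1
        return table

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "CodonCountTable":
        table = cls()
        for codon, n in counts.items():
            table.counts[codon.upper().replace("U", "T")] += int(n)
        return table

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        out = CodonCountTable()
        for c in ALL_CODONS:
            out.counts[c] = self.counts[c] + other.counts[c]
        return out

    def family_total(self, aa: str) -> int:
        return sum(self.counts[c] for c in SYNONYMOUS_FAMILIES[aa])


def rscu(table: CodonCountTable) -> dict[str, float]:
    """RSCU for all 64 codons.

    Within each degenerate family, RSCU(c) = count(c) * k / family_total;
    a family absent from the table yields 0.0 for all members. By printing
    convention the single-codon families (Met, Trp) are reported as 1.0 and
    stop codons as 0.0.
    """
    values: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        total = table.family_total(aa)
        k = len(codons)
        for c in codons:
            values[c] = table.counts[c] * k / total if total > 0 else 0.0
    for c in SINGLE_CODON_AA:
        values[c] = 1.0
    for c in STOP_CODONS:
        values[c] = 0.0
    return values


def family_homozygosity(table: CodonCountTable, aa: str) -> float:
    """Wright's F-hat for one family; NaN when the family count is < 2."""
    codons = SYNONYMOUS_FAMILIES[aa]
    n = table.family_total(aa)
    if n < 2:
        return math.nan
    sum_p2 = sum((table.counts[c] / n) ** 2 for c in codons)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def effective_number_of_codons(table: CodonCountTable) -> float:
    """Wright's Nc from a codon count table.

    F-hat is averaged over the families of each degeneracy class that have
    at least two codons observed. If the three-fold class (Ile alone) is
    unusable its mean is interpolated as (F2 + F4) / 2; if any other class
    has no usable family, or a class mean is 0, Nc is undefined (NaN).
    Sampling noise can push the estimate above the theoretical ceiling, so
    the result is capped at 61.
    """
    class_means: dict[int, float] = {}
    for k in (2, 3, 4, 6):
        fs = [
            f
            for aa, cs in SYNONYMOUS_FAMILIES.items()
            if len(cs) == k
            for f in [family_homozygosity(table, aa)]
            if not math.isnan(f)
        ]
        class_means[k] = sum(fs) / len(fs) if fs else math.nan

    # Ile is the sole 3-fold family; when it is unobserved (or its F-hat is
    # exactly 0, which makes 1/F3 blow up) interpolate from the flanking
    # degeneracy classes as in Wright-style implementations.
    if math.isnan(class_means[3]) or class_means[3] <= 0.0:
        if math.isnan(class_means[2]) or math.isnan(class_means[4]):
            logger.info("Nc undefined: cannot interpolate 3-fold class")
            return math.nan
        class_means[3] = (class_means[2] + class_means[4]) / 2.0

    for k in (2, 4, 6):
        if math.isnan(class_means[k]) or class_means[k] <= 0.0:
            logger.info("Nc undefined: degeneracy class %d unusable", k)
            return math.nan

    nc = 2.0 + sum(
        DEGENERACY_CLASS_SIZES[k] / class_means[k] for k in (2, 3, 4, 6)
    )
    return min(nc, 61.0)


def base_composition(table: CodonCountTable) -> dict[str, float]:
    """Positional base composition from a codon count table.

    gc / gc1 / gc2 are computed over all sense codons; gc3s and the x3s
    fractions over the third positions of synonymously variable sense
    codons only (Met, Trp and stops excluded), so a3s+t3s+g3s+c3s = 1 and
    gc3s = g3s + c3s. All values are NaN when the relevant codon set is
    empty.
    """
    sense = {c: n for c, n in table.counts.items() if c not in STOP_CODONS}
    n_sense = sum(sense.values())
    out: dict[str, float] = {}
    if n_sense == 0:
        out.update({k: math.nan for k in ("gc", "gc1", "gc2")})
    else:
        gc_all = sum(n * sum(b in "GC" for b in c) for c, n in sense.items())
        out["gc"] = gc_all / (3 * n_sense)
        for pos, key in ((0, "gc1"), (1, "gc2")):
            out[key] = (
                sum(n for c, n in sense.items() if c[pos] in "GC") / n_sense
            )

    syn = {
        c: table.counts[c]
        for cs in SYNONYMOUS_FAMILIES.values()
        for c in cs
    }
    n_syn = sum(syn.values())
    if n_syn == 0:
        out.update({k: math.nan for k in ("a3s", "t3s", "g3s", "c3s", "gc3s")})
    else:
        for base in "ATGC":
            out[base.lower() + "3s"] = (
                sum(n for c, n in syn.items() if c[2] == base) / n_syn
            )
        out["gc3s"] = out["g3s"] + out["c3s"]
    return out


def gravy_and_aromaticity(table: CodonCountTable) -> tuple[float, float]:
    """Mean Kyte-Doolittle hydropathy and aromatic-residue fraction.

    Computed over the residues encoded by the sense codons of the table
    (stop codons excluded); (NaN, NaN) when there are no residues.
    """
    n_res = 0
    hydro = 0.0
    n_arom = 0
    for codon, n in table.counts.items():
        aa = CODON_TO_AA1.get(codon)
        if aa is None or n == 0:
            continue
        n_res += n
        hydro += n * KYTE_DOOLITTLE[aa]
        if aa in AROMATIC:
            n_arom += n
    if n_res == 0:
        return math.nan, math.nan
    return hydro / n_res, n_arom / n_res


@dataclass(frozen=True)
class GeneMetrics:
    """Per-gene codon-usage index vector."""

    gene_id: str
    genome: str
    length_codons: int
    nc: float
    gc: float
    gc1: float
    gc2: float
    gc3s: float
    a3s: float
    t3s: float
    g3s: float
    c3s: float
    gravy: float
    aromaticity: float


def gene_metrics(gene: GeneRecord) -> GeneMetrics:
    """All per-gene indices for one gene (length includes the stop codon)."""
    table = CodonCountTable.from_gene(gene)
    comp = base_composition(table)
    gravy, arom = gravy_and_aromaticity(table)
    return GeneMetrics(
        gene_id=gene.gene_id,
        genome=gene.genome,
        length_codons=len(gene.codons),
        nc=effective_number_of_codons(table),
        gravy=gravy,
        aromaticity=arom,
        **comp,
    )


def metrics_table(genes: Iterable[GeneRecord]) -> pd.DataFrame:
    """Per-gene metrics as a DataFrame indexed by gene_id."""
    rows = [gene_metrics(g).__dict__ for g in genes]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("metrics_table requires at least one gene")
    return df.set_index("gene_id")


def pooled_rscu_table(table: CodonCountTable) -> pd.DataFrame:
    """Pooled codon-usage table: amino acid, codon (RNA), N, RSCU.

    Mirrors the classic printed layout of genome-wide codon-usage tables.
    """
    values = rscu(table)
    rows = []
    for codon in ALL_CODONS:
        aa = CODON_TO_AA3.get(codon, "Ter")
        rows.append(
            {
                "aa": aa,
                "codon": rna(codon),
                "n": table.counts[codon],
                "rscu": round(values[codon], 2),
            }
        )
    return pd.DataFrame(rows)


def write_metrics_tsv(df: pd.DataFrame, handle: IO[str]) -> None:
    df.to_csv(handle, sep="\t", float_format="%.4f")
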