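"""Bundled reference datasets.

Three small tables transcribed from a published codon-usage survey of 32
mycobacteriophage genomes ship with the package: the pooled genome-wide
codon counts with printed RSCU, the pooled codon counts of the two CA
axis-1 extreme gene groups with printed RSCU, and the per-genome mean/sd
of Nc and GC3s. They serve as fixed inputs for reproducing the survey's
desk-computable results and as a realistic amino-acid background for the
synthetic generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codon_metrics import CodonCountTable
from .genetic_code import SINGLE_CODON_AA, STOP_CODONS, dna


def _read(name: str) -> pd.DataFrame:
    path = resources.files("codonbias.data").joinpath(name)
    with path.open() as handle:
        return pd.read_csv(handle, sep="\t", comment="#")


def pooled_codon_usage() -> pd.DataFrame:
    """Pooled codon counts and printed RSCU (columns aa, codon, n, rscu_printed)."""
    return _read("pooled_codon_usage.tsv")


def expression_contrast_counts() -> pd.DataFrame:
    """Codon counts of the axis-1 extreme-group pools with printed RSCU."""
    return _read("expression_contrast_counts.tsv")


def genome_nc_gc3s() -> pd.DataFrame:
    """Per-genome mean/sd Nc and GC3s (%) for the 32 phage genomes."""
    return _read("genome_nc_gc3s.tsv")


def pooled_count_table() -> CodonCountTable:
    """The pooled genome-wide counts as a CodonCountTable."""
    df = pooled_codon_usage()
    return CodonCountTable.from_mapping(dict(zip(df["codon"], df["n"])))


def contrast_count_tables() -> tuple[CodonCountTable, CodonCountTable]:
    """(left, right) extreme-group pools as CodonCountTables."""
    df = expression_contrast_counts()
    left = CodonCountTable.from_mapping(dict(zip(df["codon"], df["n_left"])))
    right = CodonCountTable.from_mapping(dict(zip(df["codon"], df["n_right"])))
    return left, right


def amino_acid_frequencies() -> dict[str, float]:
    """Amino-acid frequencies implied by the pooled counts (sense codons).

    One-letter-keyed fractions over the 20 amino acids; used as the default
    amino-acid background of the synthetic generator.
    """
    from .genetic_code import CODON_TO_AA1

    df = pooled_codon_usage()
    totals: dict[str, float] = {}
    for codon, n in zip(df["codon"], df["n"]):
        c = dna(codon)
        if c in STOP_CODONS:
            continue
        aa = CODON_TO_AA1[c]
        totals[aa] = totals.get(aa, 0) + int(n)
    grand = sum(totals.values())
    return {aa: n / grand for aa, n in sorted(totals.items())}
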