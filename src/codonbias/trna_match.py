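"""Codon-anticodon matching against a tRNA gene inventory.

Whether the codons favoured in highly expressed genes are readable by
abundant tRNAs is assessed by mapping every codon to the summed copy number
of tRNA genes that can decode it. Two pairing modes are supported:

* ``strict`` — Watson-Crick pairing only: a tRNA reads exactly the reverse
  complement of its anticodon.
* ``crick`` — adds the classical position-34 wobble rules: anticodon G
  (position 34, the 5' base) also reads codons ending in U, and anticodon U
  also reads codons ending in G.

Wobble by modified bases (e.g. inosine) is not modelled: it cannot be
inferred from gene sequence alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence, Union

from Bio.SeqUtils import seq3

from .genetic_code import CODON_TO_AA1, dna, reverse_complement, rna

STRICT = "strict"
CRICK = "crick"

RNA_BASES = frozenset("ACGU")


@dataclass(frozen=True)
class TrnaGene:
    """One tRNA gene: amino acid (3-letter), anticodon 5'->3' (RNA), copies."""

    amino_acid: str
    anticodon: str
    copies: int

    def __post_init__(self):
        if not RNA_BASES.issuperset(self.anticodon) or len(self.anticodon) != 3:
            raise ValueError(
                f"anticodon must be an RNA 3-mer, got {self.anticodon!r}"
            )
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


def _watson_crick_codon(anticodon: str) -> str:
    """The codon read by strict pairing, as a DNA 3-mer."""
    return reverse_complement(dna(anticodon))


def _check_inventory(inventory: Iterable[TrnaGene]) -> None:
    for t in inventory:
        codon = _watson_crick_codon(t.anticodon)
        aa = CODON_TO_AA1.get(codon)
        expected = seq3(aa) if aa is not None else "Ter"
        if expected.lower() != t.amino_acid.lower():
            raise ValueError(
                f"tRNA record {t.amino_acid}/{t.anticodon}: anticodon decodes "
                f"{expected}, not {t.amino_acid}"
            )


def codons_recognized(
    inventory: Sequence[TrnaGene], wobble_mode: str = CRICK
) -> dict[str, int]:
    """Map each decodable codon (DNA) to the summed copy number reading it."""
    if wobble_mode not in (STRICT, CRICK):
        raise ValueError(f"unknown wobble mode {wobble_mode!r}")
    _check_inventory(inventory)
    recognized: dict[str, int] = {}
    for t in inventory:
        codons = {_watson_crick_codon(t.anticodon)}
        if wobble_mode == CRICK:
            wc = _watson_crick_codon(t.anticodon)
            base34 = t.anticodon[0]
            if base34 == "G":  # G:U wobble -> also reads the U-ending codon
                codons.add(wc[:2] + "T")
            elif base34 == "U":  # U:G wobble -> also reads the G-ending codon
                codons.add(wc[:2] + "G")
        for c in codons:
            recognized[c] = recognized.get(c, 0) + t.copies
    return recognized


@dataclass
class MatchReport:
    n_matched: int
    n_unmatched: int
    detail: list[tuple[str, int]]  # (codon DNA, copies; 0 = unrecognized)

    @property
    def unmatched(self) -> list[str]:
        return [c for c, copies in self.detail if copies == 0]


def match_report(
    called_codons: Iterable[str], recognized: Mapping[str, int]
) -> MatchReport:
    """How many called (over-represented) codons a tRNA set can read."""
    detail = []
    for codon in called_codons:
        c = dna(codon)
        detail.append((c, recognized.get(c, 0)))
    n_matched = sum(1 for _, copies in detail if copies > 0)
    return MatchReport(n_matched, len(detail) - n_matched, detail)


def read_inventory_tsv(handle: IO[str]) -> list[TrnaGene]:
    """Read a tRNA inventory TSV: amino_acid, anticodon, copies."""
    out = []
    for row in csv.DictReader(handle, delimiter="\t"):
        out.append(
            TrnaGene(
                row["amino_acid"].strip(),
                row["anticodon"].strip().upper().replace("T", "U"),
                int(row["copies"]),
            )
        )
    return out


def write_match_tsv(report: MatchReport, handle: IO[str]) -> None:
    handle.write("codon\ttrna_copies\tmatched\n")
    for codon, copies in report.detail:
        handle.write(f"{rna(codon)}\t{copies}\t{int(copies > 0)}\n")
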