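"""Shared genetic-code constants.

Everything here derives from the bacterial/plastid code (NCBI translation
table 11), whose sense-codon assignments are identical to the standard code.
Synonymous families partition the 59 synonymously variable sense codons:
Met (ATG) and Trp (TGG) are single-codon families and the three stop codons
are not sense codons, so none of those participate in RSCU families, Nc, or
GC3s.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

_TABLE = CodonTable.unambiguous_dna_by_id[11]

BASES = ("T", "C", "A", "G")

#: All 64 codons in TCAG order (the order codon-usage tables are printed in).
ALL_CODONS: tuple[str, ...] = tuple(
    b1 + b2 + b3 for b1 in BASES for b2 in BASES for b3 in BASES
)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA

#: Sense codon -> one-letter amino acid (61 entries).
CODON_TO_AA1: dict[str, str] = dict(_TABLE.forward_table)

#: Sense codon -> three-letter amino acid code.
CODON_TO_AA3: dict[str, str] = {c: seq3(a) for c, a in CODON_TO_AA1.items()}

SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)


def _build_families() -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = CODON_TO_AA1.get(codon)
        if aa is not None:
            fams.setdefault(aa, []).append(codon)
    return {aa: tuple(cs) for aa, cs in fams.items()}


#: One-letter amino acid -> member codons (all 20 amino acids).
FAMILIES: dict[str, tuple[str, ...]] = _build_families()

#: Degenerate families only (>= 2 synonyms): 18 amino acids, 59 codons.
#: Leu, Ser and Arg are kept as single six-fold families.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: cs for aa, cs in FAMILIES.items() if len(cs) > 1
}

#: The 59 synonymously variable codons, grouped family-by-family in a fixed
#: order (amino acids alphabetically by one-letter code, codons TCAG-ordered).
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for aa in sorted(SYNONYMOUS_FAMILIES) for c in SYNONYMOUS_FAMILIES[aa]
)

SINGLE_CODON_AA: dict[str, str] = {  # codon -> aa for the two 1-fold families
    c: aa for aa, cs in FAMILIES.items() if len(cs) == 1 for c in cs
}

#: Degeneracy class -> number of families in it (Wright's Nc bookkeeping).
#: 2-fold: Phe Tyr His Gln Asn Lys Asp Glu Cys; 3-fold: Ile;
#: 4-fold: Val Pro Thr Ala Gly; 6-fold: Leu Ser Arg.
DEGENERACY_CLASS_SIZES: dict[int, int] = {}
for _aa, _cs in SYNONYMOUS_FAMILIES.items():
    DEGENERACY_CLASS_SIZES[len(_cs)] = DEGENERACY_CLASS_SIZES.get(len(_cs), 0) + 1

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def reverse_complement(seq: str) -> str:
    """DNA reverse complement (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna(codon: str) -> str:
    """Normalise a codon to uppercase DNA (U -> T)."""
    return codon.upper().replace("U", "T")


def rna(codon: str) -> str:
    """Render a DNA codon in the RNA alphabet used in printed codon tables."""
    return codon.upper().replace("T", "U")


assert len(SYNONYMOUS_CODONS) == 59
assert DEGENERACY_CLASS_SIZES == {2: 9, 3: 1, 4: 5, 6: 3}
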