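"""Reading coding sequences and applying the gene-inclusion filter.

Genes enter the analysis from plain FASTA (one CDS per record) or from
GenBank flat files (CDS features, join- and strand-aware). Before any
codon-usage statistic is computed they pass a conservative inclusion filter:
more than ``min_codons`` codons in total (terminal stop included), a proper
start codon, a proper stop codon, no internal stop, and no ambiguous bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .genetic_code import STOP_CODONS

logger = logging.getLogger(__name__)

#: Default start codons: ATG plus the common bacterial alternatives.
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
DEFAULT_MIN_CODONS = 100

VALID_BASES = frozenset("ACGT")

# Rejection reason codes, in the order they are checked.
BAD_LENGTH = "BAD_LENGTH"
AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
TOO_SHORT = "TOO_SHORT"
BAD_START = "BAD_START"
BAD_STOP = "BAD_STOP"
INTERNAL_STOP = "INTERNAL_STOP"


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding sequence.

    Parameters
    ----------
    gene_id :
        Unique identifier within a dataset.
    genome :
        Genome/phage label the gene belongs to ("" when unknown).
    sequence :
        Uppercase DNA. Codon decomposition requires the length to be a
        multiple of 3; unfiltered records may violate this and are then
        rejected with ``BAD_LENGTH`` by :func:`filter_genes`.
    """

    gene_id: str
    genome: str
    sequence: str

    @property
    def is_codon_aligned(self) -> bool:
        return len(self.sequence) > 0 and len(self.sequence) % 3 == 0

    @property
    def codons(self) -> list[str]:
        """Ordered codon list; requires a codon-aligned sequence."""
        if len(self.sequence) % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id!r}: length {len(self.sequence)} "
                "is not a multiple of 3"
            )
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass
class FilterReport:
    """Outcome of :func:`filter_genes`: kept genes plus (id, reason) pairs."""

    kept: list[GeneRecord] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def rejection_reasons(self) -> set[str]:
        return {reason for _, reason in self.rejected}

    def write_rejects_tsv(self, handle: IO[str]) -> None:
        handle.write("gene_id\treason\n")
        for gene_id, reason in self.rejected:
            handle.write(f"{gene_id}\t{reason}\n")


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def parse_fasta(stream: Union[IO[str], str], genome: str = "") -> list[GeneRecord]:
    """Read one GeneRecord per FASTA record.

    Sequences are uppercased and U is mapped to T. Duplicate record ids
    raise ``ValueError`` naming the offending id.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene id {rec.id!r} in FASTA input")
        seen.add(rec.id)
        records.append(GeneRecord(rec.id, genome, _normalise(str(rec.seq))))
    return records


def write_fasta(genes: Iterable[GeneRecord], handle: IO[str]) -> None:
    """Write genes as FASTA, 70 columns, genome label in the description."""
    for g in genes:
        desc = f" genome={g.genome}" if g.genome else ""
        handle.write(f">{g.gene_id}{desc}\n")
        for i in range(0, len(g.sequence), 70):
            handle.write(g.sequence[i : i + 70] + "\n")


def _has_fuzzy_location(feature) -> bool:
    parts = (
        feature.location.parts
        if isinstance(feature.location, CompoundLocation)
        else [feature.location]
    )
    for part in parts:
        for pos in (part.start, part.end):
            if type(pos).__name__ in ("BeforePosition", "AfterPosition", "UnknownPosition"):
                return True
    return False


def extract_cds_genbank(stream: Union[IO[str], str]) -> list[GeneRecord]:
    """Extract CDS features from a GenBank flat file.

    Each CDS is spliced (join-aware) and strand-resolved (reverse-
    complemented when on the minus strand). Gene ids come from locus_tag,
    then protein_id, then a positional fallback; the genome label is the
    record's name. Fuzzy locations are skipped with a log entry; CDS whose
    length is not a multiple of 3 are kept here and rejected downstream.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "genbank"):
        n_cds = 0
        for feature in rec.features:
            if feature.type != "CDS":
                continue
            n_cds += 1
            qual = feature.qualifiers
            gene_id = (
                qual.get("locus_tag", [None])[0]
                or qual.get("protein_id", [None])[0]
                or f"{rec.name}_CDS{n_cds:04d}"
            )
            if gene_id in seen:
                gene_id = f"{gene_id}.{n_cds}"
            if _has_fuzzy_location(feature):
                logger.warning("skipping CDS %s: fuzzy location", gene_id)
                continue
            seq = _normalise(str(feature.location.extract(rec.seq)))
            seen.add(gene_id)
            genes.append(GeneRecord(gene_id, rec.name, seq))
    return genes


def filter_genes(
    records: Iterable[GeneRecord],
    min_codons: int = DEFAULT_MIN_CODONS,
    start_set: frozenset[str] = DEFAULT_START_CODONS,
    stop_set: frozenset[str] = frozenset(STOP_CODONS),
) -> FilterReport:
    """Apply the gene-inclusion filter.

    A gene is kept iff its codon count (terminal stop included) is strictly
    greater than ``min_codons``, its first codon is in ``start_set``, its
    last codon is in ``stop_set``, no internal codon is a stop, and every
    base is A/C/G/T. Failures are reported with the first failing reason in
    the fixed order BAD_LENGTH, AMBIGUOUS_BASE, TOO_SHORT, BAD_START,
    BAD_STOP, INTERNAL_STOP; filtering never raises.
    """
    report = FilterReport()
    for gene in records:
        reason = _rejection_reason(gene, min_codons, start_set, stop_set)
        if reason is None:
            report.kept.append(gene)
        else:
            report.rejected.append((gene.gene_id, reason))
    n = len(report.kept) + len(report.rejected)
    logger.info("filter_genes: kept %d / %d", len(report.kept), n)
    return report


def _rejection_reason(gene, min_codons, start_set, stop_set):
    if len(gene.sequence) == 0 or len(gene.sequence) % 3 != 0:
        return BAD_LENGTH
    if not VALID_BASES.issuperset(gene.sequence):
        return AMBIGUOUS_BASE
    codons = gene.codons
    if len(codons) <= min_codons:
        return TOO_SHORT
    if codons[0] not in start_set:
        return BAD_START
    if codons[-1] not in stop_set:
        return BAD_STOP
    if any(c in STOP_CODONS for c in codons[:-1]):
        return INTERNAL_STOP
    return None
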