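"""Synthetic coding-sequence datasets with controllable codon-usage bias.

The generator emulates the statistical structure the analysis assumes in a
multi-phage gene set: many genomes, gene lengths above the 100-codon
inclusion threshold, and two latent expression classes whose synonymous
codon choice is biased toward G/C-ending (and further toward C-ending)
codons. Within a family, codon ``c`` is drawn with probability proportional
to ``exp(beta_gc3 * [third base is G or C] + gamma_c * [third base is C])``;
amino acids are i.i.d. from a background distribution (by default the
pooled amino-acid frequencies of the bundled 32-phage reference table).
Genes always start with ATG, contain no internal stop, and end with a
uniformly chosen stop codon, so every generated gene passes the inclusion
filter by construction.

Default class parameters give the low class a mildly GC3-rich usage
(GC3s around 0.75, matching GC-rich phage backgrounds) and the high class
a strongly biased usage (GC3s around 0.93 with extra C-preference), so the
high class mimics putatively highly expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .gene_io import GeneRecord
from .genetic_code import FAMILIES, STOP_CODONS

HIGH = "high"
LOW = "low"

_STOPS = tuple(sorted(STOP_CODONS))


def _default_genomes() -> list[str]:
    return [f"phage{i:02d}" for i in range(1, 33)]


def _default_aa_freqs() -> dict[str, float]:
    from .datasets import amino_acid_frequencies

    return amino_acid_frequencies()


@dataclass
class SimSpec:
    """Parameters of a synthetic two-class gene set.

    beta_gc3 / gamma_c are per-class log-odds bonuses on the synonymous
    third base; lengths are total codon counts including start and stop,
    drawn uniformly from ``length_range`` (inclusive).
    """

    n_genes: int = 320
    genome_labels: list[str] = field(default_factory=_default_genomes)
    length_range: tuple[int, int] = (101, 600)
    high_fraction: float = 0.1
    beta_gc3: dict[str, float] = field(
        default_factory=lambda: {HIGH: 2.2, LOW: 1.0}
    )
    gamma_c: dict[str, float] = field(
        default_factory=lambda: {HIGH: 0.8, LOW: 0.2}
    )
    aa_freqs: Optional[dict[str, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] <= 100:
            raise ValueError("length_range minimum must exceed 100 codons")
        if not 0.0 <= self.high_fraction <= 1.0:
            raise ValueError("high_fraction must be in [0, 1]")
        if self.aa_freqs is None:
            self.aa_freqs = _default_aa_freqs()
        total = sum(self.aa_freqs.values())
        if not np.isclose(total, 1.0):
            self.aa_freqs = {a: p / total for a, p in self.aa_freqs.items()}


def codon_probabilities(spec: SimSpec, cls: str) -> dict[str, np.ndarray]:
    """Within-family codon probabilities for a class (softmax over bonuses)."""
    beta = spec.beta_gc3[cls]
    gamma = spec.gamma_c[cls]
    probs = {}
    for aa, codons in FAMILIES.items():
        w = np.array(
            [
                np.exp(beta * (c[2] in "GC") + gamma * (c[2] == "C"))
                for c in codons
            ]
        )
        probs[aa] = w / w.sum()
    return probs


def sample_gene(
    spec: SimSpec,
    cls: str,
    rng: np.random.Generator,
    gene_id: str = "g1",
    genome: str = "",
) -> GeneRecord:
    """Draw one gene: ATG + i.i.d. internal codons + uniform stop codon."""
    probs = codon_probabilities(spec, cls)
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    aas = list(spec.aa_freqs)
    aa_p = np.array([spec.aa_freqs[a] for a in aas])
    codons = ["ATG"]
    drawn = rng.choice(len(aas), size=length - 2, p=aa_p)
    for i in drawn:
        aa = aas[i]
        fam = FAMILIES[aa]
        codons.append(fam[rng.choice(len(fam), p=probs[aa])])
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    return GeneRecord(gene_id, genome, "".join(codons))


def generate_dataset(spec: SimSpec) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Generate ``n_genes`` genes plus a truth table.

    Genomes are assigned round-robin; ``round(high_fraction * n_genes)``
    genes are drawn with the high-class parameters, at positions chosen by
    a dedicated random stream. Each gene uses its own child stream derived
    from the spec seed, so the i-th gene is identical regardless of how
    many genes follow it.
    """
    class_rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(2**20,))
    )
    n_high = int(round(spec.high_fraction * spec.n_genes))
    high_idx = set(
        class_rng.choice(spec.n_genes, size=n_high, replace=False).tolist()
    )

    # per-gene substreams keyed by index: gene i never depends on n_genes
    children = [
        np.random.SeedSequence(spec.seed, spawn_key=(i,))
        for i in range(spec.n_genes)
    ]
    genes: list[GeneRecord] = []
    truth_rows = []
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        cls = HIGH if i in high_idx else LOW
        genome = spec.genome_labels[i % len(spec.genome_labels)]
        gene_id = f"gene{i + 1:0{width}d}"
        gene = sample_gene(
            spec, cls, np.random.default_rng(children[i]), gene_id, genome
        )
        genes.append(gene)
        syn3 = [c[2] for c in gene.codons[1:-1]]
        truth_rows.append(
            {
                "gene_id": gene_id,
                "genome": genome,
                "cls": cls,
                "length_codons": len(gene.codons),
                "gc3_fraction": sum(b in "GC" for b in syn3) / len(syn3),
            }
        )
    return genes, pd.DataFrame(truth_rows).set_index("gene_id")


def generate_malformed(spec: SimSpec) -> list[GeneRecord]:
    """Genes violating each inclusion-filter rule at least once.

    Every record fails exactly one rule, so filtering the output keeps
    nothing and every rejection reason code is observed. Deterministic
    under the spec seed.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(2**21,))
    )
    base = sample_gene(spec, LOW, rng, "mal_template")
    codons = base.codons  # valid: ATG ... stop, > 100 codons

    short = "".join(codons[:50]) + codons[-1]
    bad_start = "CCC" + "".join(codons[1:])
    bad_stop = "".join(codons[:-1]) + "AAA"
    internal = "".join(codons[:50]) + "TAA" + "".join(codons[51:])
    ambiguous = "ATGN" + base.sequence[4:]
    bad_length = base.sequence + "AC"

    seqs = {
        "mal_too_short": short,
        "mal_bad_start": bad_start,
        "mal_bad_stop": bad_stop,
        "mal_internal_stop": internal,
        "mal_ambiguous_base": ambiguous,
        "mal_bad_length": bad_length,
    }
    return [GeneRecord(gid, "malformed", s) for gid, s in seqs.items()]
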