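import io

import numpy as np
import pytest
from scipy import stats

from codonbias import (
    SimSpec,
    filter_genes,
    generate_dataset,
    generate_malformed,
    metrics_table,
    sample_gene,
    write_fasta,
)
from codonbias.genetic_code import FAMILIES, STOP_CODONS
from codonbias.synthetic_data import HIGH, LOW, codon_probabilities


class TestSampleGene:
    def test_structure(self):
        spec = SimSpec(n_genes=1, seed=0)
        g = sample_gene(spec, LOW, np.random.default_rng(0))
        codons = g.codons
        assert codons[0] == "ATG"
        assert codons[-1] in STOP_CODONS
        assert not any(c in STOP_CODONS for c in codons[:-1])
        assert 101 <= len(codons) <= 600

    def test_extreme_beta_forces_gc_ending(self):
        spec = SimSpec(
            n_genes=1, seed=0,
            beta_gc3={HIGH: 50.0, LOW: 0.0}, gamma_c={HIGH: 0.0, LOW: 0.0},
        )
        g = sample_gene(spec, HIGH, np.random.default_rng(1))
        for codon in g.codons[1:-1]:
            aa = next(a for a, cs in FAMILIES.items() if codon in cs)
            if len(FAMILIES[aa]) > 1 and any(c[2] in "GC" for c in FAMILIES[aa]):
                assert codon[2] in "GC"

    def test_zero_bias_family_usage_uniform(self):
        # long gene stream, null parameters: Leu codons near-uniform
        spec = SimSpec(
            n_genes=1, seed=0, length_range=(101, 101),
            beta_gc3={HIGH: 0.0, LOW: 0.0}, gamma_c={HIGH: 0.0, LOW: 0.0},
        )
        rng = np.random.default_rng(2)
        counts = {c: 0 for c in FAMILIES["L"]}
        for _ in range(120):
            for codon in sample_gene(spec, LOW, rng).codons[1:-1]:
                if codon in counts:
                    counts[codon] += 1
        observed = np.array(list(counts.values()))
        _, p = stats.chisquare(observed)
        assert p > 0.001


class TestGenerateDataset:
    def test_bookkeeping(self):
        spec = SimSpec(n_genes=200, seed=1, high_fraction=0.1)
        genes, truth = generate_dataset(spec)
        assert len(genes) == len(truth) == 200
        assert (truth["cls"] == HIGH).sum() == 20
        assert truth["genome"].nunique() == 32

    def test_all_generated_genes_pass_filter(self, default_dataset):
        _, genes, _ = default_dataset
        report = filter_genes(genes)
        assert len(report.kept) == len(genes)

    def test_byte_identical_fasta_across_runs(self):
        outputs = []
        for _ in range(2):
            genes, _ = generate_dataset(SimSpec(n_genes=30, seed=9))
            buf = io.StringIO()
            write_fasta(genes, buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_early_genes_stable_under_larger_n(self):
        small, _ = generate_dataset(SimSpec(n_genes=10, seed=3, high_fraction=0.0))
        large, _ = generate_dataset(SimSpec(n_genes=20, seed=3, high_fraction=0.0))
        assert [g.sequence for g in small] == [g.sequence for g in large[:10]]

    def test_high_class_more_biased(self):
        """Mean Nc of the high-bias class is below the low class."""
        spec = SimSpec(
            n_genes=120, seed=42,
            beta_gc3={HIGH: 1.5, LOW: 0.3}, gamma_c={HIGH: 0.0, LOW: 0.0},
        )
        genes, truth = generate_dataset(spec)
        m = metrics_table(genes)
        mean_nc = m["nc"].groupby(truth["cls"]).mean()
        assert mean_nc[HIGH] < mean_nc[LOW]

    def test_codon_distribution_matches_softmax_target(self):
        """Realized within-family codon fractions match the specified
        softmax probabilities (pooled goodness-of-fit over ~50k codons)."""
        spec = SimSpec(n_genes=150, seed=0, high_fraction=0.0,
                       length_range=(300, 400))
        genes, _ = generate_dataset(spec)
        probs = codon_probabilities(spec, LOW)
        counts: dict[str, int] = {}
        for g in genes:
            for codon in g.codons[1:-1]:
                counts[codon] = counts.get(codon, 0) + 1
        assert sum(counts.values()) >= 40_000
        chi2_total, df_total = 0.0, 0
        for aa, codons in FAMILIES.items():
            if len(codons) < 2:
                continue
            obs = np.array([counts.get(c, 0) for c in codons], dtype=float)
            if obs.sum() < 50:
                continue
            exp = probs[aa] * obs.sum()
            chi2_total += ((obs - exp) ** 2 / exp).sum()
            df_total += len(codons) - 1
        p = stats.chi2.sf(chi2_total, df_total)
        assert p > 0.001

    def test_gc3s_increases_with_beta(self):
        """Realized mean GC3s is strictly increasing over a beta sweep."""
        means = []
        for beta in (0.0, 0.5, 1.0, 1.5, 2.0):
            spec = SimSpec(
                n_genes=25, seed=4, high_fraction=0.0,
                beta_gc3={HIGH: beta, LOW: beta},
                gamma_c={HIGH: 0.0, LOW: 0.0},
            )
            _, truth = generate_dataset(spec)
            means.append(truth["gc3_fraction"].mean())
        assert all(a < b for a, b in zip(means, means[1:]))


class TestGenerateMalformed:
    def test_fully_rejected_with_full_reason_coverage(self):
        records = generate_malformed(SimSpec(n_genes=1, seed=5))
        report = filter_genes(records)
        assert report.kept == []
        assert report.rejection_reasons() == {
            "TOO_SHORT", "BAD_START", "BAD_STOP",
            "INTERNAL_STOP", "AMBIGUOUS_BASE", "BAD_LENGTH",
        }

    def test_deterministic(self):
        a = generate_malformed(SimSpec(n_genes=1, seed=5))
        b = generate_malformed(SimSpec(n_genes=1, seed=5))
        assert [g.sequence for g in a] == [g.sequence for g in b]


def test_spec_validation():
    with pytest.raises(ValueError):
        SimSpec(length_range=(90, 200))
    with pytest.raises(ValueError):
        SimSpec(high_fraction=1.5)
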