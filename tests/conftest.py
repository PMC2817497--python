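import math

import numpy as np
import pytest

from codonbias import SimSpec, filter_genes, generate_dataset, metrics_table
from codonbias.codon_metrics import CodonCountTable
from codonbias.genetic_code import SYNONYMOUS_FAMILIES


@pytest.fixture(scope="session")
def default_dataset():
    """Two-class synthetic dataset at generator defaults (seed 42)."""
    spec = SimSpec(n_genes=200, seed=42)
    genes, truth = generate_dataset(spec)
    return spec, genes, truth


@pytest.fixture(scope="session")
def default_metrics(default_dataset):
    _, genes, _ = default_dataset
    kept = filter_genes(genes).kept
    return kept, metrics_table(kept)


def wright_nc_oracle(codons):
    """Brute-force Wright Nc from a raw codon list.

    Independent of the package: per-family homozygosity
    F = (n * sum(p^2) - 1) / (n - 1) from scratch counts, class means over
    families with n >= 2, Ile class interpolated as (F2 + F4) / 2 when
    missing or zero, Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 capped at 61.
    """
    means = {}
    for k in (2, 3, 4, 6):
        fs = []
        for aa, members in SYNONYMOUS_FAMILIES.items():
            if len(members) != k:
                continue
            counts = [sum(1 for c in codons if c == m) for m in members]
            n = sum(counts)
            if n < 2:
                continue
            f = (n * sum((x / n) ** 2 for x in counts) - 1) / (n - 1)
            fs.append(f)
        means[k] = sum(fs) / len(fs) if fs else math.nan
    if math.isnan(means[3]) or means[3] <= 0:
        means[3] = (means[2] + means[4]) / 2
    nc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(nc, 61.0)


def ca_eigen_oracle(X):
    """Brute-force chi-square-metric CA by dense eigendecomposition.

    Returns (row_coords, col_coords, inertia_fractions) with axis signs
    unfixed; compares against the SVD route in the package.
    """
    X = np.asarray(X, dtype=float)
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, V = np.linalg.eigh(S.T @ S)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    V = V[:, order]
    sv = np.sqrt(evals)
    nonzero = sv > 1e-12 * sv[0]
    U = np.zeros((S.shape[0], V.shape[1]))
    U[:, nonzero] = (S @ V[:, nonzero]) / sv[nonzero]
    row = (U * sv) / np.sqrt(r)[:, None]
    col = (V * sv) / np.sqrt(c)[:, None]
    inertia = evals[nonzero] / evals[nonzero].sum()
    return row, col, inertia


def random_gene_codons(rng, n_codons=300):
    """Random sense-codon list (uniform over the 59 synonymous codons)."""
    from codonbias.genetic_code import SYNONYMOUS_CODONS

    idx = rng.integers(0, len(SYNONYMOUS_CODONS), size=n_codons)
    return [SYNONYMOUS_CODONS[i] for i in idx]


def table_from_codons(codons):
    return CodonCountTable.from_mapping(
        {c: codons.count(c) for c in set(codons)}
    )
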