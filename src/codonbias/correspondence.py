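"""Correspondence analysis of the gene x RSCU matrix.

Codon-usage trends across genes are summarised by classical correspondence
analysis (CA) under the chi-square metric: the 59-column RSCU matrix (sense
codons minus Met and Trp) is scaled to proportions, the standardized
residual matrix D_r^{-1/2} (P - r c^T) D_c^{-1/2} is decomposed by singular
values, and genes/codons receive principal coordinates; each axis carries a
fraction sigma_i^2 / sum sigma_j^2 of the total inertia. RSCU (rather than
raw counts) is used so amino-acid composition contributes as little as
possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .codon_metrics import CodonCountTable, rscu
from .gene_io import GeneRecord
from .genetic_code import SYNONYMOUS_CODONS

logger = logging.getLogger(__name__)

#: Singular values below this fraction of the largest are treated as zero.
SV_RTOL = 1e-12


def build_rscu_matrix(genes: Iterable[GeneRecord]) -> pd.DataFrame:
    """Per-gene RSCU over the 59 synonymously variable codons.

    Rows are genes (index gene_id), columns the 59 codons in fixed order.
    Families absent from a gene contribute 0 for all their members.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("correspondence analysis requires at least 2 genes")
    rows = {}
    for g in genes:
        values = rscu(CodonCountTable.from_gene(g))
        rows[g.gene_id] = [values[c] for c in SYNONYMOUS_CODONS]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(SYNONYMOUS_CODONS)
    )


@dataclass
class CAResult:
    """Row/column principal coordinates and per-axis inertia fractions."""

    row_coords: pd.DataFrame  # genes x n_axes
    col_coords: pd.DataFrame  # codons x n_axes
    inertia_fraction: np.ndarray
    n_axes: int

    def axis(self, i: int = 1) -> pd.Series:
        """Row coordinates on axis ``i`` (1-based)."""
        return self.row_coords[f"axis{i}"]


def correspondence_axes(
    matrix: pd.DataFrame,
    n_axes: int = 4,
    orient_by: Optional[pd.Series] = None,
) -> CAResult:
    """Chi-square-metric CA of a nonnegative data matrix.

    Parameters
    ----------
    matrix :
        Genes x codons nonnegative table (typically RSCU values).
    n_axes :
        Number of axes to return (truncated to the available rank).
    orient_by :
        Optional per-gene values (typically Nc) used to fix the sign of
        axis 1 so that its correlation with these values is non-negative;
        this reproduces the convention in which A/T-ending, high-Nc genes
        sit on the positive side. Other axes (and axis 1 when ``orient_by``
        is absent) are oriented so the largest-magnitude column loading is
        positive, making results deterministic.

    Zero-sum columns are dropped with a log entry; a matrix of identical
    rows yields zero inertia and all-zero coordinates.
    """
    X = matrix.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("CA requires a nonnegative matrix")
    col_ok = X.sum(axis=0) > 0
    if not col_ok.all():
        dropped = list(matrix.columns[~col_ok])
        logger.info("correspondence_axes: dropping %d zero-sum columns: %s",
                    len(dropped), dropped)
        matrix = matrix.loc[:, col_ok]
        X = X[:, col_ok]
    if X.sum() == 0:
        raise ValueError("CA requires a matrix with positive total")

    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    rank = int(np.sum(sv > SV_RTOL * sv[0])) if sv.size and sv[0] > 0 else 0
    n_axes = max(1, min(n_axes, max(rank, 1)))
    total_inertia = float(np.sum(sv[:rank] ** 2))

    if rank == 0:
        # No variation at all: every axis is degenerate.
        row = np.zeros((X.shape[0], n_axes))
        col = np.zeros((X.shape[1], n_axes))
        inertia = np.zeros(n_axes)
    else:
        U = U[:, :n_axes]
        V = Vt[:n_axes].T
        sv_used = sv[:n_axes]
        row = (U * sv_used) / np.sqrt(r)[:, None]
        col = (V * sv_used) / np.sqrt(c)[:, None]
        inertia = sv_used**2 / total_inertia
        # zero out axes beyond the rank
        row[:, rank:] = 0.0
        col[:, rank:] = 0.0
        inertia[rank:] = 0.0
        for j in range(min(n_axes, rank)):
            sign = 1.0
            if np.max(np.abs(col[:, j])) > 0:
                sign = np.sign(col[np.argmax(np.abs(col[:, j])), j])
            row[:, j] *= sign
            col[:, j] *= sign

    axes = [f"axis{i + 1}" for i in range(n_axes)]
    result = CAResult(
        row_coords=pd.DataFrame(row, index=matrix.index, columns=axes),
        col_coords=pd.DataFrame(col, index=matrix.columns, columns=axes),
        inertia_fraction=inertia,
        n_axes=n_axes,
    )
    if orient_by is not None and rank > 0:
        _orient_axis1(result, orient_by)
    return result


def _orient_axis1(result: CAResult, values: pd.Series) -> None:
    """Flip axis 1 so its correlation with ``values`` (e.g. Nc) is >= 0."""
    joined = pd.concat(
        [result.row_coords["axis1"], values.rename("v")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        return
    x = joined["axis1"].to_numpy()
    v = joined["v"].to_numpy()
    if x.std() == 0 or v.std() == 0:
        return
    if np.corrcoef(x, v)[0, 1] < 0:
        result.row_coords["axis1"] *= -1
        result.col_coords["axis1"] *= -1
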