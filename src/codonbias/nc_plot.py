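"""The Nc plot: observed Nc against GC3s versus the no-selection curve.

Under pure compositional (mutational) bias, a gene's effective number of
codons is a function of its third-position G+C alone:

    Nc*(s) = 2 + s + 29 / (s^2 + (1 - s)^2),    0 <= s <= 1.

Genes lying well below the curve carry codon-usage bias beyond what their
base composition explains (e.g. translational selection).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import IO

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def expected_nc(s: float) -> float:
    """Expected Nc under no selection at third-position G+C fraction ``s``."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass(frozen=True)
class NcPlotRow:
    gene_id: str
    gc3s: float
    nc_observed: float
    nc_expected: float

    @property
    def deviation(self) -> float:
        return self.nc_observed - self.nc_expected


def ncplot_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: gc3s, observed Nc, expected Nc, deviation.

    ``metrics`` is the per-gene table from :func:`codon_metrics.metrics_table`
    (index gene_id, columns including ``nc`` and ``gc3s``). Genes whose Nc
    or GC3s is undefined are skipped with a log entry.
    """
    usable = metrics.dropna(subset=["nc", "gc3s"])
    n_skipped = len(metrics) - len(usable)
    if n_skipped:
        logger.info("ncplot_table: skipped %d genes with undefined Nc/GC3s", n_skipped)
    out = pd.DataFrame(
        {
            "gc3s": usable["gc3s"],
            "nc_observed": usable["nc"],
            "nc_expected": [expected_nc(s) for s in usable["gc3s"]],
        }
    )
    out["deviation"] = out["nc_observed"] - out["nc_expected"]
    return out


def curve_sample(step: float = 0.01) -> pd.DataFrame:
    """Dense sample of the no-selection curve for plotting."""
    s = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return pd.DataFrame({"gc3s": s, "nc_expected": [expected_nc(x) for x in s]})


def write_ncplot_tsv(table: pd.DataFrame, handle: IO[str]) -> None:
    table.to_csv(handle, sep="\t", float_format="%.4f")
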