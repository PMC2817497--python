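"""End-to-end pipeline: filter -> indices -> CA -> contrast -> screens -> tRNA.

`run_pipeline` chains every stage on a set of coding sequences and writes
the full family of TSV outputs (pooled codon-usage table, per-genome
summaries, Nc-plot rows, CA coordinates and inertia, extreme-group contrast
table, association screens, optional tRNA match report) plus a JSON
manifest with the configuration echo and gene bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .association_stats import correlation_screens
from .codon_metrics import (
    CodonCountTable,
    metrics_table,
    pooled_rscu_table,
)
from .contrast import (
    codon_chi_square,
    extreme_groups,
    overrepresentation_summary,
)
from .correspondence import build_rscu_matrix, correspondence_axes
from .gene_io import (
    DEFAULT_MIN_CODONS,
    DEFAULT_START_CODONS,
    GeneRecord,
    filter_genes,
)
from .nc_plot import curve_sample, ncplot_table
from .trna_match import codons_recognized, match_report, read_inventory_tsv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: Path = Path("codonbias_out")
    min_codons: int = DEFAULT_MIN_CODONS
    start_set: frozenset[str] = DEFAULT_START_CODONS
    ca_axes: int = 4
    extreme_fraction: float = 0.10
    alpha: float = 0.01
    wobble_mode: str = "crick"
    trna_inventory: Optional[Path] = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.extreme_fraction <= 0.5:
            raise ValueError("extreme_fraction must be in (0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        self.out_dir = Path(self.out_dir)

    def digest(self) -> str:
        # out_dir excluded: table content must not depend on destination
        payload = {
            k: sorted(v) if isinstance(v, frozenset) else str(v)
            for k, v in self.__dict__.items()
            if k != "out_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, config_hash: str, **kwargs) -> None:
    with open(path, "w") as handle:
        handle.write(f"# config={config_hash}\n")
        df.to_csv(handle, sep="\t", float_format="%.4f", **kwargs)


def run_pipeline(
    genes: Sequence[GeneRecord], config: RunConfig
) -> dict:
    """Run every stage on ``genes`` and write TSVs under ``config.out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    h = config.digest()

    report = filter_genes(genes, config.min_codons, config.start_set)
    kept = report.kept
    if len(kept) < 2:
        raise RuntimeError(
            f"filter stage: only {len(kept)} genes passed the filter; "
            "need at least 2"
        )
    with open(out / "rejected_genes.tsv", "w") as fh:
        fh.write(f"# config={h}\n")
        report.write_rejects_tsv(fh)

    metrics = metrics_table(kept)
    _write(metrics, out / "gene_metrics.tsv", h)

    pooled = CodonCountTable.from_genes(kept)
    _write(pooled_rscu_table(pooled), out / "pooled_rscu.tsv", h, index=False)

    genome_summary = (
        metrics.groupby("genome")[["nc", "gc3s", "gc", "gc1", "gc2",
                                   "a3s", "t3s", "g3s", "c3s"]]
        .agg(["mean", "std"])
    )
    genome_summary.columns = ["_".join(c) for c in genome_summary.columns]
    _write(genome_summary, out / "genome_summary.tsv", h)

    _write(ncplot_table(metrics), out / "ncplot.tsv", h)
    _write(curve_sample(), out / "ncplot_curve.tsv", h, index=False)

    matrix = build_rscu_matrix(kept)
    ca = correspondence_axes(matrix, config.ca_axes, orient_by=metrics["nc"])
    _write(ca.row_coords, out / "ca_gene_coords.tsv", h)
    _write(ca.col_coords, out / "ca_codon_coords.tsv", h)
    _write(
        pd.DataFrame(
            {"axis": range(1, ca.n_axes + 1),
             "inertia_fraction": ca.inertia_fraction}
        ),
        out / "ca_inertia.tsv", h, index=False,
    )

    left_ids, right_ids = extreme_groups(ca, config.extreme_fraction)
    by_id = {g.gene_id: g for g in kept}
    pool_left = CodonCountTable.from_genes(by_id[g] for g in left_ids)
    pool_right = CodonCountTable.from_genes(by_id[g] for g in right_ids)
    contrast = codon_chi_square(pool_left, pool_right, config.alpha)
    _write(contrast.table, out / "contrast.tsv", h)
    groups = pd.DataFrame(
        [{"gene_id": g, "group": "left"} for g in left_ids]
        + [{"gene_id": g, "group": "right"} for g in right_ids]
    )
    _write(groups, out / "extreme_groups.tsv", h, index=False)
    over_by_base = overrepresentation_summary(contrast)

    screens = correlation_screens(metrics, ca.axis(1))
    _write(screens, out / "association_screens.tsv", h, index=False)

    trna_summary = None
    if config.trna_inventory is not None:
        with open(config.trna_inventory) as fh:
            inventory = read_inventory_tsv(fh)
        recognized = codons_recognized(inventory, config.wobble_mode)
        match = match_report(contrast.called(), recognized)
        with open(out / "trna_match.tsv", "w") as fh:
            fh.write(f"# config={h}\n")
            from .trna_match import write_match_tsv

            write_match_tsv(match, fh)
        trna_summary = {
            "n_matched": match.n_matched,
            "n_unmatched": match.n_unmatched,
        }

    manifest = {
        "codonbias_version": __version__,
        "config": {
            k: sorted(v) if isinstance(v, frozenset) else str(v)
            for k, v in config.__dict__.items()
        },
        "config_hash": h,
        "n_input": len(genes),
        "n_kept": len(kept),
        "n_rejected": len(report.rejected),
        "n_metrics_rows": len(metrics),
        "n_ca_rows": len(ca.row_coords),
        "inertia_fraction": [float(x) for x in ca.inertia_fraction],
        "extreme_group_size": len(left_ids),
        "n_over_left": len(contrast.called()),
        "over_left_by_third_base": over_by_base,
        "trna": trna_summary,
    }
    assert manifest["n_kept"] + manifest["n_rejected"] == manifest["n_input"]
    assert manifest["n_metrics_rows"] == manifest["n_ca_rows"] == manifest["n_kept"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d/%d genes kept", len(kept), len(genes))
    return manifest
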