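"""Cell- and cluster-level quality control.

Three negative indicators of cell quality are evaluated: low total counts,
low gene count (≤ 1,000 by default) and high mitochondrial content (≥ 0.2
by default).  A cell is low quality when **more than one** indicator fires.
"Low total counts" carries no published numeric threshold; the default is
the 5th percentile of per-sample library sizes.  Ribosomal fraction is
reported alongside but is not an indicator.

Quality is then assessed at the cluster level: clusters dominated by
flagged cells, or by cells expressing a contaminant gene, are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class QCThresholds:
    min_genes: int = 1000
    max_mito: float = 0.2
    low_counts_percentile: float = 5.0
    min_indicators_to_flag: int = 2

    def __post_init__(self) -> None:
        if self.min_genes <= 0 or self.max_mito <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_indicators_to_flag < 1:
            raise ValueError("min_indicators_to_flag must be ≥ 1")
        if not 0 < self.low_counts_percentile < 100:
            raise ValueError("low_counts_percentile must lie in (0, 100)")


def qc_flag_cells(
    obs: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Evaluate the three negative indicators and the low-quality flag.

    ``obs`` needs columns ``total_counts``, ``n_genes`` and
    ``mito_fraction``; an optional ``sample`` column scopes the
    low-total-counts percentile per sample.  Returns a copy with boolean
    columns ``ind_low_counts``, ``ind_low_genes``, ``ind_high_mito``, the
    integer ``n_indicators`` and the ``low_quality`` flag.
    """
    thresholds = thresholds or QCThresholds()
    out = obs.copy()
    if "sample" in out.columns:
        cutoff = out.groupby("sample")["total_counts"].transform(
            lambda s: np.percentile(s, thresholds.low_counts_percentile)
        )
    else:
        cutoff = np.percentile(out["total_counts"], thresholds.low_counts_percentile)
    out["ind_low_counts"] = out["total_counts"] < cutoff
    out["ind_low_genes"] = out["n_genes"] <= thresholds.min_genes
    out["ind_high_mito"] = out["mito_fraction"] >= thresholds.max_mito
    out["n_indicators"] = (
        out[["ind_low_counts", "ind_low_genes", "ind_high_mito"]].sum(axis=1)
    )
    out["low_quality"] = out["n_indicators"] >= thresholds.min_indicators_to_flag
    return out


def exclude_low_quality_clusters(
    counts: np.ndarray,
    gene_names: list[str] | pd.Index,
    obs: pd.DataFrame,
    contaminant_genes: list[str] = (),
    majority_fraction: float = 0.5,
    contaminant_fraction: float = 0.5,
    cluster_key: str = "cluster",
    flag_key: str = "low_quality",
) -> pd.DataFrame:
    """Per-cluster keep/drop decisions.

    A cluster is dropped when more than ``majority_fraction`` of its cells
    are flagged low quality, or more than ``contaminant_fraction`` of its
    cells express (count > 0) any contaminant gene.  Unknown contaminant
    gene names raise a warning and are ignored.  Returns one row per
    cluster with the offending fractions, the ``keep`` decision and the
    overall percentage of retained cells in ``attrs``-style column
    ``retained_cell_pct`` (identical on every row).
    """
    counts = np.asarray(counts)
    gene_index = pd.Index(gene_names)
    cont_idx = []
    for g in contaminant_genes:
        if g in gene_index:
            cont_idx.append(gene_index.get_loc(g))
        else:
            warnings.warn(f"contaminant gene {g!r} not found; ignored", stacklevel=2)
    rows = []
    for cluster, grp in obs.groupby(cluster_key, observed=True):
        idx = obs.index.get_indexer(grp.index)
        flag_frac = float(grp[flag_key].mean())
        cont_frac = 0.0
        if cont_idx:
            expr = counts[np.ix_(idx, cont_idx)] > 0
            cont_frac = float(expr.any(axis=1).mean())
        keep = not (flag_frac > majority_fraction or cont_frac > contaminant_fraction)
        rows.append(
            {
                "cluster": cluster,
                "n_cells": len(grp),
                "flagged_fraction": flag_frac,
                "contaminant_fraction": cont_frac,
                "keep": keep,
            }
        )
    table = pd.DataFrame(rows)
    kept = table.loc[table["keep"], "n_cells"].sum()
    table["retained_cell_pct"] = 100.0 * kept / max(table["n_cells"].sum(), 1)
    return table
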