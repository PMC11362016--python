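"""Epithelial–mesenchymal axis: anchor-ranked ordering and E/M quadrants.

Cells are ordered by descending expression of an epithelial anchor gene
(cadherin-1, *Cdh1*, by default) and placed in the *Cdh1*/*Vim* plane.
Per-cell epithelial (E) and mesenchymal (M) scores are the mean expression
of the respective gene sets; quadrant membership uses simple detection
thresholds on the anchor and *Vim* (expressed vs not).  A partial-EMT
state shows up as the low-E/high-M quadrant ("E-M+").
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def emt_axis(
    normalized: np.ndarray,
    gene_names,
    epithelial_set: list[str],
    mesenchymal_set: list[str],
    anchor: str = "Cdh1",
    vim: str = "Vim",
    anchor_threshold: float = 0.0,
    vim_threshold: float = 0.0,
) -> pd.DataFrame:
    """Order cells along the EMT axis and classify E/M quadrants.

    Returns one row per cell with ``anchor_expr``, ``vim_expr``,
    ``e_score``, ``m_score``, the 0-based ``rank`` (0 = highest anchor
    expression; ties broken by input order) and ``quadrant`` in
    {"E+M+", "E+M-", "E-M+", "E-M-"}.
    """
    X = np.asarray(normalized, dtype=float)
    gene_index = pd.Index(gene_names)
    for g in (anchor, vim):
        if g not in gene_index:
            raise KeyError(f"required gene {g!r} missing from the matrix")

    def _set_mean(genes: list[str]) -> np.ndarray:
        idx = [gene_index.get_loc(g) for g in genes if g in gene_index]
        if not idx:
            return np.zeros(X.shape[0])
        return X[:, idx].mean(axis=1)

    anchor_expr = X[:, gene_index.get_loc(anchor)]
    vim_expr = X[:, gene_index.get_loc(vim)]
    order = np.argsort(-anchor_expr, kind="mergesort")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    e_side = np.where(anchor_expr > anchor_threshold, "E+", "E-")
    m_side = np.where(vim_expr > vim_threshold, "M+", "M-")
    return pd.DataFrame(
        {
            "anchor_expr": anchor_expr,
            "vim_expr": vim_expr,
            "e_score": _set_mean(epithelial_set),
            "m_score": _set_mean(mesenchymal_set),
            "rank": rank,
            "quadrant": np.char.add(e_side.astype(str), m_side.astype(str)),
        }
    )
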