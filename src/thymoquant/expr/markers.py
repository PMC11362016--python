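"""One-vs-rest Wilcoxon rank-sum marker ranking with BH-FDR adjustment.

For each subset, every gene is tested group-vs-rest with the tie-corrected
normal approximation to the rank-sum statistic; the z-score's sign gives
the direction (positive = higher in the subset).  P values are two-sided
and Benjamini–Hochberg adjusted across genes within each comparison.  No
fold-change filter is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _rank_sum_z(X: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected rank-sum z per gene (columns of X)."""
    n = X.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = stats.rankdata(X, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # permutation variance with tie correction: n1·n2/12 · ((n+1) − ΣT/(n(n−1)))
    tie_term = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (r1 - mu) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def rank_markers(
    normalized: np.ndarray,
    labels,
    alpha: float = 0.05,
    gene_names=None,
) -> pd.DataFrame:
    """Rank genes per subset by one-vs-rest rank-sum z.

    Parameters
    ----------
    normalized
        Cells × genes expression (typically CP10K/log1p).
    labels
        Per-cell subset labels; at least two distinct labels and ≥2 cells
        per compared group are required.
    alpha
        FDR level recorded in the ``significant`` column.

    Returns
    -------
    DataFrame with one row per (subset, gene): ``z``, ``p``, ``q`` (BH
    within the comparison), ``direction`` and ``significant``.
    """
    X = np.asarray(normalized, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct labels")
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(X.shape[1])]
    gene_names = np.asarray(gene_names)

    frames = []
    for subset in uniq:
        in_group = labels == subset
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            raise ValueError(f"group {subset!r} needs ≥2 cells on each side")
        z = _rank_sum_z(X, in_group)
        p = 2.0 * stats.norm.sf(np.abs(z))
        _, q, _, _ = multipletests(p, method="fdr_bh")
        frames.append(
            pd.DataFrame(
                {
                    "subset": subset,
                    "gene": gene_names,
                    "z": z,
                    "p": p,
                    "q": q,
                    "direction": np.where(z >= 0, "up", "down"),
                    "significant": q <= alpha,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
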