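"""Signature construction, reference-subtracted scoring and subset mapping.

A subset signature is its top-N marker genes (FDR ≤ 0.05, sorted by
descending rank-sum z, ties broken by gene name).  A cell's signature
score is the mean expression of the signature genes minus the mean of a
control set sampled from expression-matched bins — so a score near zero
means "no enrichment over expression-matched background".  Cells or spots
are mapped to the subset with the highest score; exact ties are left
unassigned.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"


def build_signatures(
    markers: pd.DataFrame, n: int = 20, alpha: float = 0.05
) -> dict[str, list[str]]:
    """Top-``n`` FDR-passing up-regulated genes per subset, by descending z.

    Subsets with zero passing genes yield an empty list with a warning.
    """
    signatures: dict[str, list[str]] = {}
    for subset, grp in markers.groupby("subset", observed=True, sort=False):
        passing = grp[(grp["q"] <= alpha) & (grp["z"] > 0)]
        ordered = passing.sort_values(
            ["z", "gene"], ascending=[False, True], kind="mergesort"
        )
        genes = ordered["gene"].head(n).tolist()
        if not genes:
            warnings.warn(f"subset {subset!r} has no FDR-passing genes", stacklevel=2)
        signatures[str(subset)] = genes
    return signatures


def _expression_bins(gene_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size bins of genes ranked by mean expression (ties share a bin)."""
    from scipy.stats import rankdata

    ranks = rankdata(gene_means, method="average") - 1.0
    return np.minimum((ranks * n_bins / len(gene_means)).astype(int), n_bins - 1)


def score_signature(
    normalized: np.ndarray,
    gene_names,
    signature: list[str],
    n_bins: int = 25,
    ctrl_per_gene: int = 50,
    seed: int = 0,
    reference: list[str] | None = None,
) -> np.ndarray:
    """Per-cell reference-subtracted signature score.

    score = mean(signature genes) − mean(control genes), where controls are
    sampled uniformly (``ctrl_per_gene`` per signature gene, without the
    signature genes themselves) from the expression-matched bin of each
    signature gene; the control set is the union of samples.  Deterministic
    under ``seed``.  Passing ``reference`` fixes the control set explicitly
    (used for oracle comparisons).

    Missing signature genes are dropped with a warning; an empty signature
    after filtering raises.
    """
    X = np.asarray(normalized, dtype=float)
    gene_index = pd.Index(gene_names)
    present = [g for g in signature if g in gene_index]
    dropped = set(signature) - set(present)
    if dropped:
        warnings.warn(f"signature genes not found: {sorted(dropped)}", stacklevel=2)
    if not present:
        raise ValueError("signature is empty after removing missing genes")
    sig_idx = np.asarray([gene_index.get_loc(g) for g in present])

    if reference is not None:
        ctrl_idx = np.asarray([gene_index.get_loc(g) for g in reference])
    else:
        rng = np.random.default_rng(seed)
        bins = _expression_bins(X.mean(axis=0), n_bins)
        sig_set = set(sig_idx.tolist())
        ctrl: set[int] = set()
        for gi in sig_idx:
            pool = np.flatnonzero(bins == bins[gi])
            pool = pool[~np.isin(pool, sig_idx)]
            if len(pool) == 0:
                continue
            take = min(ctrl_per_gene, len(pool))
            ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
        ctrl -= sig_set
        if not ctrl:
            raise ValueError("no control genes available outside the signature")
        ctrl_idx = np.asarray(sorted(ctrl))

    return X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def score_signature_set(
    normalized: np.ndarray,
    gene_names,
    signatures: dict[str, list[str]],
    n_bins: int = 25,
    ctrl_per_gene: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every signature; one column per subset."""
    cols = {}
    for i, (subset, genes) in enumerate(signatures.items()):
        cols[subset] = score_signature(
            normalized, gene_names, genes,
            n_bins=n_bins, ctrl_per_gene=ctrl_per_gene, seed=seed + i,
        )
    return pd.DataFrame(cols)


def map_subsets(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each cell/spot the argmax-score subset; exact ties → unassigned.

    Returns columns ``assignment``, ``top_score`` and ``margin`` (top minus
    runner-up; equals 0 on a tie).
    """
    if scores.shape[1] < 1:
        raise ValueError("need at least one signature score column")
    vals = scores.to_numpy(dtype=float)
    order = np.argsort(vals, axis=1)
    top = vals[np.arange(len(vals)), order[:, -1]]
    runner = vals[np.arange(len(vals)), order[:, -2]] if vals.shape[1] > 1 else np.full(len(vals), -np.inf)
    margin = top - runner
    names = scores.columns.to_numpy()
    assignment = names[order[:, -1]].astype(object)
    assignment[margin == 0] = UNASSIGNED
    return pd.DataFrame(
        {"assignment": assignment, "top_score": top, "margin": margin},
        index=scores.index,
    )
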