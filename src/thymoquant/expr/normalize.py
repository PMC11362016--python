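"""Library-size normalization to counts-per-10k with log1p transform."""

from __future__ import annotations

import numpy as np
from scipy import sparse

TARGET_SUM = 10_000.0


def normalize_log1p(counts, target_sum: float = TARGET_SUM) -> np.ndarray:
    """CP10K + log1p: ``log(1 + target_sum × count / total)`` (natural log).

    ``counts`` is cells × genes (dense or sparse); returns a dense float
    array.  The per-cell identity ``Σ_g (exp(v) − 1) = target_sum`` holds
    exactly up to floating point.

    Raises
    ------
    ValueError
        If any cell has a zero total count (lists the offending rows).
    """
    X = counts.toarray() if sparse.issparse(counts) else np.asarray(counts, dtype=float)
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(f"cells with zero total counts: {zero.tolist()[:20]}")
    return np.log1p(target_sum * X / totals[:, None])
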