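"""Scaled per-subset frequency change between two age conditions."""

from __future__ import annotations

import numpy as np
import pandas as pd


def scaled_frequency_change(
    frequencies: pd.DataFrame,
    young: str = "young",
    aged: str = "aged",
) -> pd.Series:
    """Per-subset frequency change, scaled by the largest absolute change.

    ``frequencies`` has one row per subset and one column per condition;
    each column (a within-compartment composition) must sum to 1.  The
    change ``f_aged − f_young`` is divided by the maximum absolute change
    across subsets, yielding values in [−1, 1]; if every change is zero,
    zeros are returned unscaled.  The scaling is a reconstruction of a
    graphical summary and is labeled as such in the series name.
    """
    for cond in (young, aged):
        if cond not in frequencies.columns:
            raise KeyError(f"condition column {cond!r} missing")
        total = frequencies[cond].sum()
        if not np.isclose(total, 1.0):
            raise ValueError(f"frequencies for {cond!r} sum to {total}, expected 1")
    delta = frequencies[aged] - frequencies[young]
    scale = delta.abs().max()
    scaled = delta / scale if scale > 0 else delta
    scaled.name = "scaled_change_reconstructed"
    return scaled
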