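"""Injury-recovery statistics: recovery fraction, time-course AUC, aging index.

The aging index of a cell population is the ratio of its aged to young area
under the post-injury abundance curve over the first seven days (trapezoid
on replicate means at the observed days).  An index below 1 means the aged
curve encloses less area — depleted harder and/or recovering slower.
Uncertainty comes from a replicate-level percentile bootstrap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_COLS = ("subset", "age_group", "day", "replicate", "abundance")


def _check(tc: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COLS) - set(tc.columns)
    if missing:
        raise ValueError(f"time-course table missing columns: {sorted(missing)}")
    if (tc["abundance"] < 0).any():
        raise ValueError("abundances must be non-negative")
    return tc


def recovery_fraction(
    timecourse: pd.DataFrame, baseline_day: float = 0.0
) -> pd.DataFrame:
    """Percentage of age-matched baseline: 100 × mean(day) / mean(day 0).

    One row per (subset, age_group, day).  Raises if a series lacks the
    baseline day or its baseline mean is zero.
    """
    tc = _check(timecourse)
    means = (
        tc.groupby(["subset", "age_group", "day"], observed=True)["abundance"]
        .mean()
        .reset_index()
    )
    rows = []
    for (subset, age), grp in means.groupby(["subset", "age_group"], observed=True):
        base = grp.loc[grp["day"] == baseline_day, "abundance"]
        if base.empty:
            raise ValueError(f"series ({subset!r}, {age!r}) lacks day {baseline_day}")
        base = float(base.iloc[0])
        if base == 0:
            raise ValueError(f"zero baseline mean for series ({subset!r}, {age!r})")
        for _, r in grp.iterrows():
            rows.append(
                {
                    "subset": subset,
                    "age_group": age,
                    "day": r["day"],
                    "recovery_pct": 100.0 * r["abundance"] / base,
                }
            )
    return pd.DataFrame(rows)


def auc_timecourse(
    timecourse: pd.DataFrame, window: tuple[float, float] = (0.0, 7.0)
) -> pd.DataFrame:
    """Trapezoidal AUC of replicate means per (subset, age_group).

    Uses the actual day values inside ``window``; units are
    abundance × days.  Raises when a series has fewer than two days.
    """
    tc = _check(timecourse)
    tc = tc[(tc["day"] >= window[0]) & (tc["day"] <= window[1])]
    rows = []
    for (subset, age), grp in tc.groupby(["subset", "age_group"], observed=True):
        means = grp.groupby("day", observed=True)["abundance"].mean().sort_index()
        if len(means) < 2:
            raise ValueError(
                f"series ({subset!r}, {age!r}) has {len(means)} day(s) in window"
            )
        auc = float(np.trapezoid(means.to_numpy(), means.index.to_numpy(dtype=float)))
        rows.append({"subset": subset, "age_group": age, "auc": auc})
    return pd.DataFrame(rows)


def _bootstrap_auc_ratio(
    grp: pd.DataFrame, window, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap the aged/young AUC ratio by resampling replicates per day."""
    series = {}
    for age, g in grp.groupby("age_group", observed=True):
        days = np.sort(g["day"].unique())
        series[age] = (days, [g.loc[g["day"] == d, "abundance"].to_numpy() for d in days])
    ages = sorted(series)
    out = np.empty(n_boot)
    for b in range(n_boot):
        aucs = {}
        for age in ages:
            days, reps = series[age]
            means = np.array(
                [rng.choice(v, size=len(v), replace=True).mean() for v in reps]
            )
            aucs[age] = np.trapezoid(means, days)
        out[b] = aucs["aged"] / aucs["young"] if aucs["young"] != 0 else np.nan
    return out


def aging_index(
    timecourse: pd.DataFrame,
    window: tuple[float, float] = (0.0, 7.0),
    n_boot: int = 2000,
    ci: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Ratio of aged to young AUC per subset, with percentile bootstrap CI.

    Requires both age groups (named ``young`` and ``aged``) per subset.
    When the young AUC is zero the index is undefined: NaN with
    ``defined = False``.
    """
    tc = _check(timecourse)
    tc = tc[(tc["day"] >= window[0]) & (tc["day"] <= window[1])]
    aucs = auc_timecourse(tc, window)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    rows = []
    for subset, grp in tc.groupby("subset", observed=True):
        present = set(grp["age_group"])
        if not {"young", "aged"} <= present:
            raise ValueError(f"subset {subset!r} lacks an age group: has {present}")
        a = aucs[(aucs["subset"] == subset) & (aucs["age_group"] == "aged")]["auc"].iloc[0]
        y = aucs[(aucs["subset"] == subset) & (aucs["age_group"] == "young")]["auc"].iloc[0]
        defined = y != 0
        boot = _bootstrap_auc_ratio(grp, window, n_boot, rng) if n_boot > 0 else np.array([])
        boot = boot[np.isfinite(boot)]
        rows.append(
            {
                "subset": subset,
                "auc_young": y,
                "auc_aged": a,
                "index": a / y if defined else np.nan,
                "defined": defined,
                "ci_low": float(np.quantile(boot, alpha)) if len(boot) else np.nan,
                "ci_high": float(np.quantile(boot, 1 - alpha)) if len(boot) else np.nan,
            }
        )
    return pd.DataFrame(rows)
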