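"""Post-injury depletion/recovery time-courses with age-dependent kinetics.

The mean curve per (subset, age group) follows the canonical acute-injury
shape: baseline at day 0, a drop to ``baseline × (1 − depth)`` at the nadir
day, then exponential return toward baseline at the group's recovery rate:

    m(0) = B
    m(t) = B · (1 − depth · exp(−rate · (t − t_nadir)))   for t ≥ t_nadir

with linear interpolation between day 0 and the nadir.  Replicates add
multiplicative Gaussian noise with coefficient of variation ``noise_cv``
(clipped at zero); ``noise_cv = 0`` reproduces the mean curve exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_DEFAULT_KINETICS = {
    # subset -> age_group -> (baseline, depletion depth in [0,1], recovery rate /day)
    "cTEC": {"young": (1000.0, 0.7, 1.0), "aged": (600.0, 0.8, 0.35)},
    "mTEC": {"young": (3000.0, 0.6, 0.9), "aged": (1500.0, 0.75, 0.3)},
}


@dataclass
class TimeCourseSpec:
    """Parameters of the injury-recovery generator."""

    days: tuple[float, ...] = (0.0, 1.0, 4.0, 7.0)
    kinetics: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {
            s: dict(g) for s, g in _DEFAULT_KINETICS.items()
        }
    )
    nadir_day: float = 1.0
    n_replicates: int = 10
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if sorted(self.days) != list(self.days):
            raise ValueError("days must be sorted ascending")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for subset, groups in self.kinetics.items():
            for age, (baseline, depth, rate) in groups.items():
                if baseline < 0 or not 0 <= depth <= 1 or rate < 0:
                    raise ValueError(
                        f"invalid kinetics for ({subset!r}, {age!r})"
                    )


def mean_curve(spec: TimeCourseSpec, subset: str, age_group: str, day) -> np.ndarray:
    """Noiseless mean abundance at the given day(s)."""
    baseline, depth, rate = spec.kinetics[subset][age_group]
    t = np.asarray(day, dtype=float)
    nadir_val = baseline * (1.0 - depth)
    rising = baseline * (1.0 - depth * np.exp(-rate * (t - spec.nadir_day)))
    falling = baseline + (nadir_val - baseline) * t / max(spec.nadir_day, 1e-12)
    return np.where(t >= spec.nadir_day, rising, falling)


def make_timecourse(spec: TimeCourseSpec) -> pd.DataFrame:
    """Replicate-level tidy table: (subset, age_group, day, replicate, abundance)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for subset in spec.kinetics:
        for age_group in spec.kinetics[subset]:
            means = mean_curve(spec, subset, age_group, np.asarray(spec.days))
            for day, m in zip(spec.days, means):
                noise = (
                    rng.normal(0.0, spec.noise_cv, size=spec.n_replicates)
                    if spec.noise_cv > 0
                    else np.zeros(spec.n_replicates)
                )
                vals = np.clip(m * (1.0 + noise), 0.0, None)
                for rep, v in enumerate(vals):
                    rows.append((subset, age_group, day, rep, v))
    return pd.DataFrame(
        rows, columns=["subset", "age_group", "day", "replicate", "abundance"]
    )
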