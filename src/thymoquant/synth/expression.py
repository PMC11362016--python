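"""Negative-binomial single-cell count matrices with planted subset structure.

The generator emulates the structure of a CD45-negative stromal dataset:
subsets with dedicated marker genes, lognormal library sizes, mitochondrial
genes whose per-cell fraction follows a Beta law, an optional low-quality
cell fraction (shrunken libraries, inflated mito content), optional
doublet-like mixtures, and two conditions ("young"/"aged") that differ in
subset frequencies — with age-associated subsets present only in "aged".
Truth labels are stored per cell in ``obs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

_DEFAULT_SUBSETS = ("cTEC", "mTEC1", "mTEC2", "tuft", "aaTEC1", "aaTEC2")
_DEFAULT_FREQS = {
    # aaTEC subsets appear only in the aged condition
    "young": (0.35, 0.30, 0.20, 0.15, 0.0, 0.0),
    "aged": (0.20, 0.22, 0.14, 0.10, 0.18, 0.16),
}


@dataclass
class ExprSimSpec:
    """Parameters of the synthetic count matrix."""

    n_cells: int = 1000
    n_genes: int = 2000
    subset_names: tuple[str, ...] = _DEFAULT_SUBSETS
    markers_per_subset: int = 25
    marker_log_fold_change: float = 1.5  # natural-log shift of marker means
    nb_dispersion: float = 0.1
    library_size_lognormal_params: tuple[float, float] = (np.log(5000.0), 0.25)
    n_mito_genes: int = 13
    mito_beta_params: tuple[float, float] = (2.0, 38.0)
    frequency_vectors: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_FREQS.items()}
    )
    lowq_cell_fraction: float = 0.05
    lowq_library_factor: float = 0.1
    lowq_mito_beta_params: tuple[float, float] = (12.0, 28.0)
    doublet_fraction: float = 0.0
    contaminant_gene: str = "Ptprc"
    contaminant_cluster_fraction: float = 0.0
    seed: int = 0

    @property
    def n_subsets(self) -> int:
        return len(self.subset_names)

    def __post_init__(self) -> None:
        if self.markers_per_subset * self.n_subsets > self.n_genes:
            raise ValueError(
                "markers_per_subset × n_subsets exceeds the gene count"
            )
        for cond, freq in self.frequency_vectors.items():
            freq = np.asarray(freq, dtype=float)
            if len(freq) != self.n_subsets:
                raise ValueError(f"frequency vector for {cond!r} has wrong length")
            if np.any(freq < 0) or not np.isclose(freq.sum(), 1.0):
                raise ValueError(f"frequencies for {cond!r} must be ≥0 and sum to 1")
        if not 0.0 <= self.lowq_cell_fraction < 1.0:
            raise ValueError("lowq_cell_fraction must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def _gene_names(spec: ExprSimSpec) -> list[str]:
    names = [f"Gene{i:04d}" for i in range(spec.n_genes)]
    for i in range(spec.n_mito_genes):
        names[i] = f"mt-Gene{i:02d}"
    # one contaminant gene after the mito block
    names[spec.n_mito_genes] = spec.contaminant_gene
    return names


def make_expression(spec: ExprSimSpec) -> ad.AnnData:
    """Simulate counts and return an :class:`~anndata.AnnData` with truth labels.

    ``obs`` carries per-cell metadata computed **from the generated counts**
    (``total_counts``, ``n_genes``, ``mito_fraction``, ``ribo_fraction``)
    together with the truth columns ``subset`` (true subset label),
    ``condition``, ``is_lowq_truth`` and ``is_doublet_truth``; ``var`` carries
    the gene names and a ``mito`` flag.
    """
    rng = np.random.default_rng(spec.seed)
    names = _gene_names(spec)
    mito_mask = np.array([n.startswith("mt-") for n in names])
    n_mito = int(mito_mask.sum())

    # baseline relative expression per gene (lognormal), mito handled separately
    base = rng.lognormal(0.0, 1.0, size=spec.n_genes)
    base[mito_mask] = 1.0  # mito weight set per cell from the Beta fraction
    base[names.index(spec.contaminant_gene)] = 1e-8  # silent unless planted

    # marker blocks: contiguous non-mito genes per subset
    marker_idx: dict[str, np.ndarray] = {}
    non_special = np.flatnonzero(~mito_mask)
    non_special = non_special[non_special != names.index(spec.contaminant_gene)]
    for s, subset in enumerate(spec.subset_names):
        lo = s * spec.markers_per_subset
        marker_idx[subset] = non_special[lo : lo + spec.markers_per_subset]

    conditions = list(spec.frequency_vectors)
    n_per_cond = np.full(len(conditions), spec.n_cells // len(conditions))
    n_per_cond[: spec.n_cells % len(conditions)] += 1

    cell_cond, cell_subset = [], []
    for cond, n_c in zip(conditions, n_per_cond):
        freq = np.asarray(spec.frequency_vectors[cond], dtype=float)
        draws = rng.choice(spec.n_subsets, size=n_c, p=freq)
        cell_cond.extend([cond] * n_c)
        cell_subset.extend(spec.subset_names[i] for i in draws)
    n_cells = len(cell_cond)

    libs = rng.lognormal(*spec.library_size_lognormal_params, size=n_cells)
    mito_frac = rng.beta(*spec.mito_beta_params, size=n_cells)
    is_lowq = rng.random(n_cells) < spec.lowq_cell_fraction
    libs[is_lowq] *= spec.lowq_library_factor
    mito_frac[is_lowq] = rng.beta(*spec.lowq_mito_beta_params, size=int(is_lowq.sum()))

    lfc = np.exp(spec.marker_log_fold_change)
    r = 1.0 / spec.nb_dispersion  # NB shape: counts ~ Gamma(r, mean/r) → Poisson

    counts = np.zeros((n_cells, spec.n_genes), dtype=np.int64)
    weights = np.empty(spec.n_genes)
    for i in range(n_cells):
        weights[:] = base
        weights[marker_idx[cell_subset[i]]] *= lfc
        nm = weights[~mito_mask]
        weights[~mito_mask] = (1.0 - mito_frac[i]) * nm / nm.sum()
        weights[mito_mask] = mito_frac[i] / n_mito
        mean = libs[i] * weights
        lam = rng.gamma(r, mean / r)
        counts[i] = rng.poisson(lam)

    is_doublet = np.zeros(n_cells, dtype=bool)
    if spec.doublet_fraction > 0:
        n_dbl = int(round(spec.doublet_fraction * n_cells))
        picks = rng.choice(n_cells, size=(n_dbl, 2), replace=True)
        targets = rng.choice(n_cells, size=n_dbl, replace=False)
        counts[targets] = counts[picks[:, 0]] + counts[picks[:, 1]]
        is_doublet[targets] = True

    subset_arr = np.array(cell_subset)
    if spec.contaminant_cluster_fraction > 0:
        # plant contaminant expression in one dedicated subset's cells
        target = spec.subset_names[-1]
        cells = np.flatnonzero(subset_arr == target)
        n_cont = int(round(spec.contaminant_cluster_fraction * len(cells)))
        chosen = rng.choice(cells, size=n_cont, replace=False)
        gi = names.index(spec.contaminant_gene)
        counts[chosen, gi] += rng.poisson(20.0, size=n_cont) + 1

    total = counts.sum(axis=1)
    obs = pd.DataFrame(
        {
            "total_counts": total,
            "n_genes": (counts > 0).sum(axis=1),
            "mito_fraction": np.where(
                total > 0, counts[:, mito_mask].sum(axis=1) / np.maximum(total, 1), 0.0
            ),
            "ribo_fraction": 0.0,  # no ribosomal genes are simulated
            "subset": subset_arr,
            "cluster": subset_arr,  # truth labels double as cluster ids
            "condition": cell_cond,
            "sample": [f"{c}_1" for c in cell_cond],
            "is_lowq_truth": is_lowq,
            "is_doublet_truth": is_doublet,
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame({"mito": mito_mask}, index=names)
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["marker_truth"] = {k: [names[i] for i in v] for k, v in marker_idx.items()}
    return adata


def make_pseudobulk_spots(
    adata: ad.AnnData,
    cells_per_spot: int = 10,
    spots_per_subset: int = 20,
    seed: int = 0,
    label_key: str = "subset",
) -> ad.AnnData:
    """Single-subset pseudobulk "spots": sums of sampled cell count vectors.

    Emulates array spots dominated by one cell type; truth subset stored in
    ``obs["subset"]``.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(adata.X)
    rows, labels = [], []
    for subset in pd.unique(adata.obs[label_key]):
        pool = np.flatnonzero((adata.obs[label_key] == subset).to_numpy())
        if len(pool) == 0:
            continue
        for _ in range(spots_per_subset):
            take = rng.choice(pool, size=min(cells_per_spot, len(pool)), replace=True)
            rows.append(X[take].sum(axis=0))
            labels.append(subset)
    spots = ad.AnnData(
        X=np.asarray(rows, dtype=np.int64),
        obs=pd.DataFrame(
            {"subset": labels,
             "total_counts": np.asarray(rows).sum(axis=1)},
            index=[f"spot{i:04d}" for i in range(len(rows))],
        ),
        var=adata.var.copy(),
    )
    return spots
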