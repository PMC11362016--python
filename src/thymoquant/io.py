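"""File round-trips for the pipeline's on-disk formats.

Image stacks are multi-page TIFF (one file per channel) with voxel spacing
and channel names recorded in a YAML sidecar; masks are compressed boolean
volumes (``.npz``); expression matrices are MTX triplets with a metadata
CSV; nucleus tables, densities and time-courses are tidy CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import io as sio
from scipy import sparse

from .containers import ImageStack, RegionMask, RegionMaskSet


def write_stack(stack: ImageStack, outdir: str | Path, name: str = "stack") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch, arr in stack.channels.items():
        tifffile.imwrite(outdir / f"{name}_{ch}.tif", arr.astype(np.float32))
    sidecar = outdir / f"{name}.yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {
                "spacing_um_zyx": list(stack.spacing),
                "channels": {ch: f"{name}_{ch}.tif" for ch in stack.channels},
            },
            fh,
        )
    return sidecar


def read_stack(sidecar: str | Path) -> ImageStack:
    sidecar = Path(sidecar)
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    channels = {
        ch: tifffile.imread(sidecar.parent / fname).astype(np.float64)
        for ch, fname in meta["channels"].items()
    }
    return ImageStack(channels=channels, spacing=tuple(meta["spacing_um_zyx"]))


def write_masks(regions: RegionMaskSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, spacing=np.asarray(regions.spacing), **regions.masks
    )
    return path


def read_masks(path: str | Path) -> RegionMaskSet:
    data = np.load(path)
    spacing = tuple(data["spacing"])
    masks = {k: data[k] for k in data.files if k != "spacing"}
    return RegionMaskSet(masks=masks, spacing=spacing)


def write_regions_csv(regions: RegionMaskSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "region": name,
            "voxels": int(regions.masks[name].sum()),
            "volume_um3": regions.volumes[name],
        }
        for name in ("lobe", "medulla", "hd", "cortex")
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_expression_mtx(adata, outdir: str | Path) -> Path:
    """MTX triplet (matrix/features/barcodes) + per-cell metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sparse.csr_matrix(X) if not sparse.issparse(X) else X
    sio.mmwrite(outdir / "matrix.mtx", mat.T)  # genes × cells, 10x-style
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(outdir / "metadata.csv")
    return outdir


def read_expression_mtx(indir: str | Path):
    import anndata as ad

    indir = Path(indir)
    mat = sio.mmread(indir / "matrix.mtx").tocsr().T
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.read_csv(indir / "metadata.csv", index_col=0)
    adata = ad.AnnData(X=mat.toarray().astype(np.int64), obs=obs)
    adata.var_names = features.astype(str)
    adata.obs_names = barcodes.astype(str)
    return adata
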