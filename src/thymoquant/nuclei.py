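"""Nuclear spot detection, distance-rule classification and count estimation.

Detection is scale-space Laplacian-of-Gaussian blob detection at the scale
of one nucleus (sigma = diameter / (2√3) in physical units, corrected for
voxel anisotropy), with sub-voxel localization by parabolic interpolation.

Classification follows the distance rules of the quantification protocol:
a nucleus is *medullary/HD* when its signed distance to the medullary or
HD surface is ≤ 0 μm (inside or on the surface), *subcapsular* when its
signed distance to the section edge is ≥ −25 μm (within 25 μm inside the
edge), and *cortical* otherwise.  Distances are negative inside a surface.

Whole-lobe counts are estimated by the paired-lobe design: densities from
a sectioned (confocal) sample multiplied by region volumes from a
whole-lobe (light-sheet) sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ImageStack, RegionMask, RegionMaskSet

MEDULLARY_OR_HD = "medullary_or_hd"
SUBCAPSULAR = "subcapsular"
CORTICAL = "cortical"


@dataclass
class ClassificationRules:
    """Distance thresholds (μm) of the classification rule."""

    region_inside_threshold: float = 0.0
    subcapsular_band_threshold: float = -25.0

    def __post_init__(self) -> None:
        if self.subcapsular_band_threshold > 0:
            raise ValueError("subcapsular band threshold must be ≤ 0 μm")


def detect_nuclei(
    stack: ImageStack,
    channel: str,
    diameter_um: float = 6.0,
    score_threshold: float = 1.0,
) -> pd.DataFrame:
    """Detect nuclear spots by Laplacian-of-Gaussian blob detection.

    Returns a table with sub-voxel centers (``z_um, y_um, x_um``), the
    ``channel`` and the detection ``score`` (scale-normalized negative LoG
    response at the maximum).

    Raises
    ------
    ValueError
        If ``diameter_um`` is smaller than the voxel pitch on any axis.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    spacing = np.asarray(stack.spacing)
    if np.any(diameter_um < spacing):
        raise ValueError(
            f"nuclear diameter {diameter_um} μm is below the voxel pitch "
            f"{tuple(spacing)} μm on at least one axis"
        )
    img = stack.channel(channel)
    sigma_um = diameter_um / (2.0 * np.sqrt(3.0))
    sigma_vox = sigma_um / spacing
    # scale-normalized response: −σ²∇²(G*I), positive on bright blobs
    response = -(sigma_um**2) * ndimage.gaussian_laplace(img, sigma=sigma_vox)

    # local maxima over a nucleus-sized anisotropic neighborhood
    size = np.maximum((diameter_um / spacing).astype(int) | 1, 3)
    maxfilt = ndimage.maximum_filter(response, size=tuple(size), mode="nearest")
    peaks = (response == maxfilt) & (response > score_threshold)
    zi, yi, xi = np.nonzero(peaks)

    centers = []
    for z, y, x in zip(zi, yi, xi):
        sub = []
        for axis, idx in enumerate((z, y, x)):
            if 0 < idx < response.shape[axis] - 1:
                lo = response[(z, y, x)[:axis] + (idx - 1,) + (z, y, x)[axis + 1 :]]
                hi = response[(z, y, x)[:axis] + (idx + 1,) + (z, y, x)[axis + 1 :]]
                c = response[z, y, x]
                denom = lo - 2 * c + hi
                off = 0.5 * (lo - hi) / denom if denom != 0 else 0.0
                off = float(np.clip(off, -0.5, 0.5))
            else:
                off = 0.0
            sub.append(idx + off)
        centers.append(sub)
    centers = np.asarray(centers, dtype=float).reshape(-1, 3) * spacing
    return pd.DataFrame(
        {
            "z_um": centers[:, 0] if len(centers) else [],
            "y_um": centers[:, 1] if len(centers) else [],
            "x_um": centers[:, 2] if len(centers) else [],
            "channel": channel,
            "score": response[zi, yi, xi] if len(zi) else [],
        }
    )


def signed_distance_field(mask: RegionMask, lateral_only: bool = False) -> np.ndarray:
    """Signed anisotropic Euclidean distance to the mask surface (μm).

    Negative inside the mask, positive outside, ~0 on the boundary.  With
    ``lateral_only`` the distance is computed slice-wise in (y, x) only, so
    the top/bottom cut faces of a section do not count as edge — every
    z-slice sees only the lateral boundary.
    """
    m = mask.mask
    if not m.any():
        return np.full(m.shape, np.inf)
    if lateral_only:
        field = np.empty(m.shape, dtype=np.float64)
        samp = mask.spacing[1:]
        for i in range(m.shape[0]):
            sl = m[i]
            if not sl.any():
                field[i] = np.inf
                continue
            outside = ndimage.distance_transform_edt(~sl, sampling=samp)
            inside = ndimage.distance_transform_edt(sl, sampling=samp)
            field[i] = outside - inside
        return field
    outside = ndimage.distance_transform_edt(~m, sampling=mask.spacing)
    inside = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    return outside - inside


def signed_distance(
    points_um: np.ndarray, mask: RegionMask, lateral_only: bool = False
) -> np.ndarray:
    """Signed distance (μm) of each point to the mask surface.

    Points are ``(n, 3)`` physical coordinates ``(z, y, x)`` in μm; values
    are linearly interpolated from the voxel-wise signed distance field.
    Returns ``+inf`` for an empty mask.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if not mask.mask.any():
        return np.full(len(pts), np.inf)
    field = signed_distance_field(mask, lateral_only=lateral_only)
    coords = (pts / np.asarray(mask.spacing)).T
    finite = np.isfinite(field)
    if not finite.all():
        # inf slices (lateral-only, empty slice): nearest-slice fallback
        field = np.where(finite, field, np.nanmax(field[finite]))
    return ndimage.map_coordinates(field, coords, order=1, mode="nearest")


def classify_nuclei(
    table: pd.DataFrame,
    regions: RegionMaskSet,
    edge_mask: RegionMask,
    rules: ClassificationRules | None = None,
) -> pd.DataFrame:
    """Assign each nucleus exactly one compartment label.

    Precedence: medullary/HD (distance to medulla *or* HD surface ≤ 0 μm),
    then subcapsular (lateral edge distance ≥ −25 μm), remainder cortical.
    Adds the signed distances and the ``label`` column; also attributes
    medullary/HD nuclei to the individual region whose surface they are
    deepest inside (ties go to HD).
    """
    rules = rules or ClassificationRules()
    out = table.copy()
    pts = out[["z_um", "y_um", "x_um"]].to_numpy()
    d_med = signed_distance(pts, regions.region("medulla"))
    d_hd = signed_distance(pts, regions.region("hd"))
    d_edge = signed_distance(pts, edge_mask, lateral_only=True)
    out["dist_medulla_um"] = d_med
    out["dist_hd_um"] = d_hd
    out["dist_edge_um"] = d_edge

    inside = np.minimum(d_med, d_hd) <= rules.region_inside_threshold
    subcap = ~inside & (d_edge >= rules.subcapsular_band_threshold)
    labels = np.where(inside, MEDULLARY_OR_HD, np.where(subcap, SUBCAPSULAR, CORTICAL))
    out["label"] = labels
    # per-region attribution of the combined medullary/HD label; ties → HD
    region = np.where(d_hd <= d_med, "hd", "medulla")
    out["region"] = np.where(inside, region, np.where(subcap, "cortex", "cortex"))
    return out


def compute_densities(table: pd.DataFrame, regions: RegionMaskSet) -> pd.DataFrame:
    """Nuclear density per (region, channel): count / region volume (μm⁻³)."""
    rows = []
    for region in ("medulla", "hd", "cortex"):
        vol = regions.volumes[region]
        sub = table[table["region"] == region] if "region" in table else table.iloc[0:0]
        for channel in sorted(table["channel"].unique()) if len(table) else []:
            count = int((sub["channel"] == channel).sum())
            if count > 0 and vol == 0:
                raise ValueError(f"region {region!r} has nuclei but zero volume")
            rows.append(
                {
                    "region": region,
                    "channel": channel,
                    "count": count,
                    "volume_um3": vol,
                    "density_per_um3": count / vol if vol > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def region_core_densities(
    table: pd.DataFrame,
    regions: RegionMaskSet,
    erode_um: float = 3.0,
    channel: str | None = None,
) -> pd.DataFrame:
    """Densities measured in eroded (or dilated) region masks.

    Density is an intensive quantity: voxels within ``erode_um`` of a
    region boundary — where segmentation membership is uncertain — are
    excluded, and the count of nuclei falling inside the eroded core is
    divided by the core volume.  A *negative* ``erode_um`` dilates
    instead, which captures nuclei crowded just outside a slightly
    undersized mask (thin-shell regions).  Use together with
    :func:`estimate_counts` (which multiplies by *full* region volumes)
    for whole-lobe counts.
    """
    from scipy import ndimage as ndi

    sp = np.asarray(regions.spacing)
    voxvol = float(np.prod(sp))
    dilate = erode_um < 0
    r_vox = np.maximum(np.round(abs(erode_um) / sp).astype(int), 0)
    zz, yy, xx = np.ogrid[
        -r_vox[0] : r_vox[0] + 1, -r_vox[1] : r_vox[1] + 1, -r_vox[2] : r_vox[2] + 1
    ]
    fp = (
        (zz / max(r_vox[0], 1)) ** 2
        + (yy / max(r_vox[1], 1)) ** 2
        + (xx / max(r_vox[2], 1)) ** 2
    ) <= 1.0
    pts = table[["z_um", "y_um", "x_um"]].to_numpy()
    idx = np.round(pts / sp).astype(int)
    shape = regions.masks["lobe"].shape
    for ax in range(3):
        idx[:, ax] = np.clip(idx[:, ax], 0, shape[ax] - 1)
    chan = table["channel"].to_numpy() if "channel" in table else np.array(["?"] * len(table))
    rows = []
    channels = [channel] if channel else sorted(pd.unique(chan))
    for region in ("medulla", "hd", "cortex"):
        op = ndi.binary_dilation if dilate else ndi.binary_erosion
        core = op(regions.masks[region], structure=fp)
        vol = core.sum() * voxvol
        inside = core[idx[:, 0], idx[:, 1], idx[:, 2]] if len(idx) else np.array([], bool)
        for ch in channels:
            count = int((inside & (chan == ch)).sum()) if len(idx) else 0
            rows.append(
                {
                    "region": region,
                    "channel": ch,
                    "count": count,
                    "volume_um3": vol,
                    "density_per_um3": count / vol if vol > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def estimate_counts(
    densities: pd.DataFrame,
    volumes: RegionMaskSet | dict[str, float],
    density_rel_err: float = 0.0,
    volume_rel_err: float = 0.0,
) -> pd.DataFrame:
    """Paired-lobe count estimate: density (sample A) × volume (sample B).

    ``volumes`` may be a segmented :class:`RegionMaskSet` or a plain
    region → μm³ mapping.  The propagated relative error is reported as the
    sum of the provided input relative errors.
    """
    vols = volumes.volumes if isinstance(volumes, RegionMaskSet) else dict(volumes)
    missing = sorted(set(densities["region"]) - set(vols))
    if missing:
        raise KeyError(f"regions missing from volume table: {missing}")
    out = densities.copy()
    out["volume_b_um3"] = out["region"].map(vols)
    out["estimated_count"] = out["density_per_um3"] * out["volume_b_um3"]
    out["rel_err"] = density_rel_err + volume_rel_err
    return out[["region", "channel", "density_per_um3", "volume_b_um3",
                "estimated_count", "rel_err"]]
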