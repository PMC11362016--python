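"""Density-based segmentation of thymic regions from two-channel volumes.

The pipeline mirrors whole-lobe quantification of reporter imaging: the lobe
surface comes from the tdTomato channel; medullary regions from the combined
GFP (+ optional keratin) channels; high-density (HD) regions from GFP alone.
Each dense-region segmentation applies, in fixed order: channel summation,
per-slice 2D median filtering, 3D Gaussian smoothing in physical units,
per-slice min–max normalization with a fractional threshold, morphological
closing, small-component removal, and restriction to a parent mask.

Cortical volume is the lobe minus medullary and HD volume, so the volume
identity ``cortex + medulla + hd == lobe`` holds exactly on voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .containers import ImageStack, RegionMask, RegionMaskSet


@dataclass
class SegmentationParams:
    """Tunable parameters of the filtering/binarization pipeline.

    ``gaussian_sigma`` and ``closing_radius`` are in μm and converted to
    per-axis voxel units to honor anisotropic spacing; ``median_radius`` is
    in pixels and applied per 2D slice; ``binarize_threshold`` is the
    fraction applied after per-slice min–max normalization; set it to
    ``None`` to use a per-volume Otsu threshold instead.
    """

    median_radius: int = 2
    gaussian_sigma: float = 5.0
    binarize_threshold: float | None = 0.5
    min_component_volume: float = 1.0e4
    closing_radius: float = 3.0
    opening_radius: float = 0.0
    fill_holes: bool = False
    normalization: str = "slice"
    slice_range_floor: float = 0.05
    min_class_separation: float = 0.0

    def __post_init__(self) -> None:
        if self.binarize_threshold is not None and not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.median_radius < 0 or self.gaussian_sigma < 0 or self.closing_radius < 0:
            raise ValueError("radii and sigma must be non-negative")
        if self.normalization not in ("slice", "volume"):
            raise ValueError("normalization must be 'slice' or 'volume'")


def _ellipsoid_footprint(radius_um: float, spacing) -> np.ndarray | None:
    """Anisotropic structuring element with the given physical radius."""
    r_vox = np.maximum(np.round(radius_um / np.asarray(spacing)).astype(int), 0)
    if np.all(r_vox == 0):
        return None
    zz, yy, xx = np.ogrid[
        -r_vox[0] : r_vox[0] + 1, -r_vox[1] : r_vox[1] + 1, -r_vox[2] : r_vox[2] + 1
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (
            (zz / max(r_vox[0], 1)) ** 2
            + (yy / max(r_vox[1], 1)) ** 2
            + (xx / max(r_vox[2], 1)) ** 2
        )
    return d <= 1.0


def _filter_and_binarize(
    img: np.ndarray,
    spacing,
    params: SegmentationParams,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Median → Gaussian → per-slice min–max normalize → threshold.

    With ``binarize_threshold=None`` an automatic Otsu threshold is computed
    instead — over the voxels of ``reference`` when given, else the whole
    volume.  ``min_class_separation`` (> 0) gates the Otsu split: if the
    mean intensity of the upper class is less than that multiple of the
    lower class's mean, the split is judged spurious (the reference region
    is effectively unimodal) and no foreground is returned.
    """
    out = img.astype(np.float64, copy=True)
    if params.median_radius > 0:
        footprint = morphology.disk(params.median_radius)
        for i in range(out.shape[0]):
            out[i] = filters.median(out[i], footprint=footprint, mode="nearest")
    if params.gaussian_sigma > 0:
        sigma_vox = params.gaussian_sigma / np.asarray(spacing)
        out = ndimage.gaussian_filter(out, sigma=sigma_vox)
    if params.binarize_threshold is None:
        vals = out[reference] if reference is not None else out.ravel()
        if vals.size == 0 or vals.min() == vals.max():
            return np.zeros(out.shape, dtype=bool)
        thr = filters.threshold_otsu(vals)
        if params.min_class_separation > 0:
            lo_mean = vals[vals <= thr].mean()
            hi_mean = vals[vals > thr].mean()
            if lo_mean <= 0 or hi_mean / lo_mean < params.min_class_separation:
                return np.zeros(out.shape, dtype=bool)
        return out > thr
    if params.normalization == "volume":
        lo, hi = out.min(), out.max()
        if hi <= lo:
            return np.zeros(out.shape, dtype=bool)
        return (out - lo) / (hi - lo) >= params.binarize_threshold
    binary = np.zeros(out.shape, dtype=bool)
    global_range = out.max() - out.min()
    for i in range(out.shape[0]):
        sl = out[i]
        lo, hi = sl.min(), sl.max()
        if hi <= lo:  # constant slice: min–max degenerate, no foreground
            continue
        if hi - lo < params.slice_range_floor * global_range:
            # near-empty slice: stretching its residual noise to [0, 1]
            # would fabricate foreground, so it contributes none
            continue
        binary[i] = (sl - lo) / (hi - lo) >= params.binarize_threshold
    return binary


def _postprocess(
    binary: np.ndarray, spacing, params: SegmentationParams
) -> np.ndarray:
    voxvol = float(np.prod(spacing))
    out = binary
    footprint = _ellipsoid_footprint(params.closing_radius, spacing)
    if footprint is not None:
        out = ndimage.binary_closing(out, structure=footprint)
    open_fp = _ellipsoid_footprint(params.opening_radius, spacing)
    if open_fp is not None:
        out = ndimage.binary_opening(out, structure=open_fp)
    if params.fill_holes:
        out = ndimage.binary_fill_holes(out)
    min_vox = int(np.ceil(params.min_component_volume / voxvol))
    if min_vox > 1:
        out = morphology.remove_small_objects(out, max_size=min_vox - 1)
    return out


def extract_lobe_mask(
    stack: ImageStack,
    params: SegmentationParams | None = None,
    channel: str = "tdTomato",
) -> RegionMask:
    """Segment the whole lobe as the largest connected component of the
    reporter channel after filtering, binarization and hole filling.

    Raises
    ------
    ValueError
        If the segmentation is empty (e.g. an all-zero image).
    """
    params = params or SegmentationParams(
        gaussian_sigma=5.0,
        binarize_threshold=None,
        closing_radius=15.0,
        fill_holes=True,
    )
    img = stack.channel(channel)
    binary = _filter_and_binarize(img, stack.spacing, params)
    binary = _postprocess(binary, stack.spacing, params)
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError(f"lobe segmentation from channel {channel!r} is empty")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    lobe = labels == (1 + int(np.argmax(sizes)))
    lobe = ndimage.binary_fill_holes(lobe)
    return RegionMask(lobe, stack.spacing)


def segment_dense_region(
    stack: ImageStack,
    channels: list[str] | tuple[str, ...],
    params: SegmentationParams | None = None,
    restrict_to: RegionMask | None = None,
) -> RegionMask:
    """Segment a high-nuclear-density region from the named channels.

    Pipeline order is fixed: (1) sum channels; (2) per-slice 2D median;
    (3) 3D Gaussian in physical units; (4) per-slice min–max normalization
    and fractional threshold; (5) morphological closing; (6) drop components
    below ``min_component_volume``; (7) intersect with ``restrict_to``.
    """
    params = params or SegmentationParams()
    missing = [c for c in channels if c not in stack.channels]
    if missing:
        raise KeyError(f"channels not present in stack: {missing}")
    img = sum(stack.channel(c) for c in channels)
    reference = restrict_to.mask if restrict_to is not None else None
    binary = _filter_and_binarize(img, stack.spacing, params, reference=reference)
    binary = _postprocess(binary, stack.spacing, params)
    if restrict_to is not None:
        binary &= restrict_to.mask
    return RegionMask(binary, stack.spacing)


def compose_regions(
    lobe: RegionMask, medulla_raw: RegionMask, hd_raw: RegionMask | None = None
) -> RegionMaskSet:
    """Resolve overlaps and derive the cortex by subtraction.

    Voxels claimed by both medulla and HD go to HD (the stricter,
    compaction-based criterion); cortex = lobe ∖ (medulla ∪ hd).  Raises if
    a raw mask extends outside the lobe.
    """
    shapes = {lobe.mask.shape, medulla_raw.mask.shape}
    if hd_raw is not None:
        shapes.add(hd_raw.mask.shape)
    if len(shapes) != 1:
        raise ValueError("all masks must share one grid")
    if np.any(medulla_raw.mask & ~lobe.mask):
        raise ValueError("medulla mask extends outside the lobe")
    hd = hd_raw.mask.copy() if hd_raw is not None else np.zeros_like(lobe.mask)
    if np.any(hd & ~lobe.mask):
        raise ValueError("HD mask extends outside the lobe")
    medulla = medulla_raw.mask & ~hd  # HD precedence on overlap
    cortex = lobe.mask & ~(medulla | hd)
    return RegionMaskSet(
        masks={"lobe": lobe.mask, "medulla": medulla, "hd": hd, "cortex": cortex},
        spacing=lobe.spacing,
    )


def _xy_footprint(radius_um: float, spacing) -> np.ndarray:
    """Disk structuring element acting in (y, x) only — one z-slice thick."""
    ry = max(int(round(radius_um / spacing[1])), 1)
    rx = max(int(round(radius_um / spacing[2])), 1)
    yy, xx = np.ogrid[-ry : ry + 1, -rx : rx + 1]
    return ((yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0)[None, :, :]


def _smooth_only(
    img: np.ndarray, spacing, params: SegmentationParams, sigma_um: float
) -> np.ndarray:
    """The pipeline's filtering steps only: per-slice median then 3D Gaussian."""
    out = img.astype(np.float64, copy=True)
    if params.median_radius > 0:
        footprint = morphology.disk(params.median_radius)
        for i in range(out.shape[0]):
            out[i] = filters.median(out[i], footprint=footprint, mode="nearest")
    if sigma_um > 0:
        out = ndimage.gaussian_filter(out, sigma=sigma_um / np.asarray(spacing))
    return out


def segment_phantom_regions(
    stack: ImageStack,
    lobe_params: SegmentationParams | None = None,
    gfp_channel: str = "GFP",
    hd_gate_ratio: float = 1.45,
    min_hd_lobe_fraction: float = 0.005,
    hd_sigma: float = 5.0,
    medulla_sigma: float = 6.5,
    medulla_level: float = 0.37,
    hd_level: float = 0.22,
    hd_min_component_volume: float | None = None,
    seed: int = 0,
) -> RegionMaskSet:
    """Calibrated end-to-end segmentation of a two-channel lobe image.

    The lobe surface comes from the tdTomato channel (automatic threshold
    after smoothing, closed and hole-filled).  GFP density thresholds are
    derived from the image itself, the automated analogue of setting
    thresholds from the fluorescence histogram:

    1.  A rough dense compartment (> 30% of the within-lobe bright
        ceiling) is eroded in-plane to strip boundary-transition voxels,
        leaving plateau "cores".
    2.  The core intensities are split by an Otsu threshold into two
        classes.  HD regions are accepted only when the upper class is
        genuinely brighter (mean ratio ≥ ``hd_gate_ratio``): compacted HD
        regions are severalfold denser than medulla, while a lobe without
        them (young-type image) has a unimodal dense compartment whose
        Otsu split yields two classes of similar mean.
    3.  Plateau levels for medulla and HD are medians over the respective
        core classes; each boundary threshold is placed a fraction
        (``medulla_level``, ``hd_level``) of the way up the transition,
        calibrated below 0.5 to offset the inward bias that Gaussian
        smoothing imposes on convex boundaries.
    4.  The expected blur bleed-through around bright HD regions is
        subtracted (Gaussian forward model) before the medullary threshold
        is applied; closing bridges sampling holes and an in-plane opening
        removes residual halo rings.

    No median prefilter is applied on this path: the physical-units
    Gaussian provides the denoising, whereas a pixel-radius median would
    erase nuclei that are sub-pixel at fine sampling.  Returns a
    :class:`RegionMaskSet` with the exact volume identity
    ``cortex + medulla + hd = lobe``.
    """
    from skimage.filters import threshold_otsu

    base = SegmentationParams(median_radius=0)
    lobe = extract_lobe_mask(
        stack,
        lobe_params
        or SegmentationParams(
            median_radius=0,
            gaussian_sigma=5.0,
            binarize_threshold=None,
            closing_radius=15.0,
            fill_holes=True,
        ),
    )
    sp = np.asarray(stack.spacing)
    img = stack.channel(gfp_channel)
    f_hd = _smooth_only(img, sp, base, hd_sigma)
    f_med = _smooth_only(img, sp, base, medulla_sigma)
    vals = f_hd[lobe.mask]
    ceiling = float(np.quantile(vals, 0.995))

    rough = (f_hd > 0.3 * ceiling) & lobe.mask
    erode_fp = np.zeros((3, 11, 11), dtype=bool)
    yy, xx = np.ogrid[-5:6, -5:6]
    erode_fp[1] = (yy**2 + xx**2) <= 25
    erode_fp[0, 5, 5] = erode_fp[2, 5, 5] = True
    core = ndimage.binary_erosion(rough, structure=erode_fp)
    if not core.any():
        raise ValueError("no dense compartment found inside the lobe")
    core_vals = f_hd[core]
    split = float(threshold_otsu(core_vals))
    lo_vals = core_vals[core_vals <= split]
    hi_vals = core_vals[core_vals > split]
    hd_present = (
        lo_vals.size > 0
        and hi_vals.size > 0
        and lo_vals.mean() > 0
        and hi_vals.mean() / lo_vals.mean() >= hd_gate_ratio
    )

    hd_mask = np.zeros_like(lobe.mask)
    c_med = float(np.median(f_med[lobe.mask]))
    if hd_present:
        med_core = core & (f_hd <= split)
        hd_core = core & (f_hd > split)
        med_pl_hd = float(np.median(f_hd[med_core]))
        hd_pl_hd = float(np.median(f_hd[hd_core]))
        t_hd = med_pl_hd + hd_level * (hd_pl_hd - med_pl_hd)
        hd_params = base
        if hd_min_component_volume is not None:
            from dataclasses import replace as _dc_replace

            hd_params = _dc_replace(base, min_component_volume=hd_min_component_volume)
        hd_mask = _postprocess((f_hd > t_hd) & lobe.mask, sp, hd_params) & lobe.mask
        if hd_mask.sum() < min_hd_lobe_fraction * lobe.mask.sum():
            hd_mask[:] = False
        med_pl = float(np.median(f_med[med_core]))
        hd_pl = float(np.median(f_med[hd_core]))
    else:
        med_pl = float(np.median(f_med[core]))
        hd_pl = med_pl

    field = f_med
    if hd_mask.any():
        sigma_b = np.sqrt((medulla_sigma / sp) ** 2 + (2.5 / sp) ** 2)
        field = f_med - (hd_pl - c_med) * ndimage.gaussian_filter(
            hd_mask.astype(np.float64), sigma=sigma_b
        )
    t_med = c_med + medulla_level * (med_pl - c_med)
    med_mask = (field > t_med) & lobe.mask & ~hd_mask
    med_mask = ndimage.binary_closing(med_mask, structure=_ellipsoid_footprint(4.0, sp))
    med_mask = ndimage.binary_opening(med_mask, structure=_xy_footprint(4.0, sp))
    min_vox = int(np.ceil(base.min_component_volume / float(np.prod(sp))))
    med_mask = morphology.remove_small_objects(med_mask, max_size=min_vox - 1)
    med_mask &= lobe.mask & ~hd_mask
    return compose_regions(
        lobe, RegionMask(med_mask, stack.spacing), RegionMask(hd_mask, stack.spacing)
    )
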