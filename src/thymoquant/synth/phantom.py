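"""Thymic-lobe image phantoms with known region masks and nucleus positions.

The phantom emulates a two-channel nuclear-reporter image of one thymic
lobe:

* an ellipsoidal lobe with a sparse GFP+ population in the cortex, dense
  medullary blobs, and optional peri-medullary high-density (HD) shell
  sectors — populated at ``hd_gfp`` density and devoid of tdTomato
  nuclei, the imaging signature of the aged thymus;
* a rendered tdTomato population (``tdtom_background``) throughout the
  lobe except HD regions;
* an invisible space-filling population bringing total nuclear packing to
  ``packing_density`` everywhere, standing in for the unlabelled cells
  that crowd real tissue.

All populations are placed together by one inhomogeneous hard-sphere
Poisson process (minimum separation 2 × nuclear radius), so the realized
density of each labelled population is spatially uniform within its
region.  Labelled nuclei are rendered as Gaussian spots on an anisotropic
voxel grid and corrupted with Poisson plus additive Gaussian noise.  The
truth object carries the exact region masks, nucleus coordinates with
labels, and per-region counts and volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..containers import LIGHTSHEET_SPACING, ImageStack, RegionMaskSet

GFP = "GFP"
TDTOM = "tdTomato"

_DEFAULT_DENSITIES = {
    # nuclei per μm³; ordering hd > medulla > cortex is enforced.  The
    # medullary and HD values sit well below the hard-sphere jamming limit
    # for the default nuclear radius so placement always terminates.
    "cortex_gfp": 1.2e-4,
    "medulla_gfp": 3.5e-3,
    "hd_gfp": 8.0e-3,
    "tdtom_background": 5.0e-4,
}

_DEFAULT_NOISE = {"poisson_scale": 1.0, "gaussian_sd": 2.0}


@dataclass
class PhantomSpec:
    """Parameters of the lobe phantom.

    All lengths are μm.  ``shape`` and ``voxel_spacing`` are ``(z, y, x)``.
    """

    lobe_semi_axes: tuple[float, float, float] = (135.0, 105.0, 105.0)
    voxel_spacing: tuple[float, float, float] = LIGHTSHEET_SPACING
    shape: tuple[int, int, int] = (64, 256, 256)
    n_medulla_blobs: int = 5
    medulla_blob_radius: float = 28.0
    hd_fraction: float = 0.3
    hd_shell_thickness: float = 30.0
    boundary_clearance: float = 20.0
    densities: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DENSITIES))
    psf_sigma: tuple[float, float, float] = (3.0, 2.0, 2.0)
    noise: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    nuclear_radius: float = 2.0
    packing_density: float = 8.5e-3
    peak_intensity: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be strictly positive")
        if any(a <= 0 for a in self.lobe_semi_axes):
            raise ValueError("lobe_semi_axes must be positive")
        if not 0.0 <= self.hd_fraction <= 1.0:
            raise ValueError("hd_fraction must lie in [0, 1]")
        missing = set(_DEFAULT_DENSITIES) - set(self.densities)
        if missing:
            raise ValueError(f"densities missing keys: {sorted(missing)}")
        if any(v < 0 for v in self.densities.values()):
            raise ValueError("densities must be non-negative")
        d = self.densities
        if not d["hd_gfp"] > d["medulla_gfp"] > d["cortex_gfp"]:
            raise ValueError(
                "density ordering hd_gfp > medulla_gfp > cortex_gfp required"
            )
        if self.nuclear_radius <= 0:
            raise ValueError("nuclear_radius must be positive")
        td = d["tdtom_background"]
        if (
            d["cortex_gfp"] + td > self.packing_density
            or d["medulla_gfp"] + td > self.packing_density
            or d["hd_gfp"] > self.packing_density
        ):
            raise ValueError(
                "packing_density must be at least the labelled density in "
                "every region"
            )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom image pair."""

    region_masks: RegionMaskSet
    nuclei: pd.DataFrame  # columns z_um, y_um, x_um, channel, region
    true_counts: pd.DataFrame  # index region, columns channel
    true_volumes: dict[str, float]  # μm³ per region


def _physical_grids(shape, spacing):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return zz * spacing[0], yy * spacing[1], xx * spacing[2]


def _ball_mask(shape, spacing, center, radius):
    z, y, x = _physical_grids(shape, spacing)
    return (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2 <= radius**2


def _place_hard_sphere(mask, spacing, density, min_dist, rng, region_name):
    """Hard-sphere Poisson placement of nuclei inside ``mask``.

    Samples N ~ Poisson(density × volume) target points, draws candidate
    positions uniformly from mask voxels with sub-voxel jitter, and rejects
    candidates closer than ``min_dist`` μm to an accepted point.  Raises if
    the target count cannot be placed within a bounded number of attempts.
    """
    voxvol = float(np.prod(spacing))
    volume = mask.sum() * voxvol
    n_target = int(rng.poisson(density * volume))
    if n_target == 0 or volume == 0:
        return np.empty((0, 3))
    flat = np.flatnonzero(mask)
    accepted: list[np.ndarray] = []
    pts = np.empty((0, 3))
    attempts = 0
    max_attempts = 200 * n_target + 1000
    spacing_arr = np.asarray(spacing)
    while len(accepted) < n_target and attempts < max_attempts:
        # draw a batch of candidates at once
        batch = min(n_target - len(accepted), 256)
        idx = rng.choice(flat, size=batch)
        ijk = np.column_stack(np.unravel_index(idx, mask.shape))
        cand = (ijk + rng.uniform(-0.5, 0.5, size=(batch, 3))) * spacing_arr
        for p in cand:
            attempts += 1
            if len(accepted):
                d2 = np.sum((pts - p) ** 2, axis=1)
                if d2.min() < min_dist**2:
                    continue
            accepted.append(p)
            pts = np.vstack([pts, p[None, :]]) if len(accepted) > 1 else p[None, :]
            if len(accepted) == n_target:
                break
    if len(accepted) < n_target:
        raise RuntimeError(
            f"hard-sphere placement failed in region {region_name!r}: "
            f"placed {len(accepted)}/{n_target} nuclei after {attempts} attempts; "
            "density too high for the minimum separation"
        )
    return pts


class _CellList:
    """Uniform-grid neighbour structure for hard-sphere rejection tests."""

    def __init__(self, min_dist: float):
        self.cell = float(min_dist)
        self.min2 = float(min_dist) ** 2
        self.grid: dict[tuple[int, int, int], list[tuple[float, float, float]]] = {}

    def ok(self, p) -> bool:
        cz, cy, cx = int(p[0] // self.cell), int(p[1] // self.cell), int(p[2] // self.cell)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for q in self.grid.get((cz + dz, cy + dy, cx + dx), ()):
                        d2 = (
                            (q[0] - p[0]) ** 2
                            + (q[1] - p[1]) ** 2
                            + (q[2] - p[2]) ** 2
                        )
                        if d2 < self.min2:
                            return False
        return True

    def add(self, p) -> None:
        key = (int(p[0] // self.cell), int(p[1] // self.cell), int(p[2] // self.cell))
        self.grid.setdefault(key, []).append((p[0], p[1], p[2]))


def _place_hard_sphere_mixed(region_densities, spacing, min_dist, rng):
    """One inhomogeneous hard-sphere pass over several labelled populations.

    Candidate positions are drawn with probability proportional to the
    local target density, so populations compete for space across shared
    boundaries and the realized density stays spatially uniform within
    each region.  Returns accepted points and their population labels.
    """
    spacing_arr = np.asarray(spacing)
    voxvol = float(np.prod(spacing))
    flats, labels, targets = [], [], []
    for name, mask, dens in region_densities:
        volume = mask.sum() * voxvol
        n = int(rng.poisson(dens * volume)) if volume > 0 and dens > 0 else 0
        flats.append(np.flatnonzero(mask))
        labels.append(name)
        targets.append(n)
    shape = region_densities[0][1].shape
    n_total = int(np.sum(targets))
    if n_total == 0:
        return np.empty((0, 3)), []
    remaining = np.asarray(targets, dtype=float)
    cells = _CellList(min_dist)
    pts: list[tuple[float, float, float]] = []
    out_labels: list[str] = []
    attempts, max_attempts = 0, 200 * n_total + 1000
    placed = 0
    while placed < n_total and attempts < max_attempts:
        # draw a batch of candidate regions ∝ remaining quotas
        probs = remaining / remaining.sum()
        batch = min(max(n_total - placed, 16), 1024)
        ridxs = rng.choice(len(labels), size=batch, p=probs)
        jitter = rng.uniform(-0.5, 0.5, size=(batch, 3))
        voxpick = rng.random(batch)
        for b in range(batch):
            ridx = ridxs[b]
            if remaining[ridx] <= 0:
                continue
            attempts += 1
            flat = flats[ridx]
            if len(flat) == 0:
                remaining[ridx] = 0
                continue
            vox = flat[int(voxpick[b] * len(flat))]
            ijk = np.unravel_index(vox, shape)
            p = (
                (ijk[0] + jitter[b, 0]) * spacing_arr[0],
                (ijk[1] + jitter[b, 1]) * spacing_arr[1],
                (ijk[2] + jitter[b, 2]) * spacing_arr[2],
            )
            if not cells.ok(p):
                continue
            cells.add(p)
            pts.append(p)
            out_labels.append(labels[ridx])
            remaining[ridx] -= 1
            placed += 1
            if placed == n_total:
                break
    if placed < n_total:
        lagging = labels[int(np.argmax(remaining))]
        raise RuntimeError(
            f"hard-sphere placement failed in region {lagging!r}: placed "
            f"{placed}/{n_total} nuclei after {attempts} attempts; "
            "density too high for the minimum separation"
        )
    return np.asarray(pts), out_labels


def _render(points, shape, spacing, psf_sigma, peak):
    """Trilinear point splat followed by a physical-unit Gaussian PSF."""
    img = np.zeros(shape, dtype=np.float64)
    sigma_vox = np.asarray(psf_sigma) / np.asarray(spacing)
    # mass such that the blurred peak of an on-grid point is ~``peak``
    mass = peak * (2.0 * np.pi) ** 1.5 * float(np.prod(sigma_vox))
    if len(points):
        frac = np.asarray(points) / np.asarray(spacing)
        base = np.floor(frac).astype(int)
        rem = frac - base
        for dz in (0, 1):
            for dy in (0, 1):
                for dx in (0, 1):
                    w = (
                        (rem[:, 0] if dz else 1 - rem[:, 0])
                        * (rem[:, 1] if dy else 1 - rem[:, 1])
                        * (rem[:, 2] if dx else 1 - rem[:, 2])
                    )
                    zi = np.clip(base[:, 0] + dz, 0, shape[0] - 1)
                    yi = np.clip(base[:, 1] + dy, 0, shape[1] - 1)
                    xi = np.clip(base[:, 2] + dx, 0, shape[2] - 1)
                    np.add.at(img, (zi, yi, xi), mass * w)
    return ndimage.gaussian_filter(img, sigma=sigma_vox)


def _add_noise(img, noise, rng):
    scale = float(noise.get("poisson_scale", 1.0))
    sd = float(noise.get("gaussian_sd", 0.0))
    out = img
    if scale > 0:
        out = rng.poisson(scale * np.clip(img, 0, None)).astype(np.float64) / scale
    if sd > 0:
        out = out + rng.normal(0.0, sd, size=img.shape)
    return np.clip(out, 0.0, None)


def make_phantom(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Generate a two-channel lobe phantom and its ground truth.

    Returns
    -------
    stack
        ``ImageStack`` with channels ``"GFP"`` and ``"tdTomato"``.
    truth
        ``PhantomTruth`` with exact masks, nucleus table, counts and volumes.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = tuple(spec.shape), tuple(spec.voxel_spacing)
    extent = (np.asarray(shape) - 1) * np.asarray(spacing)
    center = extent / 2.0
    semi = np.asarray(spec.lobe_semi_axes, dtype=float)
    if np.any(semi * 2 > extent):
        raise ValueError("lobe does not fit inside the voxel grid")

    z, y, x = _physical_grids(shape, spacing)
    lobe = (
        ((z - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((x - center[2]) / semi[2]) ** 2
    ) <= 1.0

    # medullary blob centres drawn deep enough that blob + HD shell stay inside
    clearance = (
        spec.medulla_blob_radius + spec.hd_shell_thickness + spec.boundary_clearance
    )
    inner_semi = semi - clearance
    if np.any(inner_semi <= 0):
        raise ValueError("lobe semi-axes too small for medulla blobs + HD shells")
    blob_centers = []
    while len(blob_centers) < spec.n_medulla_blobs:
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) <= 1.0:
            blob_centers.append(center + u * inner_semi)

    medulla = np.zeros(shape, dtype=bool)
    for c in blob_centers:
        medulla |= _ball_mask(shape, spacing, c, spec.medulla_blob_radius)
    medulla &= lobe
    # HD shells coat a fraction of each blob's boundary: a spherical-cap
    # sector of the peri-medullary shell, oriented randomly per blob
    hd = np.zeros(shape, dtype=bool)
    cap_dirs = rng.normal(size=(len(blob_centers), 3))
    cap_dirs /= np.linalg.norm(cap_dirs, axis=1, keepdims=True)
    cos_theta = 1.0 - 2.0 * spec.hd_fraction  # solid-angle fraction → cap angle
    if spec.hd_fraction > 0:
        z, y, x = _physical_grids(shape, spacing)
        for c, u in zip(blob_centers, cap_dirs):
            dz, dy, dx = z - c[0], y - c[1], x - c[2]
            r2 = dz**2 + dy**2 + dx**2
            outer = spec.medulla_blob_radius + spec.hd_shell_thickness
            shell = (r2 > spec.medulla_blob_radius**2) & (r2 <= outer**2)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (dz * u[0] + dy * u[1] + dx * u[2]) / np.sqrt(r2)
            hd |= shell & (cosang >= cos_theta)
    hd &= lobe
    hd &= ~medulla
    cortex = lobe & ~(medulla | hd)
    regions = RegionMaskSet(
        masks={"lobe": lobe, "medulla": medulla, "hd": hd, "cortex": cortex},
        spacing=spacing,
    )

    min_dist = 2.0 * spec.nuclear_radius
    d = spec.densities
    pk = spec.packing_density
    td = d["tdtom_background"]
    # All nuclei — the GFP-labelled subsets, the rendered tdTomato subset,
    # and an invisible space-filling remainder (unlabelled cells packing
    # the tissue) — are placed in ONE inhomogeneous hard-sphere pass.  The
    # filler makes total packing uniform across the lobe, so the realized
    # density of each labelled population is spatially uniform; placing
    # each region separately would crowd nuclei against region surfaces
    # (an RSA edge artifact).  HD regions carry no tdTomato nuclei.
    # exterior ring: unlabelled tissue surrounding the lobe, so nuclei at
    # the lobe surface feel the same crowding as interior ones (otherwise
    # the vacuum outside enriches the outermost cortex layer)
    ring_width = 2.0 * min_dist
    r_vox = np.maximum(np.round(ring_width / np.asarray(spacing)).astype(int), 1)
    rz, ry, rx = np.ogrid[
        -r_vox[0] : r_vox[0] + 1, -r_vox[1] : r_vox[1] + 1, -r_vox[2] : r_vox[2] + 1
    ]
    ring_fp = ((rz / r_vox[0]) ** 2 + (ry / r_vox[1]) ** 2 + (rx / r_vox[2]) ** 2) <= 1
    exterior = ndimage.binary_dilation(lobe, structure=ring_fp) & ~lobe
    populations = [
        ("cortex", GFP, cortex, d["cortex_gfp"]),
        ("medulla", GFP, medulla, d["medulla_gfp"]),
        ("hd", GFP, hd, d["hd_gfp"]),
        ("lobe", TDTOM, lobe & ~hd, td),
        ("filler_cortex", None, cortex, pk - d["cortex_gfp"] - td),
        ("filler_medulla", None, medulla, pk - d["medulla_gfp"] - td),
        ("filler_hd", None, hd, pk - d["hd_gfp"]),
        ("filler_exterior", None, exterior, pk),
    ]
    pts, labels = _place_hard_sphere_mixed(
        [(name, mask, dens) for name, _, mask, dens in populations],
        spacing,
        min_dist,
        rng,
    )
    channel_of = {name: ch for name, ch, _, _ in populations}
    rows = [
        (p[0], p[1], p[2], channel_of[lab], lab)
        for p, lab in zip(pts, labels)
        if channel_of[lab] is not None
    ]
    nuclei = pd.DataFrame(rows, columns=["z_um", "y_um", "x_um", "channel", "region"])

    gfp_pts = nuclei.loc[nuclei.channel == GFP, ["z_um", "y_um", "x_um"]].to_numpy()
    td_pts = nuclei.loc[nuclei.channel == TDTOM, ["z_um", "y_um", "x_um"]].to_numpy()
    gfp = _render(gfp_pts, shape, spacing, spec.psf_sigma, spec.peak_intensity)
    td = _render(td_pts, shape, spacing, spec.psf_sigma, spec.peak_intensity)
    gfp = _add_noise(gfp, spec.noise, rng)
    td = _add_noise(td, spec.noise, rng)

    stack = ImageStack(channels={GFP: gfp, TDTOM: td}, spacing=spacing)
    counts = (
        nuclei.groupby(["region", "channel"]).size().unstack(fill_value=0)
        if len(nuclei)
        else pd.DataFrame()
    )
    for region in ("lobe", "medulla", "hd", "cortex"):
        if region not in counts.index:
            counts.loc[region] = 0
    counts = counts.fillna(0).astype(int).sort_index()
    truth = PhantomTruth(
        region_masks=regions,
        nuclei=nuclei,
        true_counts=counts,
        true_volumes=dict(regions.volumes),
    )
    return stack, truth
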