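"""Detection, signed distances, classification rules, count estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from thymoquant.containers import ImageStack, RegionMask, RegionMaskSet
from thymoquant import nuclei as nuc


def _ball_regions(shape=(24, 64, 64), spacing=(2.0, 1.0, 1.0),
                  med_center=(24.0, 20.0, 20.0), med_r=8.0,
                  hd_center=(24.0, 44.0, 44.0), hd_r=6.0):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    z, y, x = zz * spacing[0], yy * spacing[1], xx * spacing[2]
    lobe = np.ones(shape, bool)
    med = (z - med_center[0]) ** 2 + (y - med_center[1]) ** 2 + (x - med_center[2]) ** 2 <= med_r**2
    hd = (z - hd_center[0]) ** 2 + (y - hd_center[1]) ** 2 + (x - hd_center[2]) ** 2 <= hd_r**2
    cortex = lobe & ~(med | hd)
    return RegionMaskSet(
        masks={"lobe": lobe, "medulla": med, "hd": hd, "cortex": cortex},
        spacing=spacing,
    )


class TestSignedDistance:
    def test_ball_centroid_distance(self):
        rs = _ball_regions()
        d = nuc.signed_distance(np.array([[24.0, 20.0, 20.0]]), rs.region("medulla"))
        diag = np.linalg.norm(rs.spacing)
        assert abs(d[0] - (-8.0)) < diag

    def test_boundary_point_near_zero(self):
        rs = _ball_regions()
        d = nuc.signed_distance(np.array([[24.0, 20.0, 28.0]]), rs.region("medulla"))
        assert abs(d[0]) <= np.linalg.norm(rs.spacing)

    def test_flat_face_outside_gap(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[:, :, :10] = True  # flat face at x = 9.5 voxels
        rm = RegionMask(mask, (1.0, 1.0, 1.0))
        d = nuc.signed_distance(np.array([[10.0, 10.0, 15.0]]), rm)
        assert abs(d[0] - 5.5) < 1.0

    def test_empty_mask_inf(self):
        rm = RegionMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        d = nuc.signed_distance(np.array([[1.0, 1.0, 1.0]]), rm)
        assert np.isinf(d[0])


class TestClassification:
    def _table(self, pts):
        return pd.DataFrame(
            {"z_um": [p[0] for p in pts], "y_um": [p[1] for p in pts],
             "x_um": [p[2] for p in pts], "channel": "GFP", "score": 1.0}
        )

    def test_four_rule_cases(self):
        """The published distance rules, literally: ≤0 → medullary/HD;
        edge ≥ −25 → subcapsular; remainder cortical; 0 is inside."""
        spacing = (2.0, 1.0, 1.0)
        shape = (24, 160, 160)
        zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
        z, y, x = zz * spacing[0], yy * spacing[1], xx * spacing[2]
        lobe = np.ones(shape, bool)
        med = (z - 24) ** 2 + (y - 80) ** 2 + (x - 80) ** 2 <= 20.0**2
        hd = np.zeros(shape, bool)
        cortex = lobe & ~med
        rs = RegionMaskSet(
            masks={"lobe": lobe, "medulla": med, "hd": hd, "cortex": cortex},
            spacing=spacing,
        )
        # edge = lateral boundary of a cylinder-like section mask
        edge = np.zeros(shape, bool)
        edge[:, 5:155, 5:155] = True
        edge_mask = RegionMask(edge, spacing)
        pts = [
            (24.0, 80.0, 80.0),    # deep inside medulla → medullary_or_hd
            (24.0, 80.0, 145.0),   # 10 μm inside the edge → subcapsular
            (24.0, 80.0, 115.0),   # 35 μm from medulla, 40 μm from edge → cortical
            (24.0, 80.0, 100.0),   # exactly on medulla boundary → medullary_or_hd
        ]
        out = nuc.classify_nuclei(self._table(pts), rs, edge_mask)
        assert list(out.label) == [
            nuc.MEDULLARY_OR_HD, nuc.SUBCAPSULAR, nuc.CORTICAL, nuc.MEDULLARY_OR_HD,
        ]

    def test_partition_property(self, small_phantom):
        _, stack, truth = small_phantom
        rs = truth.region_masks
        pts = truth.nuclei[truth.nuclei.channel == "GFP"]
        table = pts.rename(columns={})[["z_um", "y_um", "x_um", "channel"]].copy()
        table["score"] = 1.0
        out = nuc.classify_nuclei(table, rs, rs.region("lobe"))
        assert len(out) == len(table)
        assert set(out.label) <= {nuc.MEDULLARY_OR_HD, nuc.SUBCAPSULAR, nuc.CORTICAL}
        assert out.label.value_counts().sum() == len(table)

    def test_band_shrink_monotonicity(self, small_phantom):
        _, _, truth = small_phantom
        rs = truth.region_masks
        table = truth.nuclei[truth.nuclei.channel == "GFP"][
            ["z_um", "y_um", "x_um", "channel"]
        ].copy()
        table["score"] = 1.0
        counts = []
        for band in (-40.0, -25.0, -10.0, -1.0):
            rules = nuc.ClassificationRules(subcapsular_band_threshold=band)
            out = nuc.classify_nuclei(table, rs, rs.region("lobe"), rules)
            counts.append((out.label == nuc.SUBCAPSULAR).sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDetection:
    def _spot_stack(self, centers, spacing=(2.0, 1.0, 1.0), shape=(24, 48, 48),
                    sigma=(1.5, 1.2, 1.2), peak=100.0):
        img = np.zeros(shape)
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        z, y, x = zz * spacing[0], yy * spacing[1], xx * spacing[2]
        for c in centers:
            img += peak * np.exp(
                -((z - c[0]) ** 2 / (2 * sigma[0] ** 2)
                  + (y - c[1]) ** 2 / (2 * sigma[1] ** 2)
                  + (x - c[2]) ** 2 / (2 * sigma[2] ** 2))
            )
        return ImageStack(channels={"GFP": img}, spacing=spacing)

    def test_isolated_spots_found(self):
        centers = [(12.0, 12.0, 12.0), (24.0, 30.0, 18.0), (36.0, 20.0, 38.0)]
        stack = self._spot_stack(centers)
        det = nuc.detect_nuclei(stack, "GFP", diameter_um=5.0, score_threshold=1.0)
        assert len(det) == 3
        found = det[["z_um", "y_um", "x_um"]].to_numpy()
        for c in centers:
            assert np.min(np.linalg.norm(found - np.asarray(c), axis=1)) < 2.0

    def test_empty_image_empty_table(self):
        stack = ImageStack(channels={"GFP": np.zeros((12, 24, 24))}, spacing=(2, 1, 1))
        det = nuc.detect_nuclei(stack, "GFP", diameter_um=5.0, score_threshold=1.0)
        assert len(det) == 0

    def test_log_linearity_scaling(self):
        centers = [(12.0, 12.0, 12.0), (24.0, 30.0, 18.0)]
        stack = self._spot_stack(centers)
        d1 = nuc.detect_nuclei(stack, "GFP", diameter_um=5.0, score_threshold=2.0)
        doubled = ImageStack(
            channels={"GFP": stack.channel("GFP") * 2}, spacing=stack.spacing
        )
        d2 = nuc.detect_nuclei(doubled, "GFP", diameter_um=5.0, score_threshold=4.0)
        np.testing.assert_allclose(
            d1[["z_um", "y_um", "x_um"]].to_numpy(),
            d2[["z_um", "y_um", "x_um"]].to_numpy(),
        )

    def test_subvoxel_diameter_rejected(self):
        stack = ImageStack(channels={"GFP": np.zeros((6, 8, 8))}, spacing=(5, 1, 1))
        with pytest.raises(ValueError, match="pitch"):
            nuc.detect_nuclei(stack, "GFP", diameter_um=4.0)


class TestDensitiesAndCounts:
    def test_density_arithmetic(self):
        rs = _ball_regions()
        table = pd.DataFrame(
            {"z_um": [24.0], "y_um": [20.0], "x_um": [20.0],
             "channel": ["GFP"], "score": [1.0], "region": ["medulla"]}
        )
        dens = nuc.compute_densities(table, rs)
        row = dens[(dens.region == "medulla") & (dens.channel == "GFP")].iloc[0]
        assert row["count"] == 1
        assert row.density_per_um3 * row.volume_um3 == pytest.approx(1.0)

    def test_zero_count_zero_density(self):
        rs = _ball_regions()
        table = pd.DataFrame(
            {"z_um": [24.0], "y_um": [20.0], "x_um": [20.0],
             "channel": ["GFP"], "score": [1.0], "region": ["medulla"]}
        )
        dens = nuc.compute_densities(table, rs)
        assert (dens.loc[dens.region == "hd", "density_per_um3"] == 0).all()

    def test_estimate_counts_product_identity(self):
        dens = pd.DataFrame(
            {"region": ["medulla"], "channel": ["GFP"],
             "count": [100], "volume_um3": [1e5], "density_per_um3": [1e-3]}
        )
        est = nuc.estimate_counts(dens, {"medulla": 5e7})
        assert est.estimated_count.iloc[0] == pytest.approx(5e4)
        est0 = nuc.estimate_counts(dens, {"medulla": 0.0})
        assert est0.estimated_count.iloc[0] == 0

    def test_region_mismatch_listed(self):
        dens = pd.DataFrame(
            {"region": ["medulla"], "channel": ["GFP"],
             "count": [1], "volume_um3": [1.0], "density_per_um3": [1.0]}
        )
        with pytest.raises(KeyError, match="medulla"):
            nuc.estimate_counts(dens, {"cortex": 1.0})

    @given(
        dens=st.floats(1e-6, 1e-2), vol=st.floats(1.0, 1e9),
    )
    def test_product_exactness_property(self, dens, vol):
        table = pd.DataFrame(
            {"region": ["medulla"], "channel": ["GFP"], "count": [1],
             "volume_um3": [1.0], "density_per_um3": [dens]}
        )
        est = nuc.estimate_counts(table, {"medulla": vol})
        assert est.estimated_count.iloc[0] == dens * vol
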