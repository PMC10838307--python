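import numpy as np
import pandas as pd
import pytest
from scipy.special import ellipe

from senodetect.features import (
    DegenerateShapeError,
    QCParams,
    compute_feature_table,
    compute_features,
    qc_filter,
    segment_image,
)

RTOL = 0.05  # rasterization tolerance for closed-form oracles


class TestDiscOracles:
    """A rasterized disc of radius r has closed-form descriptors."""

    r = 20.0

    @pytest.fixture(autouse=True)
    def _disc(self, ellipse_mask):
        self.mask = ellipse_mask(self.r, self.r)
        self.feats = compute_features(
            self.mask, "core7", pixel_size=1.0, intensity_image=self.mask.astype(float)
        )

    def test_area(self):
        assert self.feats["Area"] == pytest.approx(np.pi * self.r**2, rel=0.03)

    def test_round_ratios_near_one(self):
        assert self.feats["FormFactor"] == pytest.approx(1.0, abs=0.05)
        assert self.feats["Elongation"] == pytest.approx(1.0, abs=0.05)
        assert self.feats["ChordRatio"] == pytest.approx(1.0, abs=0.05)

    def test_gyration_radius_is_r_over_sqrt2(self):
        # continuous-disc second moment: mean(rho^2) = r^2/2
        assert self.feats["GyrationRadius"] == pytest.approx(self.r / np.sqrt(2), rel=RTOL)

    def test_compactness_is_mean_distance(self):
        # mean distance from center of a disc = 2r/3
        assert self.feats["Compactness"] == pytest.approx(2 * self.r / 3, rel=RTOL)

    def test_displacement_zero_for_uniform_intensity(self):
        assert self.feats["Displacement"] == pytest.approx(0.0, abs=1e-6)

    def test_eccentricity_near_zero(self):
        f = compute_features(self.mask, "tissue6", pixel_size=1.0)
        assert f["Eccentricity"] == pytest.approx(0.0, abs=0.1)
        assert f["Circularity"] == pytest.approx(1.0, abs=0.05)


class TestEllipseOracles:
    def test_two_to_one_elongation_and_caliper(self, ellipse_mask):
        a, b = 40.0, 20.0
        mask = ellipse_mask(a, b)
        f = compute_features(mask, "extended17", pixel_size=1.0)
        assert f["MinorAxisLength"] / f["MajorAxisLength"] == pytest.approx(0.5, abs=0.03)
        assert f["MaxFeretDiameter"] == pytest.approx(2 * a, abs=2.0)

    def test_core7_two_to_one_elongation(self, ellipse_mask):
        f = compute_features(ellipse_mask(40, 20), "core7", 1.0, ellipse_mask(40, 20).astype(float))
        assert f["Elongation"] == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("ratio", [1.0, 0.75, 0.5, 0.25])
    def test_closed_forms_across_axis_ratios(self, ellipse_mask, ratio):
        a = 40.0
        b = ratio * a
        mask = ellipse_mask(a, b)
        f = compute_features(mask, "tissue6", pixel_size=1.0)
        e2 = 1.0 - ratio**2
        perimeter = 4.0 * a * ellipe(e2)
        area = np.pi * a * b
        assert f["Area"] == pytest.approx(area, rel=RTOL)
        assert f["Perimeter"] == pytest.approx(perimeter, rel=RTOL)
        assert f["Circularity"] == pytest.approx(4 * np.pi * area / perimeter**2, rel=RTOL)
        assert f["MaxCaliper"] == pytest.approx(2 * a, rel=RTOL)
        assert f["MinCaliper"] == pytest.approx(2 * b, rel=RTOL)
        assert f["Eccentricity"] == pytest.approx(np.sqrt(e2), abs=0.05)

    def test_ellipse_gyration_closed_form(self, ellipse_mask):
        # mean(rho^2) over an ellipse = (a^2 + b^2)/4
        a, b = 30.0, 15.0
        f = compute_features(ellipse_mask(a, b), "extended17", pixel_size=1.0)
        # via the shared member-pixel geometry exercised by Mean/MaxRadius path
        core = compute_features(ellipse_mask(a, b), "core7", 1.0, ellipse_mask(a, b).astype(float))
        assert core["GyrationRadius"] == pytest.approx(np.sqrt((a**2 + b**2) / 4), rel=RTOL)
        assert f["EquivalentDiameter"] == pytest.approx(2 * np.sqrt(a * b), rel=RTOL)
        assert f["Solidity"] == pytest.approx(1.0, abs=0.05)


class TestInvariances:
    def test_scale_equivariance(self, ellipse_mask):
        mask = ellipse_mask(30, 18, angle=0.4)
        inten = mask.astype(float)
        f1 = compute_features(mask, "core7", pixel_size=0.5, intensity_image=inten)
        f2 = compute_features(mask, "core7", pixel_size=1.0, intensity_image=inten)
        assert f2["Area"] == pytest.approx(4 * f1["Area"])
        assert f2["GyrationRadius"] == pytest.approx(2 * f1["GyrationRadius"])
        assert f2["Compactness"] == pytest.approx(2 * f1["Compactness"])
        for ratio in ("FormFactor", "Elongation", "ChordRatio", "Displacement"):
            assert f2[ratio] == pytest.approx(f1[ratio], abs=1e-12)

    def test_rot90_exact_invariance(self, ellipse_mask):
        mask = ellipse_mask(35, 14, angle=0.3)
        f = compute_features(mask, "tissue6", 1.0)
        f_rot = compute_features(np.rot90(mask), "tissue6", 1.0)
        for name, val in f.items():
            assert f_rot[name] == pytest.approx(val, rel=1e-9), name

    def test_arbitrary_rotation_within_tolerance(self, ellipse_mask):
        f0 = compute_features(ellipse_mask(38, 19, angle=0.0), "tissue6", 1.0)
        f30 = compute_features(ellipse_mask(38, 19, angle=np.pi / 6), "tissue6", 1.0)
        for name in f0:
            assert f30[name] == pytest.approx(f0[name], rel=0.05, abs=0.05), name


class TestErrors:
    def test_tiny_region_is_degenerate(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = mask[4, 5] = True
        with pytest.raises(DegenerateShapeError):
            compute_features(mask, "tissue6", 1.0)

    def test_displacement_requires_intensity(self, ellipse_mask):
        with pytest.raises(ValueError, match="intensity"):
            compute_features(ellipse_mask(10, 10), "core7", 1.0)


class TestSegmentation:
    def test_two_discs_two_labels(self):
        img = np.zeros((100, 100))
        yy, xx = np.mgrid[0:100, 0:100]
        img[np.hypot(yy - 25, xx - 25) < 10] = 1.0
        img[np.hypot(yy - 70, xx - 70) < 10] = 1.0
        labels = segment_image(img, threshold=0.5)
        assert labels.max() == 2

    def test_blank_image_zero_labels(self):
        assert segment_image(np.zeros((50, 50))).max() == 0

    def test_disc_pixel_count_recovered(self):
        img = np.zeros((100, 100))
        yy, xx = np.mgrid[0:100, 0:100]
        img[np.hypot(yy - 50, xx - 50) <= 20] = 1.0
        labels = segment_image(img, threshold=0.5)
        assert np.sum(labels == 1) == pytest.approx(np.pi * 400, rel=0.03)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            segment_image(np.zeros((4, 4, 3)))


class TestFeatureTableAndQC:
    @pytest.fixture()
    def table(self, ellipse_mask):
        labels = np.zeros((200, 200), dtype=np.int32)
        disc = ellipse_mask(12, 12, size=60)
        labels[20:80, 20:80][disc] = 1
        labels[100:160, 100:160][disc] = 2
        small = ellipse_mask(3, 3, size=20)
        labels[170:190, 10:30][small] = 3
        yy, xx = np.mgrid[0:200, 0:200]
        labels[np.hypot(yy - 0, xx - 120) <= 8] = 4  # touches row 0
        return compute_feature_table(labels, "tissue6", pixel_size=1.0)

    def test_one_row_per_nucleus(self, table):
        assert len(table) == 4
        assert set(table["nucleus_id"]).issuperset({"image_0:1", "image_0:2"})

    def test_edge_exclusion(self, table):
        kept, log = qc_filter(table, QCParams(pixel_size=1.0), image_shape=(200, 200))
        assert "edge" in set(log["reason"])
        assert len(kept) + len(log) == len(table)

    def test_diameter_exclusion(self, table):
        params = QCParams(min_diameter=10.0, max_diameter=100.0, pixel_size=1.0)
        kept, log = qc_filter(table, params, image_shape=(200, 200))
        reasons = set(log["reason"])
        assert "diameter" in reasons
        assert all(np.sqrt(4 * a / np.pi) >= 10 for a in kept["Area"])

    def test_all_pass_identity(self, table):
        inner = table[(table["bbox_min_row"] > 0) & (table["bbox_min_col"] > 0)]
        params = QCParams(exclude_edge_objects=False, pixel_size=1.0)
        kept, log = qc_filter(table, params, image_shape=(200, 200))
        assert log.empty
        pd.testing.assert_frame_equal(kept, table)
        assert len(inner) <= len(kept)

    def test_intensity_exclusion(self, ellipse_mask):
        labels = np.zeros((80, 80), np.int32)
        disc = ellipse_mask(8, 8, size=30)
        labels[10:40, 10:40][disc] = 1
        labels[45:75, 45:75][disc] = 2
        intensity = np.where(labels == 1, 0.2, 0.9) * (labels > 0)
        table = compute_feature_table(labels, "tissue6", 1.0, intensity_image=intensity)
        params = QCParams(min_intensity=0.5, exclude_edge_objects=False, pixel_size=1.0)
        kept, log = qc_filter(table, params, image_shape=(80, 80))
        assert list(log["reason"]) == ["intensity"]
        assert len(kept) == 1
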