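"""DoG spot detection, watershed sizing, area fractions."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from endodance.detection import (DetectionParams, area_fraction, dog_detect,
                                 measure_diameter_watershed)
from endodance.regions import AxisFrame, make_zone_mask


def gaussian_frame(shape, cx, cy, sigma=1.2, amp=200.0, bg=0.0):
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    return bg + amp * np.exp(-((cols - cx) ** 2 + (rows - cy) ** 2)
                             / (2 * sigma**2))


def brute_force_maxima(img, threshold=0.0):
    """Oracle: exhaustive 3x3 local-maxima scan of the image."""
    out = []
    for r in range(1, img.shape[0] - 1):
        for c in range(1, img.shape[1] - 1):
            patch = img[r - 1:r + 2, c - 1:c + 2]
            if img[r, c] > threshold and img[r, c] == patch.max() \
                    and (patch < img[r, c]).sum() == 8:
                out.append((r, c))
    return out


class TestDogDetect:
    def test_all_zero_frame(self):
        assert len(dog_detect(np.zeros((64, 64)))) == 0

    def test_constant_frame(self):
        assert len(dog_detect(np.full((32, 32), 7.0))) == 0

    def test_oversized_diameter_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            dog_detect(np.zeros((8, 8)), DetectionParams(dog_diameter=20))

    def test_subpixel_localization(self):
        """Noise-free spot at (10.30, 20.70) px localized within 0.25 px
        and matching the intensity-centroid oracle."""
        img = gaussian_frame((64, 64), cx=10.30, cy=20.70)
        spots = dog_detect(img, DetectionParams(use_median_filter=False))
        assert len(spots) == 1
        assert spots.loc[0, "x"] == pytest.approx(10.30, abs=0.25)
        assert spots.loc[0, "y"] == pytest.approx(20.70, abs=0.25)
        cols, rows = np.meshgrid(np.arange(64), np.arange(64))
        cx = (img * cols).sum() / img.sum()
        cy = (img * rows).sum() / img.sum()
        assert spots.loc[0, "x"] == pytest.approx(cx, abs=0.25)
        assert spots.loc[0, "y"] == pytest.approx(cy, abs=0.25)

    def test_two_spots_vs_brute_force(self):
        img = (gaussian_frame((64, 64), 20, 30)
               + gaussian_frame((64, 64), 30, 30))
        expected = brute_force_maxima(img, threshold=1.0)
        spots = dog_detect(img, DetectionParams(use_median_filter=False))
        assert len(spots) == len(expected) == 2
        got = {(int(round(r["y"])), int(round(r["x"])))
               for _, r in spots.iterrows()}
        assert got == set(expected)

    def test_sorted_by_descending_quality(self):
        img = (gaussian_frame((64, 64), 15, 15, amp=100)
               + gaussian_frame((64, 64), 40, 40, amp=250))
        spots = dog_detect(img, DetectionParams(use_median_filter=False))
        q = spots["quality"].to_numpy()
        assert (np.diff(q) <= 0).all()
        assert spots.loc[0, "x"] == pytest.approx(40, abs=0.5)

    @given(dx=st.floats(-0.45, 0.45), dy=st.floats(-0.45, 0.45))
    def test_refinement_never_leaves_pixel(self, dx, dy):
        """Sub-pixel refinement shifts a spot by at most 0.5 px from the
        integer maximum."""
        img = gaussian_frame((32, 32), cx=16 + dx, cy=16 + dy)
        spots = dog_detect(img, DetectionParams(use_median_filter=False))
        assert len(spots) == 1
        r0, c0 = np.unravel_index(np.argmax(img), img.shape)
        assert abs(spots.loc[0, "x"] - c0) <= 0.5
        assert abs(spots.loc[0, "y"] - r0) <= 0.5

    def test_noise_free_recall_precision(self):
        """Spots >= 4 px apart are all found with nothing spurious."""
        centres = [(10, 10), (10, 20), (25, 40), (40, 12), (50, 50)]
        img = sum(gaussian_frame((64, 64), c, r) for r, c in centres)
        spots = dog_detect(img, DetectionParams(use_median_filter=False))
        assert len(spots) == len(centres)
        for r, c in centres:
            d = np.hypot(spots["x"] - c, spots["y"] - r)
            assert d.min() < 0.5

    def test_noise_mode_threshold_adapts(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(10.0, size=(64, 64)).astype(float)
        img += gaussian_frame((64, 64), 32, 32, amp=150)
        params = DetectionParams(threshold_mode="noise", dog_threshold=5.0,
                                 use_median_filter=False)
        spots = dog_detect(img, params)
        # the particle is found, ranks first, and the noise floor stays low
        assert 1 <= len(spots) <= 3
        assert spots.loc[0, "x"] == pytest.approx(32, abs=0.5)
        assert spots.loc[0, "quality"] == spots["quality"].max()

    def test_calibrated_output_units(self):
        img = gaussian_frame((64, 64), 20, 30)
        spots = dog_detect(img, DetectionParams(use_median_filter=False),
                           pixel_size=0.26, frame_index=3, t=0.3)
        assert spots.loc[0, "x"] == pytest.approx(20 * 0.26, abs=0.1)
        assert spots.loc[0, "frame"] == 3
        assert spots.loc[0, "t"] == 0.3


class TestWatershed:
    def test_disk_diameter(self):
        """Binary disk of radius 5 px at 0.26 um/px measures ~2.6 um."""
        h = w = 32
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        img = ((cols - 16) ** 2 + (rows - 16) ** 2 <= 25).astype(float)
        spots = pd.DataFrame({"x": [16 * 0.26], "y": [16 * 0.26]})
        out, report = measure_diameter_watershed(img, spots, pixel_size=0.26,
                                                 threshold=0.5)
        assert report["n_unset"] == 0
        assert out.loc[0, "diameter_um"] == pytest.approx(2.6, abs=0.26)

    def test_touching_objects_split(self):
        """Two overlapping blobs with two seeds yield two regions, each
        smaller than their union."""
        img = (gaussian_frame((40, 40), 16, 20, sigma=3)
               + gaussian_frame((40, 40), 24, 20, sigma=3))
        spots = pd.DataFrame({"x": [16.0, 24.0], "y": [20.0, 20.0]})
        thr = img.max() * 0.3
        out, _ = measure_diameter_watershed(img, spots, threshold=thr)
        union_area = (img > thr).sum()
        union_diam = 2 * np.sqrt(union_area / np.pi)
        assert out["diameter_um"].notna().all()
        assert (out["diameter_um"] < union_diam).all()
        assert (out["diameter_um"] > 0).all()

    def test_empty_spot_list_unchanged(self):
        img = gaussian_frame((32, 32), 16, 16)
        out, report = measure_diameter_watershed(img, pd.DataFrame(
            columns=["x", "y"]))
        assert len(out) == 0
        assert report["n_spots"] == 0

    def test_background_seed_gets_no_diameter(self):
        img = gaussian_frame((32, 32), 10, 10)
        spots = pd.DataFrame({"x": [10.0, 28.0], "y": [10.0, 28.0]})
        out, report = measure_diameter_watershed(img, spots,
                                                 threshold=img.max() * 0.4)
        assert np.isnan(out.loc[1, "diameter_um"])
        assert report["n_unset"] == 1

    def test_size_ordering_early_vs_late(self, geometry):
        """At the sizing pixel scale (0.1 um/px), watershed diameters
        reproduce the early < late apparent-size ordering with moderate
        median error (diffraction-limited regime)."""
        from endodance.synthetic import OpticsConfig, render_movie
        from conftest import make_truth
        rng = np.random.default_rng(0)
        medians = {}
        for cls, mean, sd in (("early", 197.0, 20.7), ("late", 336.2, 72.0)):
            pos = {i: [[2.0 + 2.5 * (i % 5), 2.0 + 2.5 * (i // 5)]]
                   for i in range(20)}
            diams = {i: float(np.clip(rng.normal(mean, sd), 150, None))
                     for i in range(20)}
            # equal peak brightness so one global threshold cuts every
            # particle at its own half maximum
            intens = {i: 2.5 * (max(diams[i], 250.0) / 250.0) ** 2
                      for i in range(20)}
            truth = make_truth(geometry, pos, diameter_nm=diams,
                               intensity=intens, fov=(16.0, 16.0))
            optics = OpticsConfig(pixel_size=0.1, noise=False, background=0.0)
            stack = render_movie(truth, optics)
            img = stack.frame(0)
            spots = pd.DataFrame(
                [{"x": p[0][0], "y": p[0][1]} for p in pos.values()])
            out, _ = measure_diameter_watershed(
                img, spots, pixel_size=0.1, threshold=img.max() * 0.5)
            rendered_fwhm = np.array([max(diams[i], 250.0) for i in range(20)])
            measured = out["diameter_um"].to_numpy() * 1000
            rel_err = np.abs(measured - rendered_fwhm) / rendered_fwhm
            assert np.median(rel_err) < 0.30
            medians[cls] = np.median(measured)
        assert medians["early"] < medians["late"]


class TestAreaFraction:
    @pytest.fixture
    def mask(self):
        axis = AxisFrame([[40.0, 6.0], [1.0, 6.0]])
        hair = np.zeros((12, 45), dtype=bool)
        hair[2:10, 4:41] = True
        return make_zone_mask((12, 45), axis, hair, pixel_size=1.0)

    def test_all_zero(self, mask):
        out = area_fraction(np.zeros((12, 45)), mask, threshold=1.0)
        assert out["apical"] == 0.0
        assert out["subapical"] == 0.0

    def test_saturated(self, mask):
        out = area_fraction(np.full((12, 45), 255.0), mask, threshold=1.0)
        assert out["apical"] == 1.0
        assert out["subapical"] == 1.0

    def test_exact_half(self, mask):
        """Image lit on exactly half of each zone's pixels -> 0.5."""
        img = np.zeros((12, 45))
        for label in (1, 2):
            rows, cols = np.nonzero(mask.labels == label)
            half = len(rows) // 2
            img[rows[:half], cols[:half]] = 10.0
            expected = half / len(rows)
            out = area_fraction(img, mask, threshold=5.0)
            key = "apical" if label == 1 else "subapical"
            assert out[key] == pytest.approx(expected)

    def test_empty_zone_warns_nan(self):
        axis = AxisFrame([[8.0, 6.0], [1.0, 6.0]])  # hair shorter than 10 um
        hair = np.zeros((12, 20), dtype=bool)
        hair[4:9, 2:9] = True
        m = make_zone_mask((12, 20), axis, hair, pixel_size=1.0)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = area_fraction(np.ones((12, 20)), m, threshold=0.5)
        assert np.isnan(out["subapical"])
        assert any("subapical" in str(w.message) for w in rec)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_threshold(self, seed):
        axis = AxisFrame([[40.0, 6.0], [1.0, 6.0]])
        hair = np.zeros((12, 45), dtype=bool)
        hair[2:10, 4:41] = True
        m = make_zone_mask((12, 45), axis, hair, pixel_size=1.0)
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 100, size=(12, 45))
        fracs = [area_fraction(img, m, thr)["subapical"]
                 for thr in (10.0, 30.0, 50.0, 90.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
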