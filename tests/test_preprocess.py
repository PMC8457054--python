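"""Binarization, closing, cluster removal and hole filling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netskel.preprocess import (
    BinarizationParams,
    NoStructureError,
    binarize,
    fill_holes,
    gaussian_blur,
    morphological_close,
    preprocess_stack,
    remove_small_clusters,
    slice_threshold_otsu,
    slice_threshold_percentile,
)
from netskel.topology import count_components
from netskel.volume_io import BinaryVolume, ImageStack, VoxelGeometry


class TestPercentileThreshold:
    def test_threshold_formula(self):
        # I_T = I_10 + V_u (I_90 - I_10) with I_10=100, I_90=200, V_u=0.3
        sl = np.concatenate([np.full(200, 100.0), np.linspace(100, 200, 600),
                             np.full(200, 200.0)])
        rec = slice_threshold_percentile(sl, 0.3)
        assert rec.i_10 == pytest.approx(100.0, abs=0.5)
        assert rec.i_90 == pytest.approx(200.0, abs=0.5)
        assert rec.i_t == pytest.approx(rec.i_10 + 0.3 * (rec.i_90 - rec.i_10))

    @pytest.mark.parametrize("v_u", [0.0, 1.0])
    def test_endpoints(self, v_u):
        sl = np.arange(100.0)
        rec = slice_threshold_percentile(sl, v_u)
        assert rec.i_t == pytest.approx(rec.i_10 if v_u == 0 else rec.i_90)

    def test_linear_ramp_against_sort_oracle(self):
        sl = np.arange(1000.0)  # pixel intensities 0..999
        rec = slice_threshold_percentile(sl, 0.4)
        # independent sort-based linear-interpolation quantile
        s = np.sort(sl)

        def quantile(q):
            pos = (len(s) - 1) * q
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        i10, i90 = quantile(0.1), quantile(0.9)
        assert rec.i_10 == pytest.approx(i10)
        assert rec.i_90 == pytest.approx(i90)
        assert rec.i_t == pytest.approx(i10 + 0.4 * (i90 - i10))

    def test_constant_slice_degenerate(self):
        rec = slice_threshold_percentile(np.full(50, 7.0), 0.5)
        assert rec.degenerate
        assert rec.i_10 == rec.i_90 == rec.i_t == 7.0


class TestOtsuThreshold:
    def test_two_valued_slice_separates_modes(self):
        sl = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)])
        rec = slice_threshold_otsu(sl)
        assert 10.0 < rec.i_t < 200.0

    def test_bimodal_against_exhaustive_search(self, rng):
        sl = np.concatenate(
            [rng.normal(50, 10, 5000), rng.normal(180, 10, 5000)]
        ).clip(0, 255)
        rec = slice_threshold_otsu(sl)
        # exhaustive between-class-variance search over a 256-bin histogram
        hist, edges = np.histogram(sl, bins=256)
        centers = 0.5 * (edges[:-1] + edges[1:])
        best, best_var = None, -1.0
        for k in range(1, 256):
            w0, w1 = hist[:k].sum(), hist[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:k] * centers[:k]).sum() / w0
            m1 = (hist[k:] * centers[k:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best_var, best = var, centers[k - 1]
        assert abs(rec.i_t - best) <= 10.0

    def test_constant_slice_flagged(self):
        rec = slice_threshold_otsu(np.full(100, 3.0))
        assert rec.degenerate


class TestBinarize:
    def test_dark_slice_contributes_nothing(self, unit_geometry):
        values = np.zeros((3, 8, 8))
        values[1] = np.linspace(10, 250, 64).reshape(8, 8)
        values[2] = np.linspace(10, 250, 64).reshape(8, 8)
        stack = ImageStack(values, unit_geometry)
        vol, recs = binarize(stack, BinarizationParams(method="percentile", v_u=0.5))
        assert not vol.material[0].any()
        assert vol.material[1].any()
        assert len(recs) == 3

    def test_uniform_stack_no_material(self, unit_geometry):
        stack = ImageStack(np.full((3, 4, 4), 9.0), unit_geometry)
        vol, _ = binarize(stack, BinarizationParams(method="percentile", v_u=0.5))
        assert not vol.material.any()  # threshold equals the value; strict '>'

    def test_per_slice_locality(self, unit_geometry, rng):
        """Changing one slice changes only that slice's output."""
        values = rng.uniform(0, 255, size=(4, 10, 10))
        a = ImageStack(values.copy(), unit_geometry)
        values2 = values.copy()
        values2[2] = values2[2] * 0.3
        b = ImageStack(values2, unit_geometry)
        p = BinarizationParams(method="percentile", v_u=0.4)
        va, _ = binarize(a, p)
        vb, _ = binarize(b, p)
        for z in (0, 1, 3):
            assert np.array_equal(va.material[z], vb.material[z])

    def test_drift_compensation_on_z_invariant_scene(self, unit_geometry, rng):
        """Per-slice thresholds equalize material fractions under intensity drift."""
        pattern = rng.uniform(0, 1, size=(20, 20))  # same scene in every slice
        nz = 10
        drift = np.linspace(1.0, 0.5, nz)  # 2x intensity decay with depth
        values = pattern[None] * drift[:, None, None] * 255
        stack = ImageStack(values, unit_geometry)
        vol, _ = binarize(stack, BinarizationParams(method="percentile", v_u=0.5))
        fracs = vol.material.mean(axis=(1, 2))
        assert np.ptp(fracs) <= 0.02 * max(fracs.max(), 1e-9)


class TestGaussianBlur:
    def test_width_zero_identity(self, unit_geometry, rng):
        stack = ImageStack(rng.uniform(0, 9, (4, 4, 4)), unit_geometry)
        assert np.array_equal(gaussian_blur(stack, 0).values, stack.values)

    def test_constant_invariance(self, unit_geometry):
        stack = ImageStack(np.full((5, 5, 5), 3.0), unit_geometry)
        assert np.allclose(gaussian_blur(stack, 1.5).values, 3.0)

    def test_point_source_profile_matches_gaussian(self, unit_geometry):
        n = 31
        values = np.zeros((n, n, n))
        values[15, 15, 15] = 1.0
        w = 2.0
        out = gaussian_blur(ImageStack(values, unit_geometry), w).values
        for r in range(1, 5):  # distances up to 2w
            expected = out[15, 15, 15] * np.exp(-0.5 * (r / w) ** 2)
            assert out[15, 15, 15 + r] == pytest.approx(expected, rel=0.01)


class TestMorphologicalClose:
    @staticmethod
    def _two_blocks(gap):
        vol = np.zeros((9, 9, 9 + gap), bool)
        vol[3:6, 3:6, 0:3] = True
        vol[3:6, 3:6, 3 + gap : 6 + gap] = True
        return vol

    def test_gap_closes_at_radius_two(self, unit_geometry):
        vol = BinaryVolume(self._two_blocks(2), unit_geometry)
        closed = morphological_close(vol, 2.0)
        assert count_components(closed.material) == 1

    def test_gap_stays_open_at_half_radius(self, unit_geometry):
        vol = BinaryVolume(self._two_blocks(2), unit_geometry)
        closed = morphological_close(vol, 0.5)
        assert count_components(closed.material) == 2

    def test_solid_cube_unchanged(self, unit_geometry):
        vol = np.zeros((9, 9, 9), bool)
        vol[2:7, 2:7, 2:7] = True
        closed = morphological_close(BinaryVolume(vol, unit_geometry), 2.0)
        assert np.array_equal(closed.material, vol)

    @given(st.integers(0, 3000), st.floats(0.5, 2.5))
    @settings(max_examples=25)
    def test_extensive_and_idempotent(self, seed, radius):
        rng = np.random.default_rng(seed)
        geom = VoxelGeometry(1, 1, 1, "sigma")
        vol = BinaryVolume(rng.random((8, 8, 8)) < 0.25, geom)
        once = morphological_close(vol, radius)
        assert np.all(vol.material <= once.material)  # never removes material
        twice = morphological_close(once, radius)
        assert np.array_equal(once.material, twice.material)


class TestRemoveSmallClusters:
    def test_small_cluster_removed(self, unit_geometry):
        vol = np.zeros((20, 20, 20), bool)
        vol[1:11, 1:11, 1:11] = True  # 1000 voxels
        vol[15, 15, 15:20] = True  # 5 voxels
        out, labels, sizes = remove_small_clusters(
            BinaryVolume(vol, unit_geometry), 0.01
        )
        assert sorted(sizes) == [5, 1000]
        assert out.count() == 1000

    def test_single_cluster_kept(self, unit_geometry):
        vol = np.zeros((5, 5, 5), bool)
        vol[1:4, 1:4, 1:4] = True
        out, _, _ = remove_small_clusters(BinaryVolume(vol, unit_geometry), 1.0)
        assert out.count() == 27

    def test_three_clusters_fraction_rule(self, unit_geometry):
        vol = np.zeros((40, 20, 20), bool)
        vol[1:7, 1:11, 1:11] = True  # 600
        vol[10:13, 1:11, 1:11] = True  # 300
        vol[20:21, 1:11, 1:11] = True  # 100
        out, labels, sizes = remove_small_clusters(
            BinaryVolume(vol, unit_geometry), 0.2
        )
        assert sorted(sizes) == [100, 300, 600]
        assert out.count() == 900
        assert labels.max() == 2  # two surviving labeled structures

    def test_all_removed_raises(self, unit_geometry):
        vol = np.zeros((5, 5, 5), bool)
        vol[1, 1, 1] = True
        vol[3, 3, 3] = True
        with pytest.raises(NoStructureError):
            # each cluster is half the total, threshold demands everything
            remove_small_clusters(BinaryVolume(vol, unit_geometry), 1.0)


class TestFillHoles:
    def test_enclosed_cavity_filled(self, unit_geometry):
        vol = np.ones((5, 5, 5), bool)
        vol[2, 2, 2] = False
        out = fill_holes(BinaryVolume(vol, unit_geometry), 5)
        assert out.material.all()

    def test_large_cavity_kept(self, unit_geometry):
        vol = np.ones((7, 7, 7), bool)
        vol[2:5, 2:5, 2:5] = False  # 27-voxel cavity
        out = fill_holes(BinaryVolume(vol, unit_geometry), 5)
        assert not out.material[3, 3, 3]

    def test_open_tube_lumen_never_filled(self, unit_geometry):
        vol = np.ones((7, 7, 7), bool)
        vol[:, 3, 3] = False  # lumen open at both z faces
        out = fill_holes(BinaryVolume(vol, unit_geometry), 1000)
        assert not out.material[:, 3, 3].any()


def test_preprocess_report_reconciles_volumes(unit_geometry, rng):
    """added/removed sets are the exact disjoint diff of binarized vs final."""
    values = rng.uniform(0, 255, size=(8, 16, 16))
    values[2:6, 4:12, 4:12] += 400  # a bright block so structure survives
    stack = ImageStack(values.clip(0, 655), unit_geometry)
    final, labels, report = preprocess_stack(
        stack,
        params=BinarizationParams(method="percentile", v_u=0.5),
        blur_widths=1.0,
        sigma=3.0,
    )
    assert not (report.added & report.removed).any()
    vol0, _ = binarize(gaussian_blur(stack, 1.0),
                       BinarizationParams(method="percentile", v_u=0.5))
    reconstructed = (vol0.material | report.added) & ~report.removed
    assert np.array_equal(reconstructed, final.material)
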