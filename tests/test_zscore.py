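import logging

import numpy as np
import pytest

from centiz import (
    Volume3D,
    VOIMask,
    build_database,
    compute_zmap,
    cluster_threshold,
    mean_positive_z,
    normalize_to_reference,
    smooth,
)
from centiz.zscore import FWHM_TO_SIGMA


def vol_of(data, voxel=2.0):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    return Volume3D(np.asarray(data, float), aff)


class TestSmooth:
    def test_impulse_matches_analytic_gaussian(self):
        # oracle: separable 3D Gaussian evaluated analytically
        n, voxel, fwhm = 33, 2.0, 8.0
        data = np.zeros((n, n, n))
        c = n // 2
        data[c, c, c] = 1.0
        out = smooth(vol_of(data, voxel), fwhm)
        sigma_vox = fwhm * FWHM_TO_SIGMA / voxel
        x = np.arange(n) - c
        g = np.exp(-(x**2) / (2 * sigma_vox**2))
        g /= g.sum()
        expected = g[:, None, None] * g[None, :, None] * g[None, None, :]
        np.testing.assert_allclose(out.data, expected, atol=1e-6)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_unchanged_in_deep_interior(self):
        out = smooth(vol_of(np.ones((40, 40, 40))), 8.0)
        np.testing.assert_allclose(out.data[15:25, 15:25, 15:25], 1.0, atol=1e-9)

    def test_sub_voxel_fwhm_is_noop_with_warning(self, rng, caplog):
        vol = vol_of(rng.random((8, 8, 8)))
        with caplog.at_level(logging.WARNING, logger="centiz.zscore"):
            out = smooth(vol, 0.5)
        np.testing.assert_array_equal(out.data, vol.data)
        assert "unchanged" in caplog.text

    def test_nonpositive_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth(vol_of(rng.random((4, 4, 4))), 0.0)

    def test_anisotropic_voxels_per_axis_sigma(self):
        # x voxels twice as large: x profile must be narrower in voxel units
        aff = np.diag([4.0, 2.0, 2.0, 1.0])
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        out = smooth(Volume3D(data, aff), 8.0)
        falloff_x = out.data[11, 10, 10] / out.data[10, 10, 10]
        falloff_y = out.data[10, 11, 10] / out.data[10, 10, 10]
        assert falloff_x < falloff_y * 0.8  # narrower in voxel units along the coarse axis


class TestNormalizeToReference:
    def test_reference_mean_becomes_one(self, rng):
        vol = vol_of(rng.random((8, 8, 8)) + 0.5)
        ref = VOIMask(rng.random((8, 8, 8)) > 0.6, vol.affine, "ref")
        out = normalize_to_reference(vol, ref)
        assert out.data[ref.data].mean() == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self, rng):
        vol = vol_of(rng.random((8, 8, 8)) + 0.5)
        ref = VOIMask(rng.random((8, 8, 8)) > 0.6, vol.affine, "ref")
        out1 = normalize_to_reference(vol, ref)
        out3 = normalize_to_reference(vol.copy(vol.data * 3.0), ref)
        np.testing.assert_allclose(out1.data, out3.data, atol=1e-12)

    def test_two_region_toy_ratio(self):
        data = np.ones((6, 6, 6))
        data[:3] = 1.2
        vol = vol_of(data)
        ref = np.zeros((6, 6, 6), bool)
        ref[3:] = True
        target = ~ref
        out = normalize_to_reference(vol, VOIMask(ref, vol.affine))
        assert out.data[target].mean() == pytest.approx(1.2)

    def test_zero_reference_rejected(self):
        vol = vol_of(np.zeros((4, 4, 4)))
        ref = VOIMask(np.ones((4, 4, 4), bool), vol.affine)
        with pytest.raises(ValueError):
            normalize_to_reference(vol, ref)


def _toy_setup(rng, n=4, delta=None, base=None):
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    shape = (10, 10, 10)
    brain = np.zeros(shape, bool)
    brain[2:8, 2:8, 2:8] = True
    ref = np.zeros(shape, bool)
    ref[4:6, 4:6, 4:6] = True
    base = rng.random(shape) + 1.0 if base is None else base
    controls = []
    for i in range(n):
        d = base.copy()
        if delta is not None and i % 2 == 1:
            d = d + delta
        controls.append(Volume3D(d, aff))
    return controls, VOIMask(ref, aff, "ref"), VOIMask(brain, aff, "brain")


class TestBuildDatabase:
    def test_identical_controls_have_zero_sd(self, rng):
        controls, ref, brain = _toy_setup(rng, n=2)
        db = build_database(controls, ref, brain, fwhm_mm=4.0)
        np.testing.assert_allclose(db.sd_img.data, 0.0, atol=1e-12)

    def test_two_sample_sd_closed_form(self, rng):
        # controls {c, c+delta} with delta constant: after reference
        # normalization both equal c/ref-mean shifted; build with raw identity
        # smoothing bypassed by sub-voxel fwhm -> sd = |d1 - d2| / sqrt(2)
        controls, ref, brain = _toy_setup(rng, n=2, delta=0.0)
        c = controls[0].data
        controls[1] = controls[1].copy(c * 1.5)  # pure scale: cancelled by normalization
        db = build_database(controls, ref, brain, fwhm_mm=0.1)
        np.testing.assert_allclose(db.sd_img.data, 0.0, atol=1e-10)
        # now an additive, non-constant delta survives normalization
        rng2 = np.random.default_rng(7)
        delta = rng2.random(c.shape) * 0.1
        d2 = c + delta
        norm1 = c / c[ref.data].mean()
        norm2 = d2 / d2[ref.data].mean()
        db2 = build_database([controls[0], controls[0].copy(d2)], ref, brain, fwhm_mm=0.1)
        np.testing.assert_allclose(db2.sd_img.data, np.abs(norm1 - norm2) / np.sqrt(2), atol=1e-10)

    def test_mean_sd_match_brute_force(self, rng):
        controls, ref, brain = _toy_setup(rng, n=5)
        for c in controls:
            c.data += rng.random(c.shape) * 0.3
        db = build_database(controls, ref, brain, fwhm_mm=4.0)
        from centiz.zscore import normalize_to_reference as n2r, smooth as sm

        stack = np.stack([n2r(sm(c, 4.0), ref).data for c in controls])
        np.testing.assert_allclose(db.mean_img.data, stack.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(db.sd_img.data, stack.std(axis=0, ddof=1), atol=1e-10)

    def test_phantom_database_excludes_white_matter_core(self, template_and_masks):
        from centiz.phantom import make_database

        template, masks, subjects = make_database(n=8, seed=4)
        db = build_database([s.pet for s in subjects], masks["WhlCbl"], masks["brain"])
        wm = masks["white_matter"].data
        frac_wm_in_analysis = (db.analysis_mask.data & wm).sum() / wm.sum()
        assert frac_wm_in_analysis < 0.15
        assert db.analysis_mask.n_voxels() > 0

    def test_rejects_single_control(self, rng):
        controls, ref, brain = _toy_setup(rng, n=1)
        with pytest.raises(ValueError):
            build_database(controls, ref, brain)


class TestComputeZmap:
    def _db(self, rng, n=5):
        controls, ref, brain = _toy_setup(rng, n=n)
        for c in controls:
            c.data += rng.random(c.shape) * 0.3
        return build_database(controls, ref, brain, fwhm_mm=4.0), ref

    def test_database_mean_gives_zero_map(self, rng):
        db, _ = self._db(rng)
        res = compute_zmap(db.mean_img, db)
        np.testing.assert_allclose(res.zmap.data, 0.0, atol=1e-12)

    def test_mean_plus_two_sd_gives_two(self, rng):
        db, _ = self._db(rng)
        floor = max(1e-3, 0.05 * np.median(db.sd_img.data[db.analysis_mask.data]))
        subject = db.mean_img.copy(db.mean_img.data + 2.0 * np.maximum(db.sd_img.data, floor))
        res = compute_zmap(subject, db)
        m = db.analysis_mask.data
        np.testing.assert_allclose(res.zmap.data[m], 2.0, atol=1e-9)

    def test_zero_outside_mask(self, rng):
        db, _ = self._db(rng)
        subject = db.mean_img.copy(db.mean_img.data + 5.0)
        res = compute_zmap(subject, db)
        assert np.all(res.zmap.data[~db.analysis_mask.data] == 0)

    def test_grid_mismatch_rejected(self, rng):
        db, _ = self._db(rng)
        bad = Volume3D(np.ones((5, 5, 5)), np.eye(4))
        with pytest.raises(ValueError):
            compute_zmap(bad, db)

    def test_global_intensity_scaling_cancels(self, rng):
        # scaling all controls and the subject by the same factor leaves the
        # Z map untouched: reference normalization cancels the scale
        controls, ref, brain = _toy_setup(rng, n=5)
        for c in controls:
            c.data += rng.random(c.shape) * 0.3
        subj_data = controls[0].data * 1.1 + 0.05 * rng.random(controls[0].shape)
        db1 = build_database(controls, ref, brain, fwhm_mm=4.0)
        s1 = normalize_to_reference(smooth(Volume3D(subj_data, controls[0].affine), 4.0), ref)
        z1 = compute_zmap(s1, db1)
        scaled = [c.copy(c.data * 7.3) for c in controls]
        db2 = build_database(scaled, ref, brain, fwhm_mm=4.0)
        s2 = normalize_to_reference(smooth(Volume3D(subj_data * 7.3, controls[0].affine), 4.0), ref)
        z2 = compute_zmap(s2, db2)
        np.testing.assert_allclose(z1.zmap.data, z2.zmap.data, atol=1e-9)


def flood_fill_clusters(above, offsets):
    """Brute-force BFS connected components oracle."""
    seen = np.zeros_like(above, bool)
    comps = []
    idx = np.argwhere(above)
    for start in map(tuple, idx):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in offsets:
                q = tuple(np.add(p, off))
                if all(0 <= q[d] < above.shape[d] for d in range(3)) and above[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


def offsets_for(connectivity):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


class TestClusterThreshold:
    def test_two_blobs_min_voxel_filter(self):
        data = np.zeros((10, 10, 10))
        data[1:6, 1, 1] = 3.0          # 5-voxel line
        data[8, 8, 8] = 3.0            # 2-voxel pair
        data[8, 8, 7] = 3.0
        vol = vol_of(data)
        clusters = cluster_threshold(vol, 2.0, min_voxels=3, connectivity=6)
        assert len(clusters) == 1
        assert clusters[0].size_voxels == 5
        # oracle agreement on sizes without the filter
        comps = flood_fill_clusters(data >= 2.0, offsets_for(6))
        assert sorted(len(c) for c in comps) == [2, 5]

    def test_diagonal_blob_connectivity(self):
        data = np.zeros((6, 6, 6))
        for i in range(4):
            data[i, i, 0] = 5.0      # body-diagonal chain in a 2D plane
        vol = vol_of(data)
        assert len(cluster_threshold(vol, 1.0, connectivity=26)) == 1
        assert len(cluster_threshold(vol, 1.0, connectivity=6)) == 4
        for conn in (6, 18, 26):
            sizes = sorted(c.size_voxels for c in cluster_threshold(vol, 1.0, connectivity=conn))
            oracle = sorted(len(c) for c in flood_fill_clusters(data >= 1.0, offsets_for(conn)))
            assert sizes == oracle

    def test_all_zero_map_is_empty(self):
        assert cluster_threshold(vol_of(np.zeros((5, 5, 5))), 1.0) == []

    def test_peaks_and_ordering(self, rng):
        data = np.zeros((12, 12, 12))
        data[2:5, 2:5, 2:5] = 3.0
        data[3, 3, 3] = 9.0
        data[9, 9, 9] = 4.0
        clusters = cluster_threshold(vol_of(data), 2.5, connectivity=18)
        assert clusters[0].size_voxels == 27
        assert clusters[0].peak_value == 9.0
        assert clusters[0].peak_index == (3, 3, 3)
        assert clusters[1].size_voxels == 1

    def test_unknown_connectivity_rejected(self):
        with pytest.raises(ValueError):
            cluster_threshold(vol_of(np.zeros((4, 4, 4))), 1.0, connectivity=10)


class TestMeanPositiveZ:
    def _target(self, shape=(6, 6, 6)):
        m = np.zeros(shape, bool)
        m[:, :, :3] = True
        return m

    def test_constant_positive(self):
        t = self._target()
        z = vol_of(np.full((6, 6, 6), 2.0))
        mpz, n = mean_positive_z(z, VOIMask(t, z.affine))
        assert mpz == pytest.approx(2.0)
        assert n == t.sum()

    def test_mixed_signs_average_positive_only(self):
        data = np.full((6, 6, 6), -1.0)
        data[:, :3, :] = 3.0
        z = vol_of(data)
        t = np.ones((6, 6, 6), bool)
        mpz, n = mean_positive_z(z, VOIMask(t, z.affine))
        assert mpz == pytest.approx(3.0)
        assert n == 108

    def test_all_negative_returns_zero(self):
        z = vol_of(np.full((6, 6, 6), -2.0))
        mpz, n = mean_positive_z(z, VOIMask(self._target(), z.affine))
        assert mpz == 0.0 and n == 0
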