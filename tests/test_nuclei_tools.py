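import numpy as np
import pytest
from scipy import ndimage

from tissuescope3d.volumetric_core import VolumeImage
from tissuescope3d.mesh_segmentation import mesh_from_mask, TriangleMesh
from tissuescope3d.nuclei_tools import (
    Ellipsoid, NucleusObject, fit_min_volume_ellipsoid, ellipsoid_fit_mse,
    fit_double_ellipsoid, classify_multiplicity, logmp_seeds,
    analyse_nucleus_objects, split_multinucleus, dapi_integral,
    normalize_dapi)


def _ellipsoid_samples(rng, axes=(6.0, 5.0, 4.0), n=500, centre=(0, 0, 0)):
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * np.asarray(axes) + np.asarray(centre)


class TestMVE:
    def test_axes_recovered_from_surface_samples(self, rng):
        pts = _ellipsoid_samples(rng, centre=(10, 20, 30))
        ell = fit_min_volume_ellipsoid(pts)
        assert np.allclose(ell.semi_axes, [6, 5, 4], rtol=0.01)
        assert np.allclose(ell.c, [10, 20, 30], atol=0.05)

    def test_enclosure_constraint(self, rng):
        pts = _ellipsoid_samples(rng)
        ell = fit_min_volume_ellipsoid(pts)
        assert ell.quadratic_form(pts).max() <= 1.001

    def test_rotation_equivariance(self, rng):
        pts = _ellipsoid_samples(rng)
        th = np.deg2rad(30)
        R = np.array([[1, 0, 0],
                      [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        e1 = fit_min_volume_ellipsoid(pts)
        e2 = fit_min_volume_ellipsoid(pts @ R.T)
        assert np.allclose(e1.semi_axes, e2.semi_axes, rtol=0.01)
        assert np.allclose(R @ e1.E @ R.T, e2.E, rtol=0.05, atol=1e-4)

    def test_coplanar_points_raise(self, rng):
        pts = rng.normal(size=(50, 3))
        pts[:, 2] = 0.0
        with pytest.raises(ValueError):
            fit_min_volume_ellipsoid(pts)


class TestEllipsoidMSE:
    def test_exact_surface_is_zero(self, rng):
        pts = _ellipsoid_samples(rng, n=100)
        ell = Ellipsoid(np.zeros(3), np.diag([1 / 36, 1 / 25, 1 / 16]))
        mesh = TriangleMesh(pts, np.zeros((1, 3), dtype=int))
        assert ellipsoid_fit_mse(mesh, ell) == pytest.approx(0.0, abs=1e-12)

    def test_ten_vertex_hand_evaluation(self, rng):
        pts = rng.normal(size=(10, 3)) * 3
        ell = Ellipsoid(np.zeros(3), np.eye(3) / 9.0)
        q = np.einsum("ij,jk,ik->i", pts, ell.E, pts)
        expected = ((q - 1) ** 2).sum() / (10 - 9)
        mesh = TriangleMesh(pts, np.zeros((1, 3), dtype=int))
        assert ellipsoid_fit_mse(mesh, ell) == pytest.approx(expected)

    def test_too_few_vertices_raise(self):
        mesh = TriangleMesh(np.zeros((9, 3)), np.zeros((1, 3), dtype=int))
        with pytest.raises(ValueError):
            ellipsoid_fit_mse(mesh, Ellipsoid(np.zeros(3), np.eye(3)))

    def test_dumbbell_prefers_double_model(self):
        Z, Y, X = np.mgrid[0:40, 0:48, 0:40]
        s1 = ((Z - 20) ** 2 + (Y - 18) ** 2 + (X - 20) ** 2) <= 81
        s2 = ((Z - 20) ** 2 + (Y - 32) ** 2 + (X - 20) ** 2) <= 81
        m = mesh_from_mask(s1 | s2, (1, 1, 1))[0]
        single = fit_min_volume_ellipsoid(m.vertices)
        double = fit_double_ellipsoid(m)
        assert ellipsoid_fit_mse(m, double) < ellipsoid_fit_mse(m, single)
        # a lone sphere prefers the single model
        ms = mesh_from_mask(s1, (1, 1, 1))[0]
        assert ellipsoid_fit_mse(ms, fit_min_volume_ellipsoid(ms.vertices)) \
            < ellipsoid_fit_mse(ms, fit_double_ellipsoid(ms))


class TestClassifyMultiplicity:
    def test_threshold_matches_generating_mixture(self, rng):
        x = np.concatenate([rng.normal(-4, 0.5, 300), rng.normal(-1, 0.5, 100)])
        thr, labels, fallback = classify_multiplicity(x, ["mono"] * 400)
        assert not fallback
        assert thr == pytest.approx(-4 + 1.96 * 0.5, abs=0.25)

    def test_identical_values_fall_back_flagged(self):
        x = np.full(40, -3.0)
        thr, labels, fallback = classify_multiplicity(x)
        assert fallback

    def test_labels_monotone_in_ln_mse(self, rng):
        x = np.sort(np.concatenate([rng.normal(-4, 0.5, 200),
                                    rng.normal(-1, 0.5, 100)]))
        _, labels, _ = classify_multiplicity(x, ["mono"] * 300)
        codes = np.array([0 if l != "multi" else 1 for l in labels])
        assert np.all(np.diff(codes) >= 0)

    def test_needs_enough_objects(self):
        with pytest.raises(ValueError):
            classify_multiplicity(np.zeros(10))


class TestLoGMP:
    def test_single_blob_single_seed(self):
        img = np.zeros((40, 40, 40))
        img[20, 20, 20] = 1000.0
        img = ndimage.gaussian_filter(img, 4.0)
        v = VolumeImage(img, (1, 1, 1))
        seeds = logmp_seeds(v, 3.0, 6.0)
        assert len(seeds) == 1
        assert np.abs(seeds[0] - 20).max() <= 1

    def test_overlapping_spheres_give_two_seeds(self):
        Z, Y, X = np.mgrid[0:40, 0:48, 0:40]
        s1 = ((Z - 20) ** 2 + (Y - 19) ** 2 + (X - 20) ** 2) <= 36
        s2 = ((Z - 20) ** 2 + (Y - 29) ** 2 + (X - 20) ** 2) <= 36
        img = ndimage.gaussian_filter((s1 | s2).astype(float) * 100, 1.5)
        v = VolumeImage(img, (1, 1, 1))
        seeds = logmp_seeds(v, 6 / np.sqrt(2) * 0.7, 6 / np.sqrt(2) * 1.3)
        assert len(seeds) == 2

    def test_empty_image_no_seeds(self):
        v = VolumeImage(np.zeros((20, 20, 20)), (1, 1, 1))
        assert len(logmp_seeds(v, 2.0, 4.0)) == 0

    def test_inverted_sigma_range_raises(self):
        v = VolumeImage(np.zeros((20, 20, 20)), (1, 1, 1))
        with pytest.raises(ValueError):
            logmp_seeds(v, 4.0, 2.0)


class TestSplitting:
    def test_mono_object_unchanged(self):
        Z, Y, X = np.mgrid[0:32, 0:32, 0:32]
        m = mesh_from_mask(((Z - 16) ** 2 + (Y - 16) ** 2 + (X - 16) ** 2) <= 64,
                           (1, 1, 1))[0]
        obj = NucleusObject(m, "mono")
        out = split_multinucleus(obj, VolumeImage(np.zeros((32, 32, 32)),
                                                  (1, 1, 1)))
        assert out == [obj]

    def test_overlapping_pair_split_accurately(self):
        Z, Y, X = np.mgrid[0:40, 0:48, 0:40]
        c1, c2 = np.array([20, 18.5, 20.0]), np.array([20, 28.7, 20.0])
        s1 = ((Z - c1[0]) ** 2 + (Y - c1[1]) ** 2 + (X - c1[2]) ** 2) <= 36
        s2 = ((Z - c2[0]) ** 2 + (Y - c2[1]) ** 2 + (X - c2[2]) ** 2) <= 36
        img = ndimage.gaussian_filter((s1 | s2).astype(float) * 100, 1.0)
        dapi = VolumeImage(img, (1, 1, 1))
        parent = mesh_from_mask(s1 | s2, (1, 1, 1))[0]
        objs = analyse_nucleus_objects([parent])
        assert objs[0].multiplicity == "double"
        parts = split_multinucleus(objs[0], dapi, sigma_min=6 / np.sqrt(2) * 0.7,
                                   sigma_max=6 / np.sqrt(2) * 1.3)
        assert len(parts) == 2
        centres = sorted(p.mesh.centroid[1] for p in parts)
        assert abs(centres[0] - c1[1]) < 1.5
        assert abs(centres[1] - c2[1]) < 1.5
        v_parent = parent.volume
        v_parts = sum(p.mesh.volume for p in parts)
        assert 0.9 * v_parent <= v_parts <= 1.05 * v_parent

    def test_split_volumes_match_generating_spheres(self):
        Z, Y, X = np.mgrid[0:40, 0:48, 0:40]
        s1 = ((Z - 20) ** 2 + (Y - 18) ** 2 + (X - 20) ** 2) <= 36
        s2 = ((Z - 20) ** 2 + (Y - 29) ** 2 + (X - 20) ** 2) <= 36
        img = ndimage.gaussian_filter((s1 | s2).astype(float) * 100, 1.0)
        parent = mesh_from_mask(s1 | s2, (1, 1, 1))[0]
        objs = analyse_nucleus_objects([parent])
        parts = split_multinucleus(objs[0], VolumeImage(img, (1, 1, 1)),
                                   sigma_min=3.0, sigma_max=5.5)
        v_sphere = 4 / 3 * np.pi * 216
        for p in parts:
            assert p.mesh.volume == pytest.approx(v_sphere, rel=0.25)


class TestDapiIntegral:
    def test_uniform_intensity_counts_interior_voxels(self, sphere_mask):
        m = mesh_from_mask(sphere_mask, (1, 1, 1))[0]
        dapi = VolumeImage(np.where(sphere_mask, 10.0, 0.0), (1, 1, 1))
        assert dapi_integral(m, dapi) == pytest.approx(10.0 * sphere_mask.sum())

    def test_matches_brute_force_inside_test(self, rng):
        Z, Y, X = np.mgrid[0:32, 0:32, 0:32]
        mask = ((Z - 16) ** 2 + (Y - 14) ** 2 + (X - 18) ** 2) <= 49
        m = mesh_from_mask(mask, (1, 1, 1))[0]
        vals = rng.random((32, 32, 32))
        dapi = VolumeImage(vals, (1, 1, 1))
        assert dapi_integral(m, dapi) == pytest.approx(vals[mask].sum())

    def test_translation_invariance(self, rng):
        Z, Y, X = np.mgrid[0:32, 0:32, 0:32]
        mask1 = ((Z - 12) ** 2 + (Y - 12) ** 2 + (X - 12) ** 2) <= 36
        mask2 = ((Z - 18) ** 2 + (Y - 18) ** 2 + (X - 18) ** 2) <= 36
        m1 = mesh_from_mask(mask1, (1, 1, 1))[0]
        m2 = mesh_from_mask(mask2, (1, 1, 1))[0]
        dapi1 = VolumeImage(np.where(mask1, 7.0, 0.0), (1, 1, 1))
        dapi2 = VolumeImage(np.where(mask2, 7.0, 0.0), (1, 1, 1))
        assert dapi_integral(m1, dapi1) == pytest.approx(dapi_integral(m2, dapi2))

    def test_additive_over_disjoint_meshes(self, rng):
        Z, Y, X = np.mgrid[0:32, 0:32, 0:32]
        mask1 = ((Z - 10) ** 2 + (Y - 10) ** 2 + (X - 10) ** 2) <= 25
        mask2 = ((Z - 22) ** 2 + (Y - 22) ** 2 + (X - 22) ** 2) <= 25
        m1 = mesh_from_mask(mask1, (1, 1, 1))[0]
        m2 = mesh_from_mask(mask2, (1, 1, 1))[0]
        vals = rng.random((32, 32, 32))
        dapi = VolumeImage(vals, (1, 1, 1))
        both = dapi_integral(m1, dapi) + dapi_integral(m2, dapi)
        assert both == pytest.approx(vals[mask1 | mask2].sum())


class TestNormalizeDapi:
    def _hist(self, vals, bins=100, rng_=(0, 5000)):
        counts, edges = np.histogram(vals, bins=bins, range=rng_)
        return counts, 0.5 * (edges[:-1] + edges[1:])

    def test_identity_scale(self, rng):
        vals = rng.lognormal(np.log(1000), 0.3, 20000)
        h = self._hist(vals)
        assert normalize_dapi(h, h) == pytest.approx(1.0, abs=0.02)

    def test_stretch_factor_recovered(self, rng):
        ref = rng.lognormal(np.log(1000), 0.3, 20000)
        s = normalize_dapi(self._hist(ref), self._hist(ref * 1.25))
        assert s == pytest.approx(1.25, rel=0.02)

    def test_empty_histogram_raises(self):
        h = (np.zeros(10), np.arange(10, dtype=float))
        with pytest.raises(ValueError):
            normalize_dapi(h, h)
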