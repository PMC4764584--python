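import numpy as np
import pytest
from scipy import ndimage

from tissuescope3d.volumetric_core import VolumeImage
from tissuescope3d.section_surface import lme_threshold_field
from tissuescope3d.mesh_segmentation import (
    segment_structure, mesh_from_mask, mesh_to_mask, tune_mesh_to_gradient,
    expand_active_mesh, skeletonize_to_graph, segment_cells)


class TestSegmentStructure:
    def test_staining_hole_closed(self, rng):
        img = np.full((32, 32, 64), 10.0)
        Z, Y, X = np.mgrid[0:32, 0:32, 0:64]
        tube = ((Z - 16) ** 2 + (Y - 16) ** 2) <= 25
        img[tube] = 200.0
        img[tube & (X >= 30) & (X < 32)] = 10.0       # 2-voxel staining hole
        img += rng.normal(0, 3, img.shape)
        v = VolumeImage(img, (1, 1, 1))
        fld = lme_threshold_field(v, cube=16, overlap=0.5)
        mask = segment_structure(v, fld, closing=2)
        core = tube & (X >= 30) & (X < 32) & (((Z - 16) ** 2 + (Y - 16) ** 2) <= 9)
        assert mask[core].mean() > 0.9

    def test_bright_tube_mask_superset_within_psf(self, rng):
        img = np.full((32, 32, 64), 10.0)
        Z, Y, X = np.mgrid[0:32, 0:32, 0:64]
        tube = ((Z - 16) ** 2 + (Y - 16) ** 2) <= 16
        img[tube] = 200.0
        img = ndimage.gaussian_filter(img, 1.0)       # PSF-like blur
        img += rng.normal(0, 3, img.shape)
        v = VolumeImage(img, (1, 1, 1))
        fld = lme_threshold_field(v, cube=16, overlap=0.5)
        mask = segment_structure(v, fld, closing=1)
        assert mask[tube].mean() > 0.95               # mask covers the tube
        dist = ndimage.distance_transform_edt(~tube)
        assert dist[mask].max() <= 3.0                # swollen by <= blur width

    def test_empty_image_gives_empty_mask(self, rng):
        v = VolumeImage(rng.normal(100, 5, (32, 32, 32)), (1, 1, 1))
        fld = lme_threshold_field(v, cube=16, overlap=0.5)
        mask = segment_structure(v, fld)
        assert mask.mean() < 0.02


class TestMeshFromMask:
    def test_sphere_volume_and_topology(self, sphere_mask):
        m = mesh_from_mask(sphere_mask, (1, 1, 1))[0]
        assert m.volume == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)
        assert m.euler_characteristic == 2
        tm = m.as_trimesh()
        assert tm.is_watertight
        assert tm.volume > 0                           # outward orientation

    def test_torus_euler_characteristic(self):
        z, y, x = np.mgrid[0:32, 0:48, 0:48]
        rho = np.sqrt((y - 24.0) ** 2 + (x - 24.0) ** 2)
        torus = (rho - 14.0) ** 2 + (z - 16.0) ** 2 <= 25.0
        m = mesh_from_mask(torus, (1, 1, 1))[0]
        assert m.euler_characteristic == 0

    def test_empty_mask(self):
        assert mesh_from_mask(np.zeros((8, 8, 8), bool)) == []

    def test_border_component_flagged_capped(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[0:8, 4:12, 4:12] = True
        m = mesh_from_mask(mask, (1, 1, 1))[0]
        assert m.flags["capped"]

    def test_rasterization_round_trip(self, sphere_mask):
        m = mesh_from_mask(sphere_mask, (1, 1, 1))[0]
        back = mesh_to_mask(m, sphere_mask.shape, (1, 1, 1))
        assert np.array_equal(back, sphere_mask)

    def test_rasterization_round_trip_anisotropic(self, sphere_mask):
        sp = (0.4, 0.4, 0.8)
        m = mesh_from_mask(sphere_mask, sp)[0]
        back = mesh_to_mask(m, sphere_mask.shape, sp)
        assert np.array_equal(back, sphere_mask)


class TestTuneMesh:
    @pytest.mark.parametrize("blur", [0.8, 1.5, 2.0])
    def test_blurred_sphere_radius_recovered(self, blur):
        n, R = 40, 10.0
        Z, Y, X = np.mgrid[0:n, 0:n, 0:n]
        r = np.sqrt((Z - 20.0) ** 2 + (Y - 20.0) ** 2 + (X - 20.0) ** 2)
        img = ndimage.gaussian_filter((r <= R).astype(float) * 100, blur)
        v = VolumeImage(img, (1, 1, 1))
        thresh_mesh = mesh_from_mask(img > 15, (1, 1, 1))[0]
        r_thresh = np.linalg.norm(thresh_mesh.vertices - 20, axis=1).mean()
        tuned = tune_mesh_to_gradient(thresh_mesh, v, search=3.0)
        r_tuned = np.linalg.norm(tuned.vertices - 20, axis=1).mean()
        # the gradient maximum of a blurred step sits on the step
        assert abs(r_tuned - R) < 0.25
        assert abs(r_tuned - R) < abs(r_thresh - R)    # tuning improves

    def test_mesh_on_gradient_maxima_barely_moves(self):
        n, R = 40, 10.0
        Z, Y, X = np.mgrid[0:n, 0:n, 0:n]
        r = np.sqrt((Z - 20.0) ** 2 + (Y - 20.0) ** 2 + (X - 20.0) ** 2)
        img = ndimage.gaussian_filter((r <= R).astype(float) * 100, 1.2)
        v = VolumeImage(img, (1, 1, 1))
        m0 = mesh_from_mask(r <= R, (1, 1, 1))[0]
        tuned = tune_mesh_to_gradient(m0, v, search=2.0)
        disp = np.linalg.norm(tuned.vertices - m0.vertices, axis=1)
        assert disp.mean() < 0.5


class TestActiveMesh:
    def test_zero_pressure_is_identity(self, sphere_mask):
        seed = mesh_from_mask(sphere_mask, (1, 1, 1))[0]
        v = VolumeImage(np.zeros(sphere_mask.shape), (1, 1, 1))
        out = expand_active_mesh(seed, v, pressure=0)
        assert np.allclose(out.vertices, seed.vertices)

    def test_seed_converges_to_bright_wall(self):
        n = 40
        Z, Y, X = np.mgrid[0:n, 0:n, 0:n]
        r = np.sqrt((Z - 20.0) ** 2 + (Y - 20.0) ** 2 + (X - 20.0) ** 2)
        img = ndimage.gaussian_filter(
            np.where(np.abs(r - 12) < 1.2, 200.0, 10.0), 0.8)
        v = VolumeImage(img, (1, 1, 1))
        seed = mesh_from_mask(r <= 4, (1, 1, 1))[0]
        out = expand_active_mesh(seed, v, pressure=1.0, rigidity=0.4)
        rr = np.linalg.norm(out.vertices - 20, axis=1)
        assert rr.mean() == pytest.approx(12.0, abs=0.5)
        assert rr.std() < 0.5

    def test_two_chambers_meet_at_wall_without_overlap(self):
        img = np.full((40, 40, 72), 10.0)
        img[:, :, 34:38] = 200.0
        for sl in (np.s_[:2], np.s_[-2:]):
            img[sl] = 200.0
            img[:, sl] = 200.0
            img[:, :, sl] = 200.0
        img = ndimage.gaussian_filter(img, 0.8)
        v = VolumeImage(img, (1, 1, 1))
        Z, Y, X = np.mgrid[0:40, 0:40, 0:72]
        s1 = mesh_from_mask(((Z - 20) ** 2 + (Y - 20) ** 2 + (X - 16) ** 2) <= 16,
                            (1, 1, 1))[0]
        s2 = mesh_from_mask(((Z - 20) ** 2 + (Y - 20) ** 2 + (X - 54) ** 2) <= 16,
                            (1, 1, 1))[0]
        occ = np.zeros(img.shape, np.int32)
        m1 = expand_active_mesh(s1, v, 1.0, 0.4, occupancy=occ, label=1)
        m2 = expand_active_mesh(s2, v, 1.0, 0.4, occupancy=occ, label=2)
        k1 = mesh_to_mask(m1, img.shape, (1, 1, 1))
        k2 = mesh_to_mask(m2, img.shape, (1, 1, 1))
        assert (k1 & k2).sum() == 0
        assert k1.sum() > 15000 and k2.sum() > 15000   # both filled chambers


class TestSkeleton:
    def test_straight_cylinder(self):
        cyl = np.zeros((20, 20, 104), bool)
        Z, Y, X = np.mgrid[0:20, 0:20, 0:104]
        cyl[((Z - 10) ** 2 + (Y - 10) ** 2 <= 16) & (X >= 2) & (X < 102)] = True
        net = skeletonize_to_graph(cyl, (1, 1, 1))
        assert net.n_edges == 1
        (u, v, d), = net.graph.edges(data=True)
        assert d["length"] == pytest.approx(100, rel=0.05)
        assert d["mean_radius"] == pytest.approx(4.0, abs=0.5)
        assert net.graph.degree(u) == 1 and net.graph.degree(v) == 1

    def test_y_junction_angles(self):
        # symmetric Y in the y-x plane with 120 deg between arms
        mask = np.zeros((16, 96, 96), bool)
        c = np.array([48.0, 48.0])
        for theta in (90.0, 210.0, 330.0):
            d = np.array([np.sin(np.deg2rad(theta)), np.cos(np.deg2rad(theta))])
            for t in np.linspace(0, 40, 200):
                p = c + t * d
                yy, xx = int(round(p[0])), int(round(p[1]))
                if 0 <= yy < 96 and 0 <= xx < 96:
                    mask[6:10, max(yy - 2, 0):yy + 3, max(xx - 2, 0):xx + 3] = True
        net = skeletonize_to_graph(mask, (1, 1, 1))
        from tissuescope3d.morphometrics import branch_angles
        deg3 = [n for n in net.graph if net.graph.degree(n) >= 3]
        assert len(deg3) >= 1
        angles = branch_angles(net, window_um=20.0)
        assert len(angles) >= 3
        assert np.abs(np.sort(angles)[-3:] - 120).max() < 8

    def test_empty_mask_empty_graph(self):
        net = skeletonize_to_graph(np.zeros((8, 8, 8), bool))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_total_length_stable_under_dilation(self):
        cyl = np.zeros((24, 24, 160), bool)
        Z, Y, X = np.mgrid[0:24, 0:24, 0:160]
        cyl[((Z - 12) ** 2 + (Y - 12) ** 2 <= 16) & (X >= 2) & (X < 158)] = True
        net0 = skeletonize_to_graph(cyl, (1, 1, 1))
        net1 = skeletonize_to_graph(ndimage.binary_dilation(cyl), (1, 1, 1))
        assert net1.total_length() == pytest.approx(net0.total_length(),
                                                    rel=0.02)


class TestSegmentCells:
    def _shell_image(self):
        n = 48
        Z, Y, X = np.mgrid[0:n, 0:n, 0:n]
        r = np.sqrt((Z - 24.0) ** 2 + (Y - 24.0) ** 2 + (X - 24.0) ** 2)
        img = np.where(np.abs(r - 16) < 1.5, 200.0, 10.0)
        return ndimage.gaussian_filter(img, 0.8), r

    def test_single_nucleus_fills_cortex_shell(self):
        img, r = self._shell_image()
        v = VolumeImage(img, (1, 1, 1))
        nuc = mesh_from_mask(r <= 5, (1, 1, 1))[0]
        cells = segment_cells(v, [nuc])
        assert len(cells) == 1
        vol = cells[0].flags["voxel_volume_um3"]
        # expansion stops at the cortex ridge (r = 16), plus the thin
        # partition-completion band
        assert vol == pytest.approx(4 / 3 * np.pi * 16 ** 3, rel=0.2)
        assert not cells[0].flags["boundary"]

    def test_binucleate_merging_depends_on_wall(self):
        # two nuclei 8 µm apart: merged without a wall, separate with one
        n = 48
        Z, Y, X = np.mgrid[0:n, 0:n, 0:n]
        r = np.sqrt((Z - 24.0) ** 2 + (Y - 24.0) ** 2 + (X - 24.0) ** 2)
        base = np.where(np.abs(r - 18) < 1.5, 200.0, 10.0)
        nuc1 = mesh_from_mask(((Z - 24) ** 2 + (Y - 24) ** 2 + (X - 20) ** 2) <= 9,
                              (1, 1, 1))[0]
        nuc2 = mesh_from_mask(((Z - 24) ** 2 + (Y - 24) ** 2 + (X - 28) ** 2) <= 9,
                              (1, 1, 1))[0]
        v_open = VolumeImage(ndimage.gaussian_filter(base, 0.8), (1, 1, 1))
        cells_open = segment_cells(v_open, [nuc1, nuc2])
        assert len(cells_open) == 1
        assert cells_open[0].flags["multiplicity"] == 2
        walled = base.copy()
        walled[:, :, 23:25] = 200.0
        v_wall = VolumeImage(ndimage.gaussian_filter(walled, 0.8), (1, 1, 1))
        cells_wall = segment_cells(v_wall, [nuc1, nuc2])
        assert len(cells_wall) == 2

    def test_cells_never_overlap(self):
        img, r = self._shell_image()
        v = VolumeImage(img, (1, 1, 1))
        Z, Y, X = np.mgrid[0:48, 0:48, 0:48]
        n1 = mesh_from_mask(((Z - 24) ** 2 + (Y - 18) ** 2 + (X - 24) ** 2) <= 9,
                            (1, 1, 1))[0]
        n2 = mesh_from_mask(((Z - 24) ** 2 + (Y - 30) ** 2 + (X - 24) ** 2) <= 9,
                            (1, 1, 1))[0]
        cells = segment_cells(v, [n1, n2], merge_distance_um=1.0)
        masks = [mesh_to_mask(c, img.shape, (1, 1, 1)) for c in cells]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert (masks[i] & masks[j]).sum() == 0
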