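"""Grid reconstruction: shrinkwrap, patch, embedding, lattice, seal."""

import numpy as np
import pytest
import trimesh

from chewfield.gridfit import (
    GridLayout,
    TriSurface,
    embed_2d,
    extract_patch,
    place_and_triangulate,
    seal_check,
    shrinkwrap,
)


def _icosphere(radius=40.0, subdivisions=3):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface(np.asarray(m.vertices), np.asarray(m.faces))


def _gyri_sphere(radius=40.0, amplitude=4.0, subdivisions=4):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(m.vertices)
    ripple = amplitude * np.sin(6.0 * np.arctan2(v[:, 1], v[:, 0])) * \
        np.sin(6.0 * np.arccos(np.clip(v[:, 2], -1, 1)))
    r = radius + ripple
    return TriSurface(v * r[:, None], np.asarray(m.faces)), ripple


def _flat_patch(nx=21, ny=21, pitch=2.5):
    xs = np.arange(nx) * pitch
    ys = np.arange(ny) * pitch
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)], axis=1)
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            tris.append([a, a + ny, a + 1])
            tris.append([a + 1, a + ny, a + ny + 1])
    return TriSurface(verts, np.array(tris))


def _quarter_cylinder(radius=40.0, height=60.0, n=25):
    thetas = np.linspace(0.0, np.pi / 2, n)
    zs = np.linspace(0.0, height, n)
    verts, tris = [], []
    for i, th in enumerate(thetas):
        for j, z in enumerate(zs):
            verts.append([radius * np.cos(th), radius * np.sin(th), z])
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris.append([a, a + n, a + 1])
            tris.append([a + 1, a + n, a + n + 1])
    # unrolled (developable) coordinates: (r*theta, z)
    TH, Z = np.meshgrid(thetas, zs, indexing="ij")
    flat = np.stack([radius * TH.ravel(), Z.ravel()], axis=1)
    return TriSurface(np.array(verts), np.array(tris)), flat


class TestShrinkwrap:
    def test_sphere_radius_recovered(self):
        hull = shrinkwrap(_icosphere(40.0))
        r = np.linalg.norm(hull.vertices - hull.vertices.mean(axis=0), axis=1)
        assert abs(r.mean() - 40.0) <= 0.02 * 40.0

    def test_gyri_smoothed_but_enclosed(self):
        surf, _ = _gyri_sphere(40.0, amplitude=4.0)
        hull = shrinkwrap(surf)
        center = surf.vertices.mean(axis=0)
        hr = np.linalg.norm(hull.vertices - center, axis=1)
        ripple = hr - hr.mean()
        assert np.max(np.abs(ripple)) < 4.0 / 3.0
        # enclosure: along each input direction the hull lies outside
        from scipy.spatial import cKDTree
        hd = (hull.vertices - center)
        hdir = hd / np.linalg.norm(hd, axis=1)[:, None]
        sd = surf.vertices - center
        sr = np.linalg.norm(sd, axis=1)
        sdir = sd / sr[:, None]
        tree = cKDTree(hdir)
        _, idx = tree.query(sdir)
        assert np.all(np.linalg.norm(hd, axis=1)[idx] >= sr - 1.0)

    def test_open_surface_rejected(self):
        s = _icosphere(30.0, subdivisions=2)
        open_surf = TriSurface(s.vertices, s.triangles[:-4])
        with pytest.raises(ValueError, match="closed"):
            shrinkwrap(open_surf)


class TestExtractPatch:
    def test_patch_subset_and_corner_coverage(self):
        hull = _icosphere(40.0)
        corners = np.array([
            [40.0, 8.0, 8.0], [40.0, -8.0, 8.0],
            [40.0, -8.0, -8.0], [40.0, 8.0, -8.0]])
        patch = extract_patch(hull, corners)
        assert 0 < len(patch.vertices) < len(hull.vertices)
        # every patch vertex exists in the hull
        hv = {tuple(np.round(v, 9)) for v in hull.vertices}
        assert all(tuple(np.round(v, 9)) in hv for v in patch.vertices)
        # boundary passes close to every corner
        edge = hull.mean_edge_length()
        for c in corners:
            d = np.linalg.norm(patch.vertices - c, axis=1)
            assert d.min() <= 1.5 * edge

    def test_bad_corner_count_rejected(self):
        with pytest.raises(ValueError):
            extract_patch(_icosphere(), np.zeros((3, 3)))


class TestEmbed2D:
    def test_flat_patch_distances_preserved(self):
        patch = _flat_patch()
        emb = embed_2d(patch)
        rng = np.random.default_rng(0)
        idx = rng.choice(len(patch.vertices), size=(200, 2))
        idx = idx[idx[:, 0] != idx[:, 1]]
        true = np.linalg.norm(
            patch.vertices[idx[:, 0], :2] - patch.vertices[idx[:, 1], :2], axis=1)
        got = np.linalg.norm(emb[idx[:, 0]] - emb[idx[:, 1]], axis=1)
        assert np.max(np.abs(got - true) / true) < 0.02

    def test_quarter_cylinder_unrolls(self):
        patch, flat = _quarter_cylinder()
        emb = embed_2d(patch)
        rng = np.random.default_rng(1)
        idx = rng.choice(len(patch.vertices), size=(300, 2))
        idx = idx[idx[:, 0] != idx[:, 1]]
        true = np.linalg.norm(flat[idx[:, 0]] - flat[idx[:, 1]], axis=1)
        got = np.linalg.norm(emb[idx[:, 0]] - emb[idx[:, 1]], axis=1)
        assert np.max(np.abs(got - true) / true) < 0.02

    def test_output_is_two_dimensional(self):
        patch = _flat_patch(11, 11)
        emb = embed_2d(patch)
        assert emb.shape == (121, 2)
        centered = emb - emb.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        assert s[1] / s[0] > 0.1     # genuinely planar spread, not a line

    def test_disconnected_patch_rejected(self):
        a = _flat_patch(5, 5)
        b = _flat_patch(5, 5)
        verts = np.vstack([a.vertices, b.vertices + [1e4, 1e4, 0.0]])
        tris = np.vstack([a.triangles, b.triangles + len(a.vertices)])
        with pytest.raises(ValueError):
            embed_2d(TriSurface(verts, tris))


class TestPlaceAndTriangulate:
    def test_flat_2x2_square(self):
        patch = _flat_patch()
        emb = embed_2d(patch)
        fit = place_and_triangulate(emb, patch, GridLayout(rows=2, cols=2))
        d = np.linalg.norm(fit.centers_2d[0] - fit.centers_2d[1])
        assert np.isclose(d, 10.0, atol=1e-9)
        # back-projected centers stay on the flat patch plane
        assert np.max(np.abs(fit.centers_3d[:, 2])) < 1e-6
        # and form a 10 mm square in 3-D as well
        d3 = np.linalg.norm(fit.centers_3d[0] - fit.centers_3d[1])
        assert abs(d3 - 10.0) < 0.5

    def test_cylinder_geodesic_spacing(self):
        patch, _ = _quarter_cylinder()
        emb = embed_2d(patch)
        fit = place_and_triangulate(emb, patch, GridLayout(rows=4, cols=4))
        r = 40.0
        c = fit.centers_3d
        # geodesic distance on the cylinder between adjacent contacts
        def geo(a, b):
            dth = abs(np.arctan2(a[1], a[0]) - np.arctan2(b[1], b[0]))
            return np.hypot(r * dth, a[2] - b[2])
        for i in range(4):
            for j in range(3):
                assert abs(geo(c[i * 4 + j], c[i * 4 + j + 1]) - 10.0) <= 0.5
                assert abs(geo(c[j * 4 + i], c[(j + 1) * 4 + i]) - 10.0) <= 0.5

    def test_back_projection_near_surface(self):
        patch, _ = _quarter_cylinder()
        emb = embed_2d(patch)
        fit = place_and_triangulate(emb, patch, GridLayout(rows=3, cols=3))
        r = np.linalg.norm(fit.centers_3d[:, :2], axis=1)
        edge = patch.mean_edge_length()
        assert np.all(np.abs(r - 40.0) <= edge)

    def test_oversized_layout_rejected(self):
        patch = _flat_patch(9, 9, pitch=1.0)   # 8 mm extent
        emb = embed_2d(patch)
        with pytest.raises(ValueError, match="extent"):
            place_and_triangulate(emb, patch, GridLayout(rows=4, cols=4))

    def test_triangulation_non_overlapping(self):
        patch = _flat_patch()
        emb = embed_2d(patch)
        fit = place_and_triangulate(emb, patch, GridLayout(rows=3, cols=3))
        # lattice split: 2 triangles per cell, consistent orientation
        def signed_area(tri):
            a, b, c = fit.centers_2d[tri]
            u, v = b - a, c - a
            return 0.5 * (u[0] * v[1] - u[1] * v[0])
        areas = np.array([signed_area(t) for t in fit.triangulation_2d])
        assert np.all(areas != 0)
        assert np.all(np.sign(areas) == np.sign(areas[0]))


class TestEndToEndShield:
    def test_reconstructed_grid_shields_the_phantom(self, spec, suite_sm1,
                                                    hm_volumes):
        """Reconstruct a grid on a spherical cortical hull, rasterize it as
        a sealed insulator into the healthy phantom, and verify the forward
        solution shows the shielding direction (sub-grid power drops)."""
        from chewfield.fem import (assemble_system, combined_load,
                                   make_source_model, mesh_from_volume,
                                   solve_forward)
        from chewfield.gridfit import rasterize_patch
        from chewfield.labels import Tissue
        from chewfield.phantom import LabeledVolume, place_electrodes

        r_cortex = spec.r_gray
        brain = _icosphere(r_cortex, subdivisions=4)
        hull = shrinkwrap(brain, iterations=40)

        d = np.asarray(spec.grid_direction, float)
        d /= np.linalg.norm(d)
        helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(helper, d)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        corners = []
        for su, sv in ((1, 1), (1, -1), (-1, -1), (-1, 1)):
            c = d * r_cortex + 24.0 * (su * u + sv * v)
            corners.append(c / np.linalg.norm(c) * r_cortex)
        patch = extract_patch(hull, np.array(corners))
        emb = embed_2d(patch)
        place_and_triangulate(emb, patch, GridLayout(rows=4, cols=4))

        vol3 = hm_volumes["HM3"]
        # the sheet occupies the CSF-side voxel layer of the interface
        # (same rasterization convention as the phantom builder)
        r_sheet = r_cortex + 0.5 * vol3.spacing_mm
        verts = patch.vertices
        sheet = TriSurface(
            verts / np.linalg.norm(verts, axis=1)[:, None] * r_sheet,
            patch.triangles)
        mask = rasterize_patch(sheet, vol3.shape, vol3.spacing_mm,
                               vol3.origin_mm)
        assert seal_check(mask).sealed
        labels = vol3.labels.copy()
        labels[mask] = int(Tissue.GRID_INSULATOR)
        shielded = LabeledVolume(labels, vol3.spacing_mm, vol3.origin_mm)

        contacts = place_electrodes(spec, vol3, n_scalp=0)
        mesh = mesh_from_volume(shielded)
        sol = solve_forward(assemble_system(mesh),
                            combined_load(make_source_model(spec, "SM1"), mesh),
                            mesh, electrodes=contacts, reference="none")
        p_shielded = float(np.max(sol.electrode_potentials_v**2))
        p_open = suite_sm1["variants"]["HM3"]["peak_subgrid_power_v2"]
        assert p_shielded < p_open


class TestSealCheck:
    def test_solid_slab_passes(self):
        mask = np.zeros((6, 6, 3), dtype=bool)
        mask[1:5, 1:5, 1] = True
        assert seal_check(mask).sealed

    def test_edge_contact_fails_and_reports(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0:2, 0:2, 1] = True
        mask[2:4, 2:4, 2] = True      # touch along one edge only
        report = seal_check(mask)
        assert not report.sealed
        assert len(report.leaks) >= 1

    def test_checkerboard_fails(self):
        mask = np.indices((4, 4, 1)).sum(axis=0) % 2 == 0
        report = seal_check(mask)
        assert not report.sealed
        assert len(report.leaks) > 4
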