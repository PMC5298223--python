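"""FEM forward solver: mesh, assembly, sources, solves, and the oracle."""

import numpy as np
import pytest

from chewfield.fem import (
    ConductivityTable,
    DipoleSource,
    _K_UNIT,
    _interpolate_nodes,
    analytic_sphere,
    assemble_system,
    error_metrics,
    make_source_model,
    mesh_from_volume,
    solve_forward,
    st_venant_load,
)
from chewfield.labels import Tissue
from chewfield.phantom import LabeledVolume, layered_sphere_volume


def _uniform_volume(n=4, tissue=Tissue.GRAY, spacing=2.0):
    labels = np.full((n, n, n), int(tissue), dtype=np.int16)
    return LabeledVolume(labels, spacing, -0.5 * n * spacing * np.ones(3))


class TestMesh:
    def test_counts_on_uniform_cube(self):
        mesh = mesh_from_volume(_uniform_volume(4))
        assert mesh.n_elems == 64
        assert mesh.n_nodes == 125          # (4+1)^3 lattice

    def test_element_labels_match_voxels(self):
        vol = _uniform_volume(3)
        vol.labels[1, 1, 1] = int(Tissue.CSF)
        mesh = mesh_from_volume(vol)
        e = mesh.elem_at(vol.origin_mm + np.array([3.0, 3.0, 3.0]))
        assert mesh.elem_labels[e] == int(Tissue.CSF)

    def test_adjacent_elements_share_four_nodes(self):
        mesh = mesh_from_volume(_uniform_volume(2))
        e0 = mesh.elem_index_grid[0, 0, 0]
        e1 = mesh.elem_index_grid[1, 0, 0]
        shared = set(mesh.elems[e0]) & set(mesh.elems[e1])
        assert len(shared) == 4

    def test_empty_volume_rejected(self):
        vol = LabeledVolume(np.zeros((3, 3, 3), dtype=np.int16), 2.0,
                            np.zeros(3))
        with pytest.raises(ValueError):
            mesh_from_volume(vol)


class TestAssembly:
    def test_local_stiffness_matches_symbolic_integration(self):
        # independent oracle: symbolic integration of the trilinear
        # gradients over the unit cube
        import sympy as sy
        x, y, z = sy.symbols("x y z")
        corners = [(i, j, k) for k in (0, 1) for j in (0, 1) for i in (0, 1)]
        # order must match the element node convention
        order = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                 (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
        shapes = []
        for (i, j, k) in order:
            n = ((x if i else 1 - x) * (y if j else 1 - y) * (z if k else 1 - z))
            shapes.append(n)
        K = np.zeros((8, 8))
        for a in range(8):
            for b in range(a, 8):
                ga = [sy.diff(shapes[a], v) for v in (x, y, z)]
                gb = [sy.diff(shapes[b], v) for v in (x, y, z)]
                val = sy.integrate(
                    sum(p * q for p, q in zip(ga, gb)),
                    (x, 0, 1), (y, 0, 1), (z, 0, 1))
                K[a, b] = K[b, a] = float(val)
        assert np.allclose(K, _K_UNIT, atol=1e-12)

    def test_linearity_in_sigma(self):
        mesh = mesh_from_volume(_uniform_volume(3))
        t1 = ConductivityTable({Tissue.GRAY: 0.33})
        t2 = ConductivityTable({Tissue.GRAY: 0.66})
        A1 = assemble_system(mesh, t1)
        A2 = assemble_system(mesh, t2)
        assert np.allclose((A2 - 2.0 * A1).data, 0.0, atol=1e-15)

    def test_constant_vector_in_null_space(self):
        mesh = mesh_from_volume(_uniform_volume(3))
        A = assemble_system(mesh)
        ones = np.ones(mesh.n_nodes)
        assert np.max(np.abs(A @ ones)) < 1e-12 * np.abs(A.data).max()

    def test_symmetry(self):
        mesh = mesh_from_volume(_uniform_volume(3))
        A = assemble_system(mesh)
        assert abs(A - A.T).max() < 1e-15

    def test_missing_conductivity_rejected(self):
        mesh = mesh_from_volume(_uniform_volume(3, Tissue.BLOOD))
        with pytest.raises(ValueError, match="label"):
            assemble_system(mesh, ConductivityTable({Tissue.GRAY: 0.33}))


@pytest.fixture(scope="module")
def venant_mesh():
    return mesh_from_volume(_uniform_volume(6))


class TestStVenant:

    def test_charge_conservation_and_moment(self, venant_mesh):
        mesh = venant_mesh
        dip = DipoleSource((0.3, -0.2, 0.4), (0.0, 0.0, 1.0), 2.5e-8)
        load = st_venant_load(dip, mesh)
        assert abs(load.sum()) < 1e-12 * np.abs(load).max()
        nd = np.flatnonzero(load)
        r = (mesh.node_coords_mm[nd] - np.array(dip.position_mm)) * 1e-3
        moment = load[nd] @ r
        assert np.linalg.norm(moment - dip.moment_vector) <= 1e-8 * dip.moment_am

    def test_loads_linear_in_moment(self, venant_mesh):
        mesh = venant_mesh
        d1 = DipoleSource((0.0, 0.0, 0.5), (1.0, 0.0, 0.0), 1e-8)
        d2 = DipoleSource((0.0, 0.0, 0.5), (1.0, 0.0, 0.0), 2e-8)
        assert np.allclose(2.0 * st_venant_load(d1, mesh),
                           st_venant_load(d2, mesh), rtol=1e-12)

    def test_dipole_outside_mesh_rejected(self, venant_mesh):
        mesh = venant_mesh
        dip = DipoleSource((100.0, 0.0, 0.0), (0.0, 0.0, 1.0), 1e-8)
        with pytest.raises(ValueError, match="outside"):
            st_venant_load(dip, mesh)


@pytest.fixture(scope="module")
def small_case():
    vol = layered_sphere_volume([30.0], [Tissue.GRAY], 3.0)
    mesh = mesh_from_volume(vol)
    A = assemble_system(mesh)
    return mesh, A


class TestSolve:

    def test_superposition_and_scaling(self, small_case):
        mesh, A = small_case
        d1 = DipoleSource((0.0, 0.0, 6.0), (0.0, 0.0, 1.0), 1e-8)
        d2 = DipoleSource((6.0, 0.0, 0.0), (1.0, 0.0, 0.0), 1e-8)
        b1 = st_venant_load(d1, mesh)
        b2 = st_venant_load(d2, mesh)
        s1 = solve_forward(A, b1, mesh, rtol=1e-11)
        s2 = solve_forward(A, b2, mesh, rtol=1e-11)
        s12 = solve_forward(A, b1 + b2, mesh, rtol=1e-11)
        ref = np.abs(s12.node_potentials_v).max()
        assert np.allclose(
            s12.node_potentials_v,
            s1.node_potentials_v + s2.node_potentials_v, atol=1e-6 * ref)
        s10 = solve_forward(A, 10.0 * b1, mesh, rtol=1e-11)
        assert np.allclose(s10.node_potentials_v, 10.0 * s1.node_potentials_v,
                           atol=1e-6 * ref)
        assert np.allclose(s10.ef_magnitude_v_per_m,
                           10.0 * s1.ef_magnitude_v_per_m,
                           rtol=1e-5, atol=1e-8)

    def test_zero_mean_reference_and_residual(self, small_case):
        mesh, A = small_case
        b = st_venant_load(
            DipoleSource((0.0, 0.0, 6.0), (0.0, 0.0, 1.0), 1e-8), mesh)
        sol = solve_forward(A, b, mesh)
        assert abs(sol.node_potentials_v.mean()) < 1e-15
        assert sol.residual <= 1e-9

    def test_car_invariant_to_constant_shift(self, small_case):
        mesh, A = small_case
        b = st_venant_load(
            DipoleSource((0.0, 0.0, 6.0), (0.0, 0.0, 1.0), 1e-8), mesh)
        sol = solve_forward(A, b, mesh)
        pts = np.array([[0.0, 0.0, 20.0], [20.0, 0.0, 0.0], [0.0, 20.0, 0.0]])
        v0 = _interpolate_nodes(mesh, sol.node_potentials_v, pts)
        v1 = _interpolate_nodes(mesh, sol.node_potentials_v + 3.14, pts)
        assert np.allclose(v0 - v0.mean(), v1 - v1.mean(), atol=1e-12)

    def test_unbalanced_load_rejected(self, small_case):
        mesh, A = small_case
        b = np.zeros(mesh.n_nodes)
        b[0] = 1.0
        with pytest.raises(ValueError, match="sum"):
            solve_forward(A, b, mesh)

    def test_central_dipole_matches_closed_form(self):
        # homogeneous sphere R = 100 mm, sigma = 0.33, p = 10 nA m:
        # pole surface potential 3 p / (4 pi sigma R^2) = 0.723 uV
        R, sigma, p = 100.0, 0.33, 1e-8
        pole = 3 * p / (4 * np.pi * sigma * (R * 1e-3) ** 2)
        assert abs(pole * 1e6 - 0.723) < 0.001
        dip = DipoleSource((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), p)
        series_pole = analytic_sphere([R], [sigma], dip,
                                      np.array([[0.0, 0.0, R]]))[0]
        assert abs(series_pole - pole) <= 1e-6 * abs(pole)
        vol = layered_sphere_volume([R], [Tissue.GRAY], 2.0)
        mesh = mesh_from_volume(vol)
        A = assemble_system(mesh, ConductivityTable({Tissue.GRAY: sigma}))
        sol = solve_forward(A, st_venant_load(dip, mesh), mesh)
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(100, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= 96.0
        v_fem = _interpolate_nodes(mesh, sol.node_potentials_v, pts)
        v_ana = analytic_sphere([R], [sigma], dip, pts)
        rdm, _ = error_metrics(v_fem - v_fem.mean(), v_ana - v_ana.mean())
        assert rdm <= 0.05

    def test_rdm_decreases_with_mesh_refinement(self):
        R, sigma = 50.0, 0.33
        dip = DipoleSource((0.0, 0.0, 25.0), (0.0, 0.0, 1.0), 1e-8)
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(80, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= 46.0
        v_ana = analytic_sphere([R], [sigma], dip, pts)
        rdms = []
        for h in (4.0, 2.0):
            vol = layered_sphere_volume([R], [Tissue.GRAY], h)
            mesh = mesh_from_volume(vol)
            A = assemble_system(mesh, ConductivityTable({Tissue.GRAY: sigma}))
            sol = solve_forward(A, st_venant_load(dip, mesh), mesh)
            v = _interpolate_nodes(mesh, sol.node_potentials_v, pts)
            rdm, _ = error_metrics(v - v.mean(), v_ana - v_ana.mean())
            rdms.append(rdm)
        assert rdms[1] < rdms[0]


class TestAnalyticSphere:
    def test_matches_infinite_medium_near_source(self):
        # independent oracle: a very large single sphere approximates an
        # infinite medium; compare against the direct dipole formula
        sigma, p = 0.33, 1e-8
        r0 = np.array([0.0, 0.0, 50.0])
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(8, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= 90.0
        for ori in ((0.0, 0.0, 1.0), (1.0, 0.0, 0.0)):
            dip = DipoleSource(tuple(r0), ori, p)
            v = analytic_sphere([10000.0], [sigma], dip, pts, n_max=2000)
            d = (pts - r0) * 1e-3
            pvec = dip.moment_vector
            v_inf = (d @ pvec) / (4 * np.pi * sigma *
                                  np.linalg.norm(d, axis=1) ** 3)
            assert np.max(np.abs(v - v_inf)) <= 1e-4 * np.max(np.abs(v_inf))

    def test_conductivity_scaling(self):
        dip = DipoleSource((0.0, 0.0, 20.0), (1.0, 0.0, 0.0), 1e-8)
        pts = np.array([[0.0, 30.0, 60.0], [50.0, 0.0, 40.0]])
        v1 = analytic_sphere([70.0, 80.0], [0.3, 0.01], dip, pts)
        v2 = analytic_sphere([70.0, 80.0], [0.9, 0.03], dip, pts)
        assert np.allclose(v2, v1 / 3.0, rtol=1e-10)

    def test_surface_zero_mean_and_distinct_topographies(self):
        from chewfield.phantom import _fibonacci_sphere
        pts = 80.0 * _fibonacci_sphere(4000)
        rad = analytic_sphere([80.0], [0.33],
                              DipoleSource((0, 0, 40.0), (0, 0, 1.0), 1e-8), pts)
        tan = analytic_sphere([80.0], [0.33],
                              DipoleSource((0, 0, 40.0), (1.0, 0, 0), 1e-8), pts)
        assert abs(rad.mean()) < 1e-3 * np.abs(rad).max()
        assert abs(tan.mean()) < 1e-3 * np.abs(tan).max()
        rdm, _ = error_metrics(rad, tan)
        assert rdm > 0.5

    def test_dipole_placement_validation(self):
        dip = DipoleSource((0.0, 0.0, 75.0), (0.0, 0.0, 1.0), 1e-8)
        with pytest.raises(ValueError):
            analytic_sphere([70.0, 80.0], [0.3, 0.3], dip,
                            np.array([[0.0, 0.0, 79.0]]))
        with pytest.raises(ValueError):
            analytic_sphere([70.0, 80.0], [0.3, 0.3],
                            DipoleSource((0, 0, 30.0), (0, 0, 1.0), 1e-8),
                            np.array([[0.0, 0.0, 95.0]]))


class TestErrorMetrics:
    def test_identity_scaling_and_sign(self):
        a = np.array([1.0, -2.0, 3.0])
        assert error_metrics(a, a) == (0.0, 0.0)
        rdm, lnmag = error_metrics(2.0 * a, a)
        assert rdm < 1e-15 and np.isclose(lnmag, np.log(2.0))
        rdm, lnmag = error_metrics(-a, a)
        assert np.isclose(rdm, 2.0) and abs(lnmag) < 1e-15

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            error_metrics(np.zeros(3), np.ones(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_metrics(np.ones(3), np.ones(4))


class TestShieldBoundaryCondition:
    def test_field_runs_parallel_in_film_under_shield(self):
        """In the CSF film bounded above by the insulating sheet, the
        field runs parallel to the shield (radial fraction <= 10%).

        Uses the configuration where strong muscle EMG flux impinges on
        the shield: grid centered over the muscle, skull defects near the
        patch rim, and a resolved CSF film on both sides of the sheet.
        """
        from chewfield.fem import (_shield_radial_fraction, combined_load,
                                   run_head_model_suite)
        from chewfield.phantom import (CylinderDefect, PhantomSpec, SawLine,
                                       build_phantom)

        spec = PhantomSpec(
            radii_mm=(66.0, 78.0, 84.0, 90.0, 96.0),
            grid_direction=(1.0, 0.0, 0.0),
            grid_gap_voxels=1,
            burr_holes=(CylinderDefect((0.88, 0.33, 0.34), 12.0),
                        CylinderDefect((0.88, -0.33, 0.34), 16.0)),
            saw_lines=(SawLine((0.88, 0.33, 0.34), (0.88, -0.33, 0.34), 3.0),),
        )
        vol = build_phantom(spec, "HM1")
        mesh = mesh_from_volume(vol)
        sol = solve_forward(
            assemble_system(mesh),
            combined_load(make_source_model(spec, "SM1"), mesh),
            mesh, reference="none")
        frac = _shield_radial_fraction(spec, vol, mesh, sol)
        assert frac <= 0.10


class TestSourceModels:
    def test_dipole_counts(self, spec):
        assert len(make_source_model(spec, "SM1").dipoles) == 1
        assert len(make_source_model(spec, "SM2").dipoles) == 8
        assert len(make_source_model(spec, "SM3").dipoles) == 1

    def test_dipoles_inside_muscle(self, spec, hm_volumes):
        vol = hm_volumes["HM1"]
        for name in ("SM1", "SM2", "SM3"):
            for dip in make_source_model(spec, name).dipoles:
                assert vol.label_at(dip.position_mm) is Tissue.MUSCLE

    def test_unknown_model_rejected(self, spec):
        with pytest.raises(ValueError):
            make_source_model(spec, "SM4")

    def test_orientations_are_unit(self, spec):
        for name in ("SM1", "SM2", "SM3"):
            for dip in make_source_model(spec, name).dipoles:
                assert np.isclose(np.linalg.norm(dip.orientation), 1.0)
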