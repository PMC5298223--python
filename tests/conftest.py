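"""Shared fixtures.

The expensive forward solves (head-model suite, 4-layer oracle sphere) are
session-scoped and reused across tests; everything downstream of them is
pure arithmetic.
"""

from __future__ import annotations

import numpy as np
import pytest

from chewfield.calibrate import UnitForward
from chewfield.fem import (
    ConductivityTable,
    DipoleSource,
    analytic_sphere,
    assemble_system,
    make_source_model,
    mesh_from_volume,
    run_head_model_suite,
    solve_forward,
    st_venant_load,
    _interpolate_nodes,
)
from chewfield.labels import Tissue
from chewfield.phantom import PhantomSpec, build_phantom, layered_sphere_volume

ORACLE_RADII_MM = (78.0, 80.0, 86.0, 92.0)
ORACLE_TISSUES = (Tissue.GRAY, Tissue.CSF, Tissue.SKULL, Tissue.SOFT_TISSUE)
ORACLE_SIGMAS = (0.33, 1.54, 0.0063, 0.17)


@pytest.fixture(scope="session")
def spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def hm_volumes(spec):
    return {v: build_phantom(spec, v) for v in ("HM1", "HM2", "HM3")}


@pytest.fixture(scope="session")
def suite_sm1(spec):
    """Forward solutions of all three head models for the belly dipole."""
    return run_head_model_suite(spec, make_source_model(spec, "SM1"))


@pytest.fixture(scope="session")
def unit_sm1(suite_sm1) -> UnitForward:
    """Unit-moment forward constants derived from the suite solutions."""
    sol1 = suite_sm1["variants"]["HM1"]["solution"]
    sol3 = suite_sm1["variants"]["HM3"]["solution"]
    car_uv = (sol1.electrode_potentials_v - sol1.electrode_potentials_v.mean()) * 1e6
    return UnitForward(
        source_model="SM1",
        grid_amplitude_uv=float(np.median(np.abs(car_uv))),
        peak_ef_v_per_m=sol3.peak_ef_v_per_m,
        contact_potentials_uv=car_uv,
        peak_ef_position_mm=sol3.peak_ef_position_mm,
    )


@pytest.fixture(scope="session")
def sphere_oracle():
    """FEM vs analytic-series comparison on the 4-layer sphere at 2 mm.

    Eccentric dipole at 60% of the innermost radius, radial and tangential
    orientations, potentials compared at 200 points in the scalp shell.
    """
    vol = layered_sphere_volume(ORACLE_RADII_MM, ORACLE_TISSUES, 2.0)
    mesh = mesh_from_volume(vol)
    A = assemble_system(mesh, ConductivityTable())
    pos = (0.0, 0.0, 0.6 * ORACLE_RADII_MM[0])
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(200, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= 89.0
    out = {}
    for name, ori in (("radial", (0.0, 0.0, 1.0)), ("tangential", (1.0, 0.0, 0.0))):
        dip = DipoleSource(pos, ori, 1e-8)
        sol = solve_forward(A, st_venant_load(dip, mesh), mesh)
        v_fem = _interpolate_nodes(mesh, sol.node_potentials_v, pts)
        v_ana = analytic_sphere(ORACLE_RADII_MM, ORACLE_SIGMAS, dip, pts)
        out[name] = (v_fem - v_fem.mean(), v_ana - v_ana.mean(), sol)
    return out
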