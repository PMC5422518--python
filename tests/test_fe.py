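import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_box_mesh
from mandifem import fe, model
from mandifem.model import ConstraintSet, Material


def oracle_stiffness(coords, material):
    """Independent CST stiffness: shape-function coefficients from the
    4x4 Vandermonde system, strain-displacement matrix assembled from
    them, integrated by midpoint quadrature over the tetrahedron."""
    coords = np.asarray(coords, float)
    V = np.abs(np.linalg.det(np.column_stack([np.ones(4), coords]))) / 6.0
    M = np.column_stack([np.ones(4), coords])
    grads = np.linalg.solve(M, np.eye(4))[1:, :].T  # dN_a/dx_j
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c], B[1, c + 1], B[2, c + 2] = gx, gy, gz
        B[3, c], B[3, c + 1] = gy, gx
        B[4, c + 1], B[4, c + 2] = gz, gy
        B[5, c], B[5, c + 2] = gz, gx
    E, nu = material.E, material.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.diag([2 * mu, 2 * mu, 2 * mu, mu, mu, mu]).astype(float)
    D[:3, :3] += lam
    return V * B.T @ D @ B


REF_TET = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])


def test_element_stiffness_matches_independent_oracle():
    mat = Material(E=1.0, nu=0.0)
    K = fe.element_stiffness_tet4(REF_TET, mat)
    assert np.allclose(K, oracle_stiffness(REF_TET, mat), atol=1e-14)
    # and for a skewed element with realistic constants
    coords = REF_TET + 0.2 * np.array([[0.1, -0.2, 0.05]] * 4) + np.array(
        [[0, 0, 0], [0.03, 0.01, 0], [0, 0.02, -0.01], [0.01, 0, 0.04]]
    )
    mat2 = Material(E=19920.0, nu=0.3)
    assert np.allclose(
        fe.element_stiffness_tet4(coords, mat2), oracle_stiffness(coords, mat2)
    )


def test_element_stiffness_has_six_rigid_modes():
    K = fe.element_stiffness_tet4(REF_TET, Material(E=1000.0, nu=0.3))
    assert np.allclose(K, K.T)
    w = np.linalg.eigvalsh(K)
    assert (np.abs(w[:6]) < 1e-9 * w[-1]).all()
    assert (w[6:] > 1e-9 * w[-1]).all()


def test_rigid_translation_produces_zero_forces():
    K = fe.element_stiffness_tet4(REF_TET, Material(E=1000.0, nu=0.3))
    u = np.tile([1.0, -2.0, 0.5], 4)
    assert np.allclose(K @ u, 0.0, atol=1e-12 * 1000)


def test_degenerate_element_rejected():
    flat = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [1.0, 1.0, 0]])
    with pytest.raises(ValueError, match="degenerate"):
        fe.element_stiffness_tet4(flat, Material(E=1.0, nu=0.3))


def test_von_mises_closed_forms():
    assert fe.von_mises(np.zeros((3, 3))) == 0.0
    assert fe.von_mises(np.diag([5.0, 5.0, 5.0])) == pytest.approx(0.0)
    assert fe.von_mises(np.diag([7.0, 0, 0])) == pytest.approx(7.0)
    tau = 3.0
    s = np.zeros((3, 3))
    s[0, 1] = s[1, 0] = tau
    assert fe.von_mises(s) == pytest.approx(np.sqrt(3) * tau)


@given(
    st.lists(st.floats(-50, 50), min_size=6, max_size=6),
    st.floats(-20, 20),
)
def test_von_mises_invariant_under_hydrostatic_shift(comps, p):
    s = np.array(
        [
            [comps[0], comps[3], comps[5]],
            [comps[3], comps[1], comps[4]],
            [comps[5], comps[4], comps[2]],
        ]
    )
    vm1 = fe.von_mises(s)
    vm2 = fe.von_mises(s + p * np.eye(3))
    assert vm2 == pytest.approx(vm1, abs=1e-8 * (1 + vm1))


@pytest.fixture(scope="module")
def cube_setup():
    mesh = make_box_mesh((4, 4, 4), 0.25)
    mats = model.default_materials().replace(1, Material(1000.0, 0.3))
    nodes = mesh.nodes
    bot = np.isclose(nodes[:, 2], 0.0)
    ids = np.where(bot)[0]
    fixed = np.zeros((len(ids), 3), bool)
    fixed[:, 2] = True
    pin = np.argmin(np.abs(nodes[:, 0]) + np.abs(nodes[:, 1]) + 100 * nodes[:, 2])
    pin2 = np.argmin(np.abs(nodes[:, 0] - 1) + np.abs(nodes[:, 1]) + 100 * nodes[:, 2])
    cons = ConstraintSet(
        np.concatenate([ids, [pin, pin2]]),
        np.concatenate([fixed, [[True, True, False], [False, True, False]]]),
    )
    return mesh, mats, cons


def test_zero_load_gives_zero_solution(cube_setup):
    mesh, mats, cons = cube_setup
    res = fe.solve(mesh, mats, None, cons)
    assert np.allclose(res.displacements, 0.0)
    assert np.allclose(res.element_stress, 0.0)
    assert np.allclose(res.von_mises, 0.0)


def test_unit_cube_uniaxial_exact(cube_setup):
    mesh, mats, cons = cube_setup
    F = -2.0  # N over 1 mm^2 top face
    top = np.isclose(mesh.nodes[:, 2], 1.0)
    loads = fe.surface_traction_loads(mesh, top, [0.0, 0.0, F])
    res = fe.solve(mesh, mats, loads, cons)
    assert np.allclose(res.element_stress[:, 2, 2], F, atol=1e-9)
    assert np.allclose(res.element_stress[:, 0, 0], 0.0, atol=1e-9)
    strain_zz = res.displacements[top][:, 2].mean() / 1.0
    assert strain_zz == pytest.approx(F / 1000.0, rel=1e-9)


def test_patch_test_reproduces_affine_field(cube_setup):
    mesh, mats, cons = cube_setup
    A = np.array([[1e-3, 2e-4, -1e-4], [0.0, 5e-4, 3e-4], [2e-4, -2e-4, 8e-4]])
    surf = mesh.surface_node_ids()
    vals = mesh.nodes[surf] @ A.T
    cons2 = ConstraintSet(surf, np.ones((len(surf), 3), bool), vals)
    res = fe.solve(mesh, mats, None, cons2)
    assert np.abs(res.displacements - mesh.nodes @ A.T).max() < 1e-12
    eps = 0.5 * (A + A.T)
    D = fe.isotropic_elasticity_matrix(mats[1])
    sv = D @ np.array(
        [eps[0, 0], eps[1, 1], eps[2, 2], 2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[0, 2]]
    )
    expect = np.array(
        [[sv[0], sv[3], sv[5]], [sv[3], sv[1], sv[4]], [sv[5], sv[4], sv[2]]]
    )
    assert np.abs(res.element_stress - expect).max() < 1e-10


def test_cantilever_matches_euler_bernoulli(cantilever_solution):
    _, _, tip_def, delta_eb = cantilever_solution
    assert abs(tip_def - delta_eb) / abs(delta_eb) < 0.05


def test_linearity_and_superposition(cube_setup):
    mesh, mats, cons = cube_setup
    op = fe.StiffnessOperator(mesh, mats, cons)
    top = np.isclose(mesh.nodes[:, 2], 1.0)
    f1 = fe.surface_traction_loads(mesh, top, [0.0, 0.0, -1.0])
    f2 = fe.surface_traction_loads(mesh, top, [0.5, 0.0, 0.0])
    r1, r2 = op.solve(f1), op.solve(f2)
    alpha = 3.7
    scaled = model.NodalLoadSet(f1.node_ids, alpha * f1.forces)
    rs = op.solve(scaled)
    assert np.allclose(rs.displacements, alpha * r1.displacements, rtol=1e-8)
    assert np.allclose(rs.von_mises, alpha * r1.von_mises, rtol=1e-8)
    combined = model.NodalLoadSet.combine([f1, f2])
    rc = op.solve(combined)
    assert np.allclose(
        rc.displacements, r1.displacements + r2.displacements, rtol=1e-8, atol=1e-15
    )
    assert np.allclose(
        rc.element_stress,
        r1.element_stress + r2.element_stress,
        rtol=1e-8,
        atol=1e-12,
    )


def test_frame_invariance_of_von_mises(cube_setup):
    mesh, mats, cons = cube_setup
    top = np.isclose(mesh.nodes[:, 2], 1.0)
    loads = fe.surface_traction_loads(mesh, top, [0.3, 0.0, -1.0])
    base = fe.solve(mesh, mats, loads, cons)
    th = np.deg2rad(30.0)
    R = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
    )
    rmesh = type(mesh)(
        mesh.nodes @ R.T, mesh.elements, mesh.tissue, dict(mesh.provenance)
    )
    rloads = model.NodalLoadSet(loads.node_ids, loads.forces @ R.T)
    # all three axes of each constrained node are fixed -> rotation-safe
    rcons = ConstraintSet(cons.node_ids, np.ones_like(cons.fixed_axes))
    rbase = fe.solve(mesh, mats, loads, ConstraintSet(cons.node_ids, np.ones_like(cons.fixed_axes)))
    rres = fe.solve(rmesh, mats, rloads, rcons)
    assert np.allclose(rres.von_mises, rbase.von_mises, rtol=1e-8, atol=1e-10)


def test_equilibrium_of_reactions(cube_setup):
    mesh, mats, cons = cube_setup
    top = np.isclose(mesh.nodes[:, 2], 1.0)
    loads = fe.surface_traction_loads(mesh, top, [0.2, 0.1, -1.5])
    res = fe.solve(mesh, mats, loads, cons)
    total = sum(res.reactions.values()) + loads.total()
    assert np.linalg.norm(total) <= 1e-8 * np.linalg.norm(loads.total())


def test_singular_system_raises_rigid_mode_error():
    mesh = make_box_mesh((2, 2, 2), 0.5)
    mats = model.default_materials().replace(1, Material(1000.0, 0.3))
    # single fully fixed node leaves rotational rigid modes
    cons = ConstraintSet(np.array([0]), np.ones((1, 3), bool))
    top = np.isclose(mesh.nodes[:, 2], 1.0)
    loads = fe.surface_traction_loads(mesh, top, [0.0, 0.0, -1.0])
    with pytest.raises((model.RigidModeError, fe.SolverError)):
        fe.solve(mesh, mats, loads, cons)
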