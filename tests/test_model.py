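import numpy as np
import pytest
from hypothesis import given, strategies as st

from mandifem import model
from mandifem.meshing import EmptySelectionError
from mandifem.phantom import ALVEOLAR, CORTICAL, ENAMEL, PDL, MandibleGeometry


def test_default_materials_match_published_table():
    mats = model.default_materials()
    assert mats[CORTICAL].E == pytest.approx(19920.0)
    assert mats[CORTICAL].nu == pytest.approx(0.30)
    assert mats[ENAMEL].E == pytest.approx(84100.0)
    assert mats[ENAMEL].nu == pytest.approx(0.33)
    assert mats[PDL].E == pytest.approx(50.0)
    assert mats[PDL].nu == pytest.approx(0.45)
    assert mats[ALVEOLAR].E == pytest.approx(345.0)


def test_material_invariants_enforced():
    with pytest.raises(ValueError):
        model.Material(E=-1.0, nu=0.3)
    with pytest.raises(ValueError):
        model.Material(E=1.0, nu=0.5)


@pytest.mark.parametrize(
    "biting, food, fz, fx",
    [
        ("gnawing", "hard", 2.5, 0.0),
        ("gnawing", "soft", 0.84, 0.0),
        ("chewing", "soft", 0.42, 0.42),
        ("chewing", "hard", 1.26, 1.26),
    ],
)
def test_scenario_load_table(biting, food, fz, fx):
    sc = model.scenario_loads(biting, food)
    assert sc.Fz == fz and sc.Fx == fx


def test_unknown_scenario_enum_rejected():
    with pytest.raises(ValueError):
        model.scenario_loads("licking", "hard")


def test_gnawing_with_horizontal_load_is_invalid():
    with pytest.raises(ValueError):
        model.Scenario(model.Biting.GNAWING, model.Food.HARD, Fz=1.0, Fx=0.5)


def test_muscle_allocation_fractions():
    sc = model.scenario_loads("gnawing", "hard")
    forces = model.allocate_muscle_forces(sc)
    assert forces["internal_pterygoid"][2] == pytest.approx(0.23 * 2.5)  # 0.575 N
    sc2 = model.scenario_loads("chewing", "hard")
    forces2 = model.allocate_muscle_forces(sc2)
    assert forces2["temporalis"][0] == pytest.approx(0.40 * 1.26)  # 0.504 N
    zero = model.Scenario(model.Biting.CHEWING, model.Food.SOFT, Fz=0.0, Fx=0.0)
    assert all(np.allclose(f, 0) for f in model.allocate_muscle_forces(zero).values())


def test_published_fraction_sums():
    muscles = model.default_muscles()
    assert sum(m.fz_fraction for m in muscles) == pytest.approx(0.88)
    assert sum(m.fx_fraction for m in muscles) == pytest.approx(1.00)


def test_full_bounds_box_selects_all_surface_nodes(gt_mesh):
    lo = gt_mesh.nodes.min(axis=0) - 1
    hi = gt_mesh.nodes.max(axis=0) + 1
    box = [((lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2]))]
    sel = model.select_region_nodes(gt_mesh, "custom", boxes=box)
    assert np.array_equal(np.sort(sel), gt_mesh.surface_node_ids())


def test_condyle_region_is_mediolaterally_symmetric(gt_mesh):
    sel = model.select_region_nodes(gt_mesh, "condyle_articular", MandibleGeometry(), 4.0)
    y = gt_mesh.nodes[sel, 1]
    assert len(sel) > 0
    assert (y > 4.0).any() and (y < 4.0).any()
    # mirror symmetry of the selected y offsets, to within one block
    # (the block lattice need not straddle the midline exactly)
    block = max(gt_mesh.provenance["block_size"])
    pos = np.abs(y[y > 4.0] - 4.0)
    neg = np.abs(y[y < 4.0] - 4.0)
    assert abs(pos.mean() - neg.mean()) <= block
    assert abs(pos.max() - neg.max()) <= block


def test_disjoint_box_raises_empty_selection(gt_mesh):
    box = [((1e3, 2e3), (1e3, 2e3), (1e3, 2e3))]
    with pytest.raises(EmptySelectionError, match="bounds"):
        model.select_region_nodes(gt_mesh, "nowhere", boxes=box)


def test_distribute_load_equal_split_and_conservation():
    ls = model.distribute_load(np.arange(4), [0.0, 0.0, -2.5])
    assert np.allclose(ls.forces, [0.0, 0.0, -0.625])
    assert np.allclose(ls.total(), [0.0, 0.0, -2.5])
    single = model.distribute_load(np.array([7]), [1.0, 2.0, 3.0])
    assert np.allclose(single.forces[0], [1.0, 2.0, 3.0])
    with pytest.raises(EmptySelectionError):
        model.distribute_load(np.array([], np.int64), [1.0, 0.0, 0.0])


@given(st.integers(1, 50), st.floats(-10, 10), st.floats(-10, 10))
def test_distribute_load_total_to_machine_precision(n, fx, fz):
    ls = model.distribute_load(np.arange(n), [fx, 0.0, fz])
    assert np.allclose(ls.total(), [fx, 0.0, fz], rtol=0, atol=1e-12 * max(1, abs(fx), abs(fz)))


def test_distribute_load_zero_moment_for_symmetric_nodes():
    # nodes symmetric about their centroid -> zero moment of equal loads
    pts = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 2.0, 0], [0, -2.0, 0]])
    ls = model.distribute_load(np.arange(4), [0, 0, -1.0])
    centroid = pts.mean(axis=0)
    m = np.cross(pts - centroid, ls.forces).sum(axis=0)
    assert np.allclose(m, 0.0, atol=1e-15)


def test_bite_directions():
    g = model.bite_direction("gnawing")
    assert g[0] == 0.0 and np.isclose(np.linalg.norm(g), 1.0)
    c = model.bite_direction("chewing", "hard")
    assert np.isclose(np.linalg.norm(c), 1.0)
    assert np.allclose(c, np.array([1.26, 0.0, 1.26]) / np.linalg.norm([1.26, 0.0, 1.26]))


def test_tmj_constraints_symmetric_and_solvable(gt_mesh):
    cons = model.tmj_constraints(gt_mesh, MandibleGeometry(), 4.0)
    y = gt_mesh.nodes[cons.node_ids, 1]
    assert (y > 4.0).any() and (y < 4.0).any()
    assert cons.fixed_axes.all()
    # constrained nodes are non-collinear (suppresses all rigid modes)
    p = gt_mesh.nodes[cons.node_ids]
    s = np.linalg.svd(p - p.mean(axis=0), compute_uv=False)
    assert s[1] > 1e-9


def test_tmj_constraints_error_without_condyle():
    from conftest import make_box_mesh

    bar = make_box_mesh((6, 2, 2), 0.25)  # no condylar anatomy
    with pytest.raises(EmptySelectionError):
        model.tmj_constraints(bar, MandibleGeometry(), 0.25)


def test_scenario_system_is_nonsingular(scenario_results):
    for res in scenario_results.results.values():
        assert res.residual <= 1e-8
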