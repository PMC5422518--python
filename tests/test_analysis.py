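import numpy as np
import pandas as pd
import pytest

from mandifem import analysis, model


GNAWING_RATIO = 2.5 / 0.84
CHEWING_RATIO = 1.26 / 0.42


def test_report_covers_all_scenarios_and_regions(scenario_results):
    rep = scenario_results.report
    assert set(rep.scenario) == {
        "gnawing_soft",
        "gnawing_hard",
        "chewing_soft",
        "chewing_hard",
    }
    assert set(rep.region) == set(analysis.REPORT_REGIONS)


def test_region_statistics_are_ordered(scenario_results):
    rep = scenario_results.report
    ok = rep.dropna()
    assert (ok["max"] >= ok["p99"] - 1e-12).all()
    assert (ok["p99"] >= ok["mean"] - 1e-12).all()
    assert (ok["mean"] >= 0).all()


@pytest.mark.parametrize(
    "hard, soft, ratio",
    [
        ("gnawing_hard", "gnawing_soft", GNAWING_RATIO),
        ("chewing_hard", "chewing_soft", CHEWING_RATIO),
    ],
)
def test_food_type_ratio_equals_load_ratio_exactly(scenario_results, hard, soft, ratio):
    """Linearity: every reported statistic scales by the published load
    ratio between food types, to 1e-6 relative."""
    rep = scenario_results.report
    h = rep[rep.scenario == hard].set_index("region")
    s = rep[rep.scenario == soft].set_index("region")
    for stat in ("max", "mean", "p99"):
        r = (h[stat] / s[stat]).dropna()
        assert np.allclose(r, ratio, rtol=1e-6), (stat, r)


def test_gnawing_stresses_pdl_without_molar_load(scenario_results):
    rep = scenario_results.report
    pdl = rep[(rep.scenario == "gnawing_hard") & (rep.region == "pdl")]
    assert pdl["max"].item() > 0


def test_gnawing_doubles_anterior_corpus_stress(scenario_results):
    rep = scenario_results.report.set_index(["scenario", "region"])
    g = rep.loc[("gnawing_hard", "anterior_corpus"), "p99"]
    c = rep.loc[("chewing_hard", "anterior_corpus"), "p99"]
    assert g >= 2.0 * c


def test_chewing_dominates_at_the_molars(scenario_results):
    """The bite load applied on the molar row stresses the molars more
    during chewing than during gnawing at equal food type."""
    rep = scenario_results.report.set_index(["scenario", "region"])
    assert (
        rep.loc[("chewing_hard", "molars"), "p99"]
        > rep.loc[("gnawing_hard", "molars"), "p99"]
    )


def test_pdl_report_four_rows_and_load_ratios(scenario_results):
    pdl = analysis.pdl_report(scenario_results.report)
    assert len(pdl) == 4
    assert (pdl["max"] >= 0).all()
    ratios = pdl.attrs["hard_soft_ratio"]
    assert ratios["gnawing"] == pytest.approx(GNAWING_RATIO, rel=1e-6)
    assert ratios["chewing"] == pytest.approx(CHEWING_RATIO, rel=1e-6)


def test_pdl_report_missing_scenario_raises(scenario_results):
    partial = scenario_results.report[
        scenario_results.report.scenario != "chewing_soft"
    ]
    with pytest.raises(ValueError, match="chewing_soft"):
        analysis.pdl_report(partial)


def test_cushioning_comparison_is_reported_for_both_loads(cushioning):
    assert set(cushioning.soft_pdl_peak) == {"chewing_soft", "chewing_hard"}
    assert all(v > 0 for v in cushioning.soft_pdl_peak.values())
    assert all(v > 0 for v in cushioning.stiff_pdl_peak.values())


def test_cushioning_identical_moduli_give_identical_peaks(
    default_config, scenario_results
):
    cmp1 = analysis.pdl_cushioning_test(
        default_config, mesh=scenario_results.mesh, factor=1.0
    )
    for k in cmp1.soft_pdl_peak:
        assert cmp1.soft_pdl_peak[k] == pytest.approx(cmp1.stiff_pdl_peak[k], rel=1e-9)


def test_convergence_element_counts_increase(default_config):
    df = analysis.convergence_study(default_config, levels=(6, 5, 4))
    assert df["n_elements"].is_monotonic_increasing
    assert df["coarsen"].is_monotonic_decreasing


def test_convergence_rejects_non_refining_levels(default_config):
    with pytest.raises(ValueError, match="refine"):
        analysis.convergence_study(default_config, levels=(4, 4, 2))
    with pytest.raises(ValueError, match="3 refinement"):
        analysis.convergence_study(default_config, levels=(4, 2))


def test_cantilever_error_decreases_under_refinement():
    """Tip-deflection error against the Euler-Bernoulli closed form
    shrinks monotonically over three mesh refinements."""
    from conftest import make_box_mesh
    from mandifem import fe

    errors = []
    for n, h in (((30, 3, 3), 1.0 / 3.0), ((50, 5, 5), 0.2), ((100, 10, 10), 0.1)):
        mesh = make_box_mesh(n, h)
        mats = model.default_materials().replace(1, model.Material(1000.0, 0.3))
        root = np.isclose(mesh.nodes[:, 0], 0.0)
        cons = model.ConstraintSet(
            np.where(root)[0], np.ones((int(root.sum()), 3), bool)
        )
        tip = np.isclose(mesh.nodes[:, 0], 10.0)
        loads = fe.surface_traction_loads(mesh, tip, [0.0, 0.0, -0.001])
        res = fe.solve(mesh, mats, loads, cons)
        tip_def = res.displacements[tip][:, 2].mean()
        delta = -0.001 * 1000.0 / (3.0 * 1000.0 * (1.0 / 12.0))
        errors.append(abs(tip_def - delta) / abs(delta))
    assert errors[0] > errors[1] > errors[2]


def test_lever_oracle_closed_form_and_monotonicity():
    est = analysis.lever_oracle(10.0, 2.5, 2.0, 2.0)
    assert est.moment == pytest.approx(25.0)
    assert est.stress == pytest.approx(18.75)
    double = analysis.lever_oracle(20.0, 2.5, 2.0, 2.0)
    assert double.stress == pytest.approx(2 * est.stress)
    incisor_arm, molar_arm = 13.0, 6.5
    g = analysis.lever_oracle(incisor_arm, 1.0, 2.0, 2.0)
    c = analysis.lever_oracle(molar_arm, 1.0, 2.0, 2.0)
    assert g.moment > c.moment
    with pytest.raises(ValueError):
        analysis.lever_oracle(-1.0, 1.0, 1.0, 1.0)


def test_lever_oracle_predicts_fe_gnawing_vs_chewing_ordering(scenario_results):
    """The moment ratio from simple lever mechanics agrees in direction
    with the FE anterior-corpus ordering."""
    rep = scenario_results.report.set_index(["scenario", "region"])
    fe_ratio = (
        rep.loc[("gnawing_hard", "anterior_corpus"), "p99"]
        / rep.loc[("chewing_hard", "anterior_corpus"), "p99"]
    )
    lever_ratio = (
        analysis.lever_oracle(13.0, 2.5, 2.4, 2.0).stress
        / analysis.lever_oracle(6.5, 1.26, 2.4, 2.0).stress
    )
    assert (fe_ratio > 1) == (lever_ratio > 1)


def test_run_scenarios_stage_errors_are_labelled():
    bad = analysis.PipelineConfig(
        spec=analysis.PhantomSpec(voxel_size=0.5)  # PDL below one voxel
    )
    with pytest.raises(RuntimeError, match="stage"):
        analysis.run_scenarios(bad)
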