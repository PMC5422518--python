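import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mandifem import analysis, model
from mandifem.meshing import labels_to_tetmesh
from mandifem.phantom import LabelVolume, PhantomSpec, generate_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_box_mesh(shape=(4, 4, 4), h=0.25, tissue=1, coarsen=1):
    """Uniform-tissue structured block mesh, used by the FE oracles."""
    lab = np.full(shape, tissue, np.uint8)
    return labels_to_tetmesh(LabelVolume((0.0, 0.0, 0.0), (h, h, h), lab), coarsen)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def clean_phantom(default_spec):
    """Noise- and blur-free phantom: grayscale equals class means exactly."""
    return generate_phantom(default_spec.replace(noise_sigma=0.0, blur_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_phantom(default_spec):
    """Phantom at the default study conditions."""
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def gt_mesh(clean_phantom):
    """Coarse mesh of the ground-truth labels (model/FE tests)."""
    _, labels = clean_phantom
    return labels_to_tetmesh(labels, 3)


@pytest.fixture(scope="session")
def default_config():
    return analysis.PipelineConfig()


@pytest.fixture(scope="session")
def scenario_results(default_config):
    """The four masticatory scenarios solved once on the default pipeline."""
    return analysis.run_scenarios(default_config)


@pytest.fixture(scope="session")
def cushioning(default_config, scenario_results):
    return analysis.pdl_cushioning_test(
        default_config, mesh=scenario_results.mesh, statistic="max"
    )


@pytest.fixture(scope="session")
def cantilever_solution():
    """Slender cantilever (L/h = 10) under an end load, with the
    Euler-Bernoulli closed form."""
    from mandifem import fe

    mesh = make_box_mesh((100, 10, 10), 0.1)
    mats = model.default_materials().replace(1, model.Material(1000.0, 0.3))
    nodes = mesh.nodes
    root = np.isclose(nodes[:, 0], 0.0)
    cons = model.ConstraintSet(
        np.where(root)[0], np.ones((int(root.sum()), 3), bool)
    )
    tip = np.isclose(nodes[:, 0], 10.0)
    F = -0.001  # N total over the 1 mm^2 tip
    loads = fe.surface_traction_loads(mesh, tip, [0.0, 0.0, F])
    res = fe.solve(mesh, mats, loads, cons)
    delta_eb = F * 10.0**3 / (3.0 * 1000.0 * (1.0 / 12.0))
    tip_def = res.displacements[tip][:, 2].mean()
    return mesh, res, tip_def, delta_eb
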