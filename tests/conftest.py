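import numpy as np
import pytest

from trajgrn.data_io import FixtureConfig, generate_fixture_dataset
from trajgrn.ode_core import GRNModel, GeneKinetics, RegulationEdgeParams
from trajgrn.trajectories import TrajectoryBundle, uniform_grid


@pytest.fixture(scope="session")
def grid201():
    return uniform_grid(201)


@pytest.fixture(scope="session")
def fixture_dataset():
    """Small synthetic dataset with known trajectory shapes."""
    ds, truth = generate_fixture_dataset(FixtureConfig(n_genes=60, n_cells=200),
                                         seed=1)
    return ds, truth


@pytest.fixture
def unregulated_gene():
    kin = {"A": GeneKinetics("A", production=3.0, degradation=1.5)}
    return GRNModel(genes=["A"], kinetics=kin, edges=[])


@pytest.fixture
def toggle_switch():
    """Symmetric mutual-inhibition two-gene switch (bistable)."""
    kin = {g: GeneKinetics(g, production=2.0, degradation=1.0) for g in "AB"}
    edges = [RegulationEdgeParams("A", "B", 0.05, 1.0, 4.0),
             RegulationEdgeParams("B", "A", 0.05, 1.0, 4.0)]
    return GRNModel(genes=["A", "B"], kinetics=kin, edges=edges)


@pytest.fixture
def cascade_model():
    """Monostable linear cascade A -> B -> C."""
    kin = {g: GeneKinetics(g, production=2.0, degradation=1.0) for g in "ABC"}
    edges = [RegulationEdgeParams("A", "B", 4.0, 1.0, 3.0),
             RegulationEdgeParams("B", "C", 4.0, 2.0, 3.0)]
    return GRNModel(genes=["A", "B", "C"], kinetics=kin, edges=edges)


@pytest.fixture
def cascade_bundle(grid201):
    a = 0.2 + 1.6 * grid201
    return TrajectoryBundle.from_arrays(["A", "B", "C"], grid201,
                                        np.vstack([a, a * 0.5, a * 0.3]))
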