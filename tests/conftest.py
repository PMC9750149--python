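import warnings

import numpy as np
import pytest

import tattooseq as tq

# scipy's trust-constr warns when the quasi-Newton update sees a locally
# linear objective; harmless here
warnings.filterwarnings(
    "ignore", message="delta_grad == 0.0", category=UserWarning)


@pytest.fixture(scope="session")
def model():
    return tq.LimbModel.build()


@pytest.fixture(scope="session")
def sim_small(model):
    """One small end-to-end simulation shared across test modules."""
    cfg = tq.SimulationConfig(seed=1, n_limbs_per_pattern=2,
                              n_cells_per_limb=1200, n_genes=300,
                              n_spatial=30)
    facs, cm, truth = tq.simulate_limb_dataset(cfg, model)
    return cfg, facs, cm, truth


@pytest.fixture(scope="session")
def calls_small(sim_small):
    _, facs, _, _ = sim_small
    return tq.call_colors(facs, seed=1)


@pytest.fixture(scope="session")
def groups_small(sim_small, model):
    _, _, _, truth = sim_small
    return tq.make_metacells(truth, model, min_size=20, seed=1)


@pytest.fixture(scope="session")
def posts_small(calls_small, groups_small, model):
    groups, _ = groups_small
    return tq.infer_groups(calls_small, groups, model.grid.forward, seed=1)


@pytest.fixture(scope="session")
def toy_forward():
    """3-sbin toy forward model with all three patterns informative."""
    return {
        "PD": np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]], float),
        "AP": np.array([[0, 0, 1, 0], [1, 0, 0, 0], [0, 1, 0, 0]], float),
        "AER": np.array([[0.6, 0.3, 0.1, 0], [0.2, 0.5, 0.3, 0],
                         [0.1, 0.2, 0.7, 0]], float),
    }
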