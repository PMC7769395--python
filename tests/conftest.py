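import numpy as np
import pytest

from dosenoise import DoseGrid, PlanSpec, StructureMask, make_plan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_grid(rng):
    """Small random dose grid with float32-representable values."""
    values = rng.uniform(0.0, 30.0, size=(8, 8, 8)).astype(np.float32)
    return DoseGrid(values=values.astype(np.float64), spacing_cm=0.1,
                    origin_cm=(1.0, -2.0, 3.5), plan_id="rand")


@pytest.fixture(scope="session")
def brain_plan():
    """One small normalised brain plan shared across tests."""
    spec = PlanSpec(site="brain", gtv_radius_cm=0.6, shape=(64, 64, 64), seed=7)
    grid, masks = make_plan(spec)
    return spec, grid, masks


@pytest.fixture(scope="session")
def spine_plan():
    spec = PlanSpec(site="spine", gtv_radius_cm=1.2, shape=(64, 72, 64), seed=11)
    grid, masks = make_plan(spec)
    return spec, grid, masks
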