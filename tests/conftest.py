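import sys, pathlib
sys.path.insert(0, str(pathlib.Path(__file__).parent))
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import burstrel as br
from burstrel.synthetic_data import (
    GaussianComponents,
    SimConfig,
    TaskSpec,
    study2_config,
    study3_config,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: components where every facet has substantial variance; keeps REML
#: solutions away from the boundary so estimator-agreement checks are clean
INTERIOR = GaussianComponents(mu=5.0, p=1.0, o=0.3, i=0.5, po=0.4, pi=0.3, oi=0.2, e=1.0)

THREE_TASKS = [
    TaskSpec(name="ospan", set_sizes=[5, 6]),
    TaskSpec(name="sspan", set_sizes=[4, 5]),
    TaskSpec(name="rspan", set_sizes=[4, 5]),
]


def interior_config(**overrides) -> SimConfig:
    base = dict(
        n_persons=25,
        n_days=2,
        sessions_per_day=3,
        tasks=THREE_TASKS,
        mode="gaussian",
        components=INTERIOR,
        compliance=1.0,
        seed=3,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def interior_result():
    """Balanced gaussian burst with all components solidly positive."""
    return br.simulate(interior_config())


@pytest.fixture(scope="session")
def mech_result():
    """Small mechanistic three-task burst with full compliance."""
    cfg = study2_config(mode="mechanistic", n_persons=12, compliance=1.0, seed=21)
    return br.simulate(cfg)


@pytest.fixture(scope="session")
def study3_balanced():
    """Balanced gaussian single-task burst at the 7-day geometry."""
    cfg = study3_config(n_persons=60, compliance=1.0, seed=9)
    return br.simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
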