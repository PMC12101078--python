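import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from membind import SyntheticParams, simulate_binding_trajectory, simulate_replicas

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


SMALL_BOX = (6.0, 6.0, 18.0)


def make_params(**overrides) -> SyntheticParams:
    """Small, fast generator settings shared across tests."""
    base = dict(
        n_residues=10,
        first_residue=1,
        interface_residues=frozenset({2, 3, 4}),
        box=SMALL_BOX,
        n_frames=400,
        p_bind=0.1,
        p_unbind=0.1,
        seed=11,
    )
    base.update(overrides)
    return SyntheticParams(**base)


@pytest.fixture(scope="session")
def small_params():
    return make_params()


@pytest.fixture(scope="session")
def small_trajectory(small_params):
    return simulate_binding_trajectory(small_params)


@pytest.fixture(scope="session")
def bound_only_trajectory():
    params = make_params(
        p_bind=1.0, p_unbind=0.0, initial_state="bound", n_frames=1250, seed=5
    )
    return simulate_binding_trajectory(params)


@pytest.fixture(scope="session")
def unbound_only_trajectory():
    params = make_params(p_bind=0.0, p_unbind=1.0, initial_state="unbound", seed=6)
    return simulate_binding_trajectory(params)


@pytest.fixture(scope="session")
def small_replicas():
    params = make_params(n_frames=800, seed=21)
    return simulate_replicas(params, 4)


def random_frame(rng: np.random.Generator, n_a: int, n_b: int, box=(17.0, 17.0, 25.0)):
    """Random disjoint two-group system inside an orthorhombic box."""
    from membind import Frame

    box = np.asarray(box, dtype=float)
    coords = rng.uniform(0.0, 1.0, size=(n_a + n_b, 3)) * box
    frame = Frame(time=0.0, box=box, coords=coords)
    return frame, np.arange(n_a), np.arange(n_a, n_a + n_b)
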