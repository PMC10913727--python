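import numpy as np
import pytest

from mssid.params import MultiscaleParams, pset_from_nset
from mssid.simulate import SimConfig, generate_random_model, simulate_data


def random_stable_params(seed: int, n_x=3, n_y=2, n_z=2) -> MultiscaleParams:
    """Small random stable model, not in canonical block-diagonal form."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_x, n_x))
    A *= 0.9 / max(np.abs(np.linalg.eigvals(A)))
    L = rng.standard_normal((n_x, n_x)) * 0.5
    Q = L @ L.T + 0.1 * np.eye(n_x)
    Lr = rng.standard_normal((n_y, n_y)) * 0.3
    R_y = Lr @ Lr.T + 0.05 * np.eye(n_y)
    return MultiscaleParams(
        A=A,
        C_y=rng.standard_normal((n_y, n_x)),
        C_z=rng.standard_normal((n_z, n_x)) * 0.3,
        Q=Q,
        R_y=R_y,
        d_z=rng.uniform(-2.5, -1.5, n_z),
    )


@pytest.fixture(scope="session")
def small_model():
    return random_stable_params(seed=7)


@pytest.fixture(scope="session")
def study_model():
    """A ground-truth model drawn under the standard study conditions."""
    cfg = SimConfig(n_z=8, n_y=16, M=5, seed=42)
    model, info = generate_random_model(cfg)
    return cfg, model, info


@pytest.fixture(scope="session")
def study_data(study_model):
    cfg, model, info = study_model
    return simulate_data(model, T=40_000, M=cfg.M, seed=4242)


@pytest.fixture(scope="session")
def study_truth(study_model):
    _, model, _ = study_model
    return pset_from_nset(model)
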