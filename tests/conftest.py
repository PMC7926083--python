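import numpy as np
import pytest

from diffcpf import Trajectory
from diffcpf.models import LgssParams, SeirParams, lgss_model, simulate_lgss, simulate_seir


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lgss_setup():
    """Canonical noisy AR(1) dataset with model and exact-smoother params."""
    params = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=50, sigma_1=10.0)
    gen = np.random.default_rng(777)
    x, y = simulate_lgss(params, 0.0, gen)
    return {
        "params": params,
        "x": x,
        "y": y,
        "model": lgss_model(y, params),
        "reference": Trajectory(x[:, None]),
    }


@pytest.fixture(scope="session")
def seir_setup():
    """Synthetic epidemic at the study parameters (n_pop=1e4, T=60)."""
    params = SeirParams(
        n_pop=10_000, r0_max=10.0, a=1 / 3, gamma=1 / 7,
        e=0.15, p=0.134, sigma=0.15, T=60,
    )
    gen = np.random.default_rng(99)
    init = np.array([params.n_pop - 30, 20, 10, 0, -1.0])
    path, counts = simulate_seir(params, init, gen)
    return {"params": params, "path": path, "counts": counts, "true_init": init}
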