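import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nfwaves import KernelParams, ModelParams, NoiseSpec, SimConfig


@pytest.fixture(scope="session")
def fig_kernel() -> KernelParams:
    """Reference kernel: W_E=144.4, W_I=73.7, scales 1.87/3.24 field units."""
    return KernelParams(144.4, 73.7, 1.87, 3.24)


@pytest.fixture(scope="session")
def strong_kernel() -> KernelParams:
    """More excitatory kernel used for wave solutions and regime studies."""
    return KernelParams(200.0, 73.7, 1.87, 3.24)


@pytest.fixture(scope="session")
def model() -> ModelParams:
    return ModelParams(p=0.42, kappa=1.0, tau=10.0)


@pytest.fixture(scope="session")
def model_p03() -> ModelParams:
    return ModelParams(p=0.3, kappa=1.0, tau=10.0)


@pytest.fixture
def small_config(fig_kernel, model) -> SimConfig:
    """Cheap 64x64 configuration for fast simulator tests."""
    return SimConfig(
        grid_n=64, spacing=0.5, dt=0.01, duration=0.1, snapshot_stride=5,
        kernel=fig_kernel, model=model, noise=NoiseSpec(),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
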