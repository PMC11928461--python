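import numpy as np
import pytest
from scipy.linalg import solve_banded

from guvphase.synth import SynthConfig


def crank_nicolson_profile(width_um, frac, d_m2_s, t_s, nx=4000, nt=2000):
    """Implicit finite-difference oracle for the lateral diffusion model:
    Crank-Nicolson with two implicit-Euler startup steps (damps the
    top-hat discontinuity), no-flux walls."""
    dx = width_um * 1e-6 / nx
    x = (np.arange(nx) + 0.5) * dx
    u = (x <= frac * width_um * 1e-6).astype(float)
    dt = t_s / nt
    r = d_m2_s * dt / dx**2

    def step(u, theta):
        n = len(u)
        diag = np.full(n, 1 + 2 * theta * r)
        diag[0] = diag[-1] = 1 + theta * r
        rhs = u + (1 - theta) * r * (np.roll(u, -1) - 2 * u + np.roll(u, 1))
        rhs[0] = u[0] + (1 - theta) * r * (u[1] - u[0])
        rhs[-1] = u[-1] + (1 - theta) * r * (u[-2] - u[-1])
        ab = np.zeros((3, n))
        ab[0, 1:] = -theta * r
        ab[1] = diag
        ab[2, :-1] = -theta * r
        return solve_banded((1, 1), ab, rhs)

    u = step(u, 1.0)
    u = step(u, 1.0)
    for _ in range(nt - 2):
        u = step(u, 0.5)
    return x / 1e-6, u


@pytest.fixture
def quiet_cfg():
    """Noise-free generator configuration (ideal-data contracts)."""
    return SynthConfig(seed=1, noise_sd=0.0)


@pytest.fixture
def noisy_cfg():
    """Default-SNR generator configuration."""
    return SynthConfig(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
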