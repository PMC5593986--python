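import numpy as np
import pytest

from spotvar import (
    CorrelationCurve,
    DiffusionLawPoint,
    MembraneModel,
    SimConfig,
    build_membrane,
    model_acf,
    simulate,
)
from spotvar.acffit import AcfModelParams


@pytest.fixture(scope="session")
def free_model() -> MembraneModel:
    return build_membrane(box_edge=2.0, D_out=2.0)


@pytest.fixture(scope="session")
def free_traj(free_model):
    """Short free-diffusion trajectory shared by read-only tests."""
    return simulate(free_model, SimConfig(n_particles=50, n_steps=2 ** 14, seed=3))


@pytest.fixture
def synthetic_curve():
    """Noise-free correlation curve generated from the ACF model itself."""

    def make(G0=0.1, tau_D=5.0, alpha=1.0, baseline=0.0, n=120):
        lags_s = np.logspace(-5, 0, n)
        p = AcfModelParams(G0=G0, tau_D=tau_D, alpha=alpha, baseline=baseline)
        return CorrelationCurve(lags_s, model_acf(lags_s * 1e3, p))

    return make


def law_points_on_line(slope, t0, d_values, noise=0.0, seed=None, se=None):
    """Diffusion-law points on tau = slope*d^2 + t0 (d in nm, tau in ms)."""
    rng = np.random.default_rng(seed)
    pts = []
    for d in d_values:
        tau = slope * d ** 2 + t0
        if noise:
            tau *= 1.0 + noise * rng.standard_normal()
        pts.append(
            DiffusionLawPoint(
                d, tau, se if se is not None else (noise * tau if noise else None)
            )
        )
    return pts
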