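import numpy as np
import pytest

from foldcaustic import build_chain, integrate_trajectory
from foldcaustic.dynamics import Trajectory


@pytest.fixture
def harmonic_half_chain():
    """Unit oscillator: V = theta^2/2, m = 1, omega = 1."""
    return build_chain({
        "n_angles": 1, "inertias": 1.0,
        "potential": {"kind": "harmonic_spring", "k": 1.0, "half_k": True},
    })


@pytest.fixture
def harmonic_paper_chain():
    """Printed-convention spring: V = k*theta^2 with k=1 -> omega = sqrt(2)."""
    return build_chain({
        "n_angles": 1, "inertias": 1.0,
        "potential": {"kind": "harmonic_spring", "k": 1.0},
    })


@pytest.fixture
def free_chain():
    return build_chain({
        "n_angles": 1, "inertias": 1.0, "potential": {"kind": "free"},
    })


@pytest.fixture
def inverted_chain():
    """V = -theta^2/2: Jacobi fields grow like sinh, no conjugate points."""
    return build_chain({
        "n_angles": 1, "inertias": 1.0,
        "potential": {"kind": "harmonic_spring", "k": -1.0, "half_k": True},
    })


def analytic_trajectory(chain, f, fdot, t0, t1, n_steps):
    """Sample closed-form motion theta(t) = f(t) onto a Trajectory."""
    t = t0 + (t1 - t0) * np.arange(n_steps + 1) / n_steps
    return Trajectory(t=t, q=f(t)[:, None], v=fdot(t)[:, None], chain=chain,
                      integrator="analytic")


@pytest.fixture
def harmonic_trajectory(harmonic_half_chain):
    """Integrated unit-oscillator path on [0, 4] (conjugate point at pi)."""
    return integrate_trajectory(harmonic_half_chain, 1.0, 0.0, 0.0, 4.0, 800)
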