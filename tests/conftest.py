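import numpy as np
import pytest

from ntpsleep.cascade import EpisodeModel, ModeOccupancy, PhasePlan


def rk4_cascade(n0, p1, p2, t_end, n_steps=20000):
    """Independent fixed-step RK4 integration of the serial decay chain.

    dN1/dt = -p1 N1; dN2/dt = p1 N1 - p2 N2; dN3/dt = p2 N2.
    Used as the oracle against which the closed form is checked.
    """
    y = np.asarray(n0, dtype=float)
    h = t_end / n_steps

    def rhs(y):
        return np.array([-p1 * y[0], p1 * y[0] - p2 * y[1], p2 * y[1]])

    for _ in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + h / 2 * k1)
        k3 = rhs(y + h / 2 * k2)
        k4 = rhs(y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


@pytest.fixture
def three_cycle_model():
    """A three-TA-cycle episode with well-separated switchovers."""
    return EpisodeModel(
        plan=PhasePlan(switchover_times=(19.0, 31.0, 53.0, 65.0, 85.0)),
        initial_occupancy=ModeOccupancy(1.0, 0.0, 0.0),
        band_scales={"delta": 120.0, "sigma": 12.0, "beta": 5.0},
        beta_bias=2.0,
    )
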