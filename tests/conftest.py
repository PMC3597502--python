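import numpy as np
import pytest

from phagedyn.core import ModelParams
from phagedyn.engine import SimulationControl
from phagedyn.scenarios import Scenario

# Reference wild-type parameterisation used across the suite.
BASE_KW = dict(v=1.4, k=1.0, e=5e-7, delta=8e-8, beta=80.0, lam=0.4)


@pytest.fixture
def base_params():
    return ModelParams(**BASE_KW, m=0.0, mu=0.0, n_orders=1)


@pytest.fixture
def base_params3():
    return ModelParams(**BASE_KW, m=0.0, mu=0.0, n_orders=3)


def make_scenario(
    params,
    B,
    P,
    r=350.0,
    dt=1e-3,
    duration=24.0,
    output_every=0.1,
    seed=0,
    event_mode="unit",
    **kw,
):
    return Scenario(
        name="test",
        params=params,
        control=SimulationControl(
            dt=dt,
            duration=duration,
            seed=seed,
            event_mode=event_mode,
            output_every=output_every,
        ),
        init_r=r,
        init_B=tuple(B),
        init_P=tuple(P),
        **kw,
    )


def euler_delay_reference(r0, B0, P0, v, k, e, delta, beta, lam, dt, t_end, sample_every=None):
    """Independent scalar Euler integration of the one-order delay system.

    Deliberately separate from the package's engine: plain Python floats, a
    list-based flux history, no event machinery.  Used as the fine-step
    oracle for the hybrid integrator (m = mu = 0).
    """
    n = round(t_end / dt)
    n_lag = round(lam / dt)
    hist = [0.0] * n_lag
    head = 0
    r, B, P = r0, B0, P0
    samples = {}
    stride = None if sample_every is None else round(sample_every / dt)
    for s in range(n):
        lag = hist[head]
        psi = v * r / (r + k)
        f = delta * B * P
        r_next = r - e * psi * B * dt
        B_next = B + (psi * B - f) * dt
        P_next = P + ((beta - 1.0) * lag - f) * dt
        hist[head] = f
        head = (head + 1) % n_lag
        r = r_next if r_next > 0 else 0.0
        B = B_next if B_next > 0 else 0.0
        P = P_next if P_next > 0 else 0.0
        if stride and (s + 1) % stride == 0:
            samples[round((s + 1) * dt, 9)] = (r, B, P)
    if sample_every is None:
        return r, B, P
    return samples
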