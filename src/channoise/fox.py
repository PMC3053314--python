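"""Fox-Lu Langevin comparator: noise added to the gating-variable equations.

Each gating variable x obeys ``dx = [alpha (1 - x) - beta x] dt + xi_x``
where ``xi_x`` is Gaussian white noise with covariance
``2 alpha beta / (N (alpha + beta)) * delta(t - t')`` (the stationary
coefficient of Fox 1997). Equivalently, x is an Ornstein-Uhlenbeck process
around ``x_inf`` with time constant ``1/(alpha + beta)`` and stationary
variance ``x_inf (1 - x_inf)/N``; the update used here is the exact OU
exponential one, and gates are clipped to [0, 1] after each step. The
conductance is formed from the plain gate product (m^3 h, n^4).

For a single 2-state gate this construction coincides with the diffusion
approximation; for gate products it mis-states variance and autocorrelation,
which is what the comparisons in this package quantify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .effective import simulate_ou
from .kinetics import ChannelScheme
from .rates import subunit_steady_state

__all__ = ["FoxState", "init_fox_state", "step_fox", "run_voltage_clamp_fox"]


@dataclass
class FoxState:
    """Gating-variable values in [0, 1], one per subunit type."""

    gates: np.ndarray

    def __post_init__(self):
        self.gates = np.asarray(self.gates, dtype=float)


def init_fox_state(scheme: ChannelScheme, v) -> FoxState:
    gates = np.array([subunit_steady_state(s.rates, v)[0] for s in scheme.subunits])
    return FoxState(gates=gates)


def step_fox(state: FoxState, scheme: ChannelScheme, v, n_channels: int,
             dt: float, rng: np.random.Generator,
             noise_scale: float = 1.0) -> FoxState:
    """One Fox-Lu step at gating value ``v``; noise vanishes as N -> inf."""
    gates = np.empty_like(state.gates)
    for j, spec in enumerate(scheme.subunits):
        x_inf, tau_x = subunit_steady_state(spec.rates, v)
        sd = noise_scale * np.sqrt(x_inf * (1.0 - x_inf) / n_channels)
        e = np.exp(-dt / tau_x)
        gates[j] = (
            x_inf
            + (state.gates[j] - x_inf) * e
            + sd * np.sqrt(1.0 - e * e) * rng.standard_normal()
        )
    np.clip(gates, 0.0, 1.0, out=gates)
    return FoxState(gates=gates)


def fox_open_fraction(state: FoxState, scheme: ChannelScheme) -> float:
    counts = np.array([s.count for s in scheme.subunits])
    return float(np.prod(state.gates**counts))


def run_voltage_clamp_fox(scheme: ChannelScheme, v_hold: float, n_channels: int,
                          duration: float, dt: float = 0.01, seed=0,
                          burn_in: float = 0.0):
    """Voltage-clamped Fox-model open-fraction trace.

    At fixed voltage each gate is an AR(1) recursion; gates are clipped to
    [0, 1] and the open fraction is the gate product. Returns ``(t, z)``
    after burn-in.
    """
    if duration <= burn_in:
        raise ValueError("duration must exceed burn_in")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    burn_steps = int(round(burn_in / dt))
    z = np.ones(n_steps)
    for spec in scheme.subunits:
        x_inf, tau_x = subunit_steady_state(spec.rates, v_hold)
        sd = np.sqrt(x_inf * (1.0 - x_inf) / n_channels)
        gate = x_inf + simulate_ou(sd, tau_x, dt, n_steps, rng)
        np.clip(gate, 0.0, 1.0, out=gate)
        z *= gate**spec.count
    t = (1 + np.arange(n_steps)) * dt
    return t[burn_steps:], z[burn_steps:]
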