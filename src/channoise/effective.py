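"""The diffusion approximation: deterministic gates plus Ornstein-Uhlenbeck noise.

The fraction of open channels is written ``z = z_det + sum_i zeta_i`` where
``z_det`` is the deterministic gate product and the ``zeta_i`` are
independent zero-mean OU processes whose variances and time constants are
the terms of the analytic :class:`~channoise.kinetics.NoiseSpectrum` at the
instantaneous gating value. With all noise amplitudes forced to zero the
deterministic description is recovered exactly.

The OU update used throughout is the exact exponential one
``x <- x e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) xi``: it is correct for
any dt, uniform or not. A first-order Euler variant is provided for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import scipy.signal

from .kinetics import (
    ChannelScheme,
    NoiseSpectrum,
    covariance_spectrum,
    reduce_to_single_term,
)
from .rates import subunit_steady_state

__all__ = [
    "OUProcess",
    "ou_step_exact",
    "ou_step_euler",
    "simulate_ou",
    "EffectiveChannelState",
    "init_effective_state",
    "step_effective_channels",
    "effective_open_fraction",
    "run_voltage_clamp_effective",
]


@dataclass(frozen=True)
class OUProcess:
    """One OU noise term: current sample, stationary SD and time constant (ms)."""

    value: float
    sigma: float
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def ou_step_exact(p: OUProcess, dt: float, rng: np.random.Generator) -> OUProcess:
    """Exact OU update, valid for arbitrary dt >= 0."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    e = np.exp(-dt / p.tau)
    value = p.value * e + p.sigma * np.sqrt(1.0 - e * e) * rng.standard_normal()
    return replace(p, value=float(value))


def ou_step_euler(p: OUProcess, dt: float, rng: np.random.Generator) -> OUProcess:
    """First-order (Euler-Maruyama) OU update; requires dt << tau.

    Agrees with the exact update to O(dt^2) in distribution; warns when
    dt > 0.1 tau.
    """
    if dt > 0.1 * p.tau:
        warnings.warn(
            f"ou_step_euler: dt={dt} > 0.1*tau={0.1 * p.tau}; "
            "the first-order update is biased at this step size",
            stacklevel=2,
        )
    value = (
        p.value * (1.0 - dt / p.tau)
        + p.sigma * np.sqrt(2.0 * dt / p.tau) * rng.standard_normal()
    )
    return replace(p, value=float(value))


def simulate_ou(sigma: float, tau: float, dt: float, n_steps: int,
                rng: np.random.Generator, x0: Optional[float] = None,
                update: str = "exact") -> np.ndarray:
    """Vectorized OU trajectory (AR(1) recursion via lfilter).

    ``x0=None`` draws the initial value from the stationary law.
    """
    if x0 is None:
        x0 = sigma * rng.standard_normal()
    if update == "exact":
        a = np.exp(-dt / tau)
        b = sigma * np.sqrt(1.0 - a * a)
    elif update == "euler":
        a = 1.0 - dt / tau
        b = sigma * np.sqrt(2.0 * dt / tau)
    else:
        raise ValueError(f"unknown update {update!r}")
    eps = rng.standard_normal(n_steps)
    out, _ = scipy.signal.lfilter([1.0], [1.0, -a], b * eps, zi=[a * x0])
    return out


@dataclass
class EffectiveChannelState:
    """Deterministic gate values plus the OU noise terms of one population."""

    gates: np.ndarray  # one value in [0,1] per subunit type
    noise_terms: list  # list[OUProcess], canonical spectrum order

    def z_det(self, scheme: ChannelScheme) -> float:
        """Deterministic open fraction: the gate product."""
        return _gate_product(self.gates, scheme)


def _gate_product(gates: np.ndarray, scheme: ChannelScheme) -> float:
    counts = np.array([s.count for s in scheme.subunits])
    return float(np.prod(np.asarray(gates) ** counts))


def init_effective_state(scheme: ChannelScheme, v, n_channels: int,
                         rng: Optional[np.random.Generator] = None,
                         stationary_noise: bool = True) -> EffectiveChannelState:
    """Gates at steady state; OU terms at 0 or drawn from their stationary law."""
    stats = [subunit_steady_state(s.rates, v) for s in scheme.subunits]
    gates = np.array([s[0] for s in stats])
    spec = covariance_spectrum(scheme, v, n_channels)
    terms = []
    for s2, tau in spec.terms:
        sd = float(np.sqrt(s2))
        val = sd * rng.standard_normal() if (stationary_noise and rng is not None) else 0.0
        terms.append(OUProcess(value=float(val), sigma=sd, tau=tau))
    return EffectiveChannelState(gates=gates, noise_terms=terms)


def step_effective_channels(state: EffectiveChannelState, scheme: ChannelScheme,
                            v, n_channels: int, dt: float,
                            rng: np.random.Generator,
                            noise_scale: float = 1.0) -> EffectiveChannelState:
    """One step of the effective model at gating value ``v``.

    Deterministic gates advance by the exponential (Rush-Larsen) update,
    exact for frozen voltage; each OU term's (sigma_i, tau_i) is recomputed
    from the covariance spectrum at ``v`` (the slow-gating assumption) and
    then stepped exactly. ``noise_scale=0`` freezes all noise at zero and
    the trajectory is exactly the deterministic model.
    """
    gates = np.empty_like(state.gates)
    for j, spec in enumerate(scheme.subunits):
        x_inf, tau_x = subunit_steady_state(spec.rates, v)
        gates[j] = x_inf + (state.gates[j] - x_inf) * np.exp(-dt / tau_x)
    spec = covariance_spectrum(scheme, v, n_channels)
    if len(spec) != len(state.noise_terms):
        raise ValueError(
            "noise-term count changed between steps; spectrum is degenerate at this v"
        )
    terms = []
    for p, (s2, tau) in zip(state.noise_terms, spec.terms):
        p = replace(p, sigma=noise_scale * float(np.sqrt(s2)), tau=tau)
        terms.append(ou_step_exact(p, dt, rng))
    return EffectiveChannelState(gates=gates, noise_terms=terms)


def effective_open_fraction(state: EffectiveChannelState, scheme: ChannelScheme,
                            clip: bool = True) -> float:
    """z = gate product + sum of OU terms, optionally clipped to [0, 1].

    Clipping applies to the returned value only; the state variables are
    never modified, preserving the OU statistics.
    """
    z = _gate_product(state.gates, scheme) + sum(p.value for p in state.noise_terms)
    if clip:
        z = min(max(z, 0.0), 1.0)
    return float(z)


def run_voltage_clamp_effective(scheme: ChannelScheme, v_hold: float,
                                n_channels: int, duration: float,
                                dt: float = 0.01, seed=0, burn_in: float = 0.0,
                                clip: bool = False,
                                reduced: Optional[str] = None):
    """Voltage-clamped effective-model open-fraction trace.

    At fixed voltage the OU coefficients are constant, so each term is an
    AR(1) recursion simulated in vectorized form. ``reduced`` ("taylor" or
    "best_fit") replaces the multi-term spectrum by its single-term
    reduction. Returns ``(t, z)`` after burn-in.
    """
    if duration <= burn_in:
        raise ValueError("duration must exceed burn_in")
    rng = np.random.default_rng(seed)
    spec = covariance_spectrum(scheme, v_hold, n_channels)
    if reduced is not None:
        s2, tau = reduce_to_single_term(spec, method=reduced)
        terms = [(s2, tau)]
    else:
        terms = spec.terms
    n_steps = int(round(duration / dt))
    burn_steps = int(round(burn_in / dt))
    z = np.full(n_steps, spec.p_open)  # gates start (and stay) at steady state
    for s2, tau in terms:
        z += simulate_ou(np.sqrt(s2), tau, dt, n_steps, rng)
    if clip:
        np.clip(z, 0.0, 1.0, out=z)
    t = (1 + np.arange(n_steps)) * dt
    return t[burn_steps:], z[burn_steps:]
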