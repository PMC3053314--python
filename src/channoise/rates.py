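"""Voltage-dependent transition-rate laws for Markov channel gating.

Rates are expressed per millisecond as functions of the gating variable
(membrane potential in mV for the fixtures shipped here, but any scalar
gating quantity — e.g. a ligand concentration — can be used). The classic
Hodgkin-Huxley rate expressions contain removable 0/0 singularities of the
form ``a*x / (1 - exp(-x/b))``; these are evaluated by a guarded series
expansion near the singular point so that rates are finite everywhere on
the declared domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DegenerateKineticsError, InvalidRateError

__all__ = [
    "RatePair",
    "exp_linear_rate",
    "exponential_rate",
    "sigmoid_rate",
    "constant_rate",
    "subunit_steady_state",
    "HH_RATES",
]


def exp_linear_rate(a: float, b: float, v0: float) -> Callable:
    """Rate law ``a*(v - v0) / (1 - exp(-(v - v0)/b))``.

    The singularity at ``v = v0`` is removable with limit ``a*b``; near the
    singular point the expression is replaced by its Taylor series
    ``a*(b + x/2 + x^2/(12 b) - x^4/(720 b^3))`` with ``x = v - v0``.
    """

    def rate(v):
        v = np.asarray(v, dtype=float)
        x = v - v0
        small = np.abs(x / b) < 1e-4
        xs = np.where(small, b, x)  # dummy value in the masked branch
        with np.errstate(over="ignore"):
            direct = a * xs / -np.expm1(-xs / b)
        series = a * (b + x / 2.0 + x * x / (12.0 * b))
        out = np.where(small, series, direct)
        return out if out.ndim else float(out)

    rate.law = ("exp_linear", {"a": a, "b": b, "v0": v0})
    return rate


def exponential_rate(a: float, b: float, v0: float) -> Callable:
    """Rate law ``a * exp((v - v0)/b)`` (``b`` may be negative)."""

    def rate(v):
        v = np.asarray(v, dtype=float)
        out = a * np.exp((v - v0) / b)
        return out if out.ndim else float(out)

    rate.law = ("exponential", {"a": a, "b": b, "v0": v0})
    return rate


def sigmoid_rate(a: float, b: float, v0: float) -> Callable:
    """Rate law ``a / (1 + exp(-(v - v0)/b))``."""

    def rate(v):
        v = np.asarray(v, dtype=float)
        out = a / (1.0 + np.exp(-(v - v0) / b))
        return out if out.ndim else float(out)

    rate.law = ("sigmoid", {"a": a, "b": b, "v0": v0})
    return rate


def constant_rate(a: float) -> Callable:
    """Voltage-independent rate."""

    def rate(v):
        v = np.asarray(v, dtype=float)
        out = np.full_like(v, a, dtype=float)
        return out if out.ndim else float(out)

    rate.law = ("constant", {"a": a})
    return rate


@dataclass(frozen=True)
class RatePair:
    """Forward (closed->open) and backward (open->closed) rates of a 2-state gate.

    Both are callables of the gating variable, returning rates per ms.
    """

    alpha: Callable = field(repr=False)
    beta: Callable = field(repr=False)

    def __call__(self, v):
        a = self.alpha(v)
        b = self.beta(v)
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise InvalidRateError(f"non-finite rate at v={v!r}")
        if np.any(np.asarray(a) < 0) or np.any(np.asarray(b) < 0):
            raise InvalidRateError(f"negative rate at v={v!r}")
        return a, b


def subunit_steady_state(rates: RatePair, v) -> tuple:
    """Steady-state open probability and relaxation time of a 2-state gate.

    Returns ``(x_inf, tau)`` with ``x_inf = alpha/(alpha+beta)`` and
    ``tau = 1/(alpha+beta)`` (ms).

    Raises
    ------
    DegenerateKineticsError
        If ``alpha + beta == 0`` (no stationary relaxation).
    """
    a, b = rates(v)
    total = np.asarray(a) + np.asarray(b)
    if np.any(total == 0):
        raise DegenerateKineticsError(
            f"alpha + beta = 0 at v={v!r}: no stationary relaxation"
        )
    x_inf = np.asarray(a) / total
    tau = 1.0 / total
    if x_inf.ndim == 0:
        return float(x_inf), float(tau)
    return x_inf, tau


# Canonical squid-axon rate laws (modern voltage convention, rest near -65 mV).
HH_RATES = {
    "m": RatePair(
        alpha=exp_linear_rate(0.1, 10.0, -40.0),
        beta=exponential_rate(4.0, -18.0, -65.0),
    ),
    "h": RatePair(
        alpha=exponential_rate(0.07, -20.0, -65.0),
        beta=sigmoid_rate(1.0, 10.0, -35.0),
    ),
    "n": RatePair(
        alpha=exp_linear_rate(0.01, 10.0, -55.0),
        beta=exponential_rate(0.125, -80.0, -65.0),
    ),
}
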