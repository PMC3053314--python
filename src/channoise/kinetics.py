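"""Markov kinetic schemes and the analytic statistics of the open fraction.

A channel scheme is either *composed* — built from independent 2-state
subunits (the familiar m^3 h and n^4 structures) — or *general*, given by an
explicit M-state transition-rate matrix with a single conducting state.

For a population of N identical, independent channels clamped at a fixed
gating value, the fraction of open channels is binomial with mean ``p_open``
and stationary autocovariance a weighted sum of M-1 decaying exponentials.
This module derives that sum — the :class:`NoiseSpectrum` ``{sigma_i^2,
tau_i}`` — analytically, either by binomial expansion of the subunit product
(composed path) or by spectral decomposition of the rate matrix (general
path). The spectrum is what the diffusion approximation feeds with
Ornstein-Uhlenbeck processes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .errors import (
    DefectiveSchemeError,
    InvalidRateError,
    NonErgodicSchemeError,
    OscillatorySchemeError,
)
from .rates import RatePair, subunit_steady_state

__all__ = [
    "SubunitSpec",
    "ChannelScheme",
    "NoiseSpectrum",
    "transition_matrix",
    "stationary_distribution",
    "covariance_spectrum",
    "covariance_spectrum_composed",
    "covariance_spectrum_general",
    "reduce_to_single_term",
]

#: relative threshold below which spectrum terms are pruned
PRUNE_REL = 1e-15


@dataclass(frozen=True)
class SubunitSpec:
    """One subunit type: a 2-state gate repeated ``count`` times per channel."""

    name: str
    count: int
    rates: RatePair

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"subunit {self.name!r}: count must be >= 1")


@dataclass(frozen=True)
class ChannelScheme:
    """An M-state Markov single-channel model with one conducting state.

    Either ``subunits`` is given (composed scheme: states are the tuples of
    per-subunit open-gate counts, conducting state = all gates open), or
    ``states``/``rate_builder``/``open_state`` describe a general scheme.
    ``rate_builder(v)`` must return an M x M matrix with ``A[i, j]`` the rate
    of the j -> i transition (off-diagonal, per ms) and columns summing to
    zero.
    """

    name: str
    subunits: Optional[tuple] = None
    states: Optional[tuple] = None
    rate_builder: Optional[Callable] = field(default=None, repr=False)
    open_state: Optional[int] = None

    @classmethod
    def from_subunits(cls, name: str, subunits: Sequence[SubunitSpec]) -> "ChannelScheme":
        return cls(name=name, subunits=tuple(subunits))

    @classmethod
    def from_rate_matrix(cls, name, states, rate_builder, open_state) -> "ChannelScheme":
        states = tuple(states)
        if not 0 <= open_state < len(states):
            raise ValueError("open_state out of range")
        return cls(name=name, states=states, rate_builder=rate_builder,
                   open_state=open_state)

    @property
    def is_composed(self) -> bool:
        return self.subunits is not None

    @property
    def n_states(self) -> int:
        if self.is_composed:
            return int(np.prod([s.count + 1 for s in self.subunits]))
        return len(self.states)

    @property
    def conducting_index(self) -> int:
        if self.is_composed:
            return self.n_states - 1  # all-gates-open is last in our ordering
        return self.open_state

    def state_labels(self) -> tuple:
        if self.is_composed:
            labels = []
            for combo in self._state_tuples():
                labels.append(
                    "".join(f"{s.name}{i}" for s, i in zip(self.subunits, combo))
                )
            return tuple(labels)
        return self.states

    def _state_tuples(self):
        """Aggregated states of a composed scheme: tuples of open-gate counts,
        ordered lexicographically with the last subunit varying fastest and the
        all-open state last."""
        ranges = [range(s.count + 1) for s in self.subunits]
        return list(itertools.product(*ranges))

    def to_general(self) -> "ChannelScheme":
        """Express a composed scheme as its aggregated M-state general form.

        Lumping the independent identical gates by open-gate count is exact:
        a state with i of k gates open leaves at rate ``(k-i)*alpha`` upward
        and ``i*beta`` downward per subunit type.
        """
        if not self.is_composed:
            return self
        subunits = self.subunits
        tuples = self._state_tuples()
        index = {t: i for i, t in enumerate(tuples)}
        m = len(tuples)

        def build(v, _subunits=subunits, _tuples=tuples, _index=index, _m=m):
            a = np.zeros((_m, _m))
            rates = [s.rates(v) for s in _subunits]
            for t in _tuples:
                j = _index[t]
                for jj, (spec, (al, be)) in enumerate(zip(_subunits, rates)):
                    i_open = t[jj]
                    if i_open < spec.count:  # one more gate opens
                        up = list(t)
                        up[jj] += 1
                        a[_index[tuple(up)], j] += (spec.count - i_open) * al
                    if i_open > 0:  # one gate closes
                        dn = list(t)
                        dn[jj] -= 1
                        a[_index[tuple(dn)], j] += i_open * be
            np.fill_diagonal(a, 0.0)
            np.fill_diagonal(a, -a.sum(axis=0))
            return a

        open_idx = index[tuple(s.count for s in subunits)]
        return ChannelScheme.from_rate_matrix(
            f"{self.name}(general)", self.state_labels(), build, open_idx
        )


def transition_matrix(scheme: ChannelScheme, v) -> np.ndarray:
    """M x M transition-rate matrix A at gating value ``v`` (per ms).

    ``A[i, j]`` is the j -> i rate for i != j; diagonals make columns sum to
    zero (probability conservation). Raises :class:`InvalidRateError` on
    negative off-diagonal entries.
    """
    if scheme.is_composed:
        a = scheme.to_general().rate_builder(v)
    else:
        a = np.array(scheme.rate_builder(v), dtype=float)
        if a.shape != (scheme.n_states, scheme.n_states):
            raise InvalidRateError(
                f"rate builder returned shape {a.shape}, expected "
                f"({scheme.n_states}, {scheme.n_states})"
            )
    off = a - np.diag(np.diag(a))
    if np.any(off < 0) or not np.all(np.isfinite(a)):
        raise InvalidRateError(f"negative or non-finite rate in scheme {scheme.name!r} at v={v!r}")
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(a, -a.sum(axis=0))
    return a


def stationary_distribution(a: np.ndarray) -> np.ndarray:
    """Stationary occupancy probabilities: the normalized null vector of A.

    Raises :class:`NonErgodicSchemeError` when the null space has dimension
    greater than one (no unique stationary distribution).
    """
    ns = scipy.linalg.null_space(a, rcond=1e-10)
    if ns.shape[1] != 1:
        raise NonErgodicSchemeError(
            f"rate matrix null space has dimension {ns.shape[1]}, expected 1"
        )
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-9):
        raise NonErgodicSchemeError("stationary vector has negative entries")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


@dataclass(frozen=True)
class NoiseSpectrum:
    """Open-fraction autocovariance as a weighted sum of exponentials.

    ``C(t) = sum_i sigma_sq[i] * exp(-t / tau[i])`` for a population of
    ``n_channels`` channels clamped at one gating value. Terms are stored in
    canonical order: descending tau, ties broken by descending sigma_sq.
    ``sum(sigma_sq) == p_open (1 - p_open) / N`` (binomial total variance).
    """

    sigma_sq: np.ndarray
    tau: np.ndarray
    n_channels: int
    p_open: float

    def __post_init__(self):
        object.__setattr__(self, "sigma_sq", np.asarray(self.sigma_sq, dtype=float))
        object.__setattr__(self, "tau", np.asarray(self.tau, dtype=float))
        if np.any(self.sigma_sq < 0):
            raise ValueError("sigma_sq entries must be >= 0")
        if np.any(self.tau <= 0):
            raise ValueError("tau entries must be > 0")

    def __len__(self):
        return self.sigma_sq.size

    @property
    def terms(self):
        return list(zip(self.sigma_sq.tolist(), self.tau.tolist()))

    @property
    def total_variance(self) -> float:
        return float(self.sigma_sq.sum())

    def autocovariance(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.sigma_sq[:, None] * np.exp(-t[None, :] / self.tau[:, None])).sum(axis=0)


def _canonical(sigma_sq, tau, n_channels, p_open) -> NoiseSpectrum:
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    tau = np.asarray(tau, dtype=float)
    total = sigma_sq.sum()
    if total > 0:
        keep = sigma_sq >= PRUNE_REL * total
        sigma_sq, tau = sigma_sq[keep], tau[keep]
    order = np.lexsort((-sigma_sq, -tau))
    return NoiseSpectrum(sigma_sq[order], tau[order], n_channels, float(p_open))


def covariance_spectrum_composed(scheme: ChannelScheme, v, n_channels: int) -> NoiseSpectrum:
    """Noise spectrum of a subunit-composed scheme by binomial expansion.

    For independent subunits the single-channel open-state autocovariance is
    the product over subunit types of
    ``(x_inf^2 + x_inf (1 - x_inf) e^{-t/tau_x})^count`` minus the constant
    ``prod x_inf^{2 count}``; expanding the powers yields one term per
    non-zero exponent combination, with time constant the harmonic
    combination ``1 / sum_j i_j / tau_j``. Dividing by N gives the
    population spectrum. m^3 h yields 7 terms; n^4 yields 4.
    """
    if not scheme.is_composed:
        raise ValueError("covariance_spectrum_composed requires a composed scheme")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    stats = [subunit_steady_state(s.rates, v) for s in scheme.subunits]
    x_inf = np.array([s[0] for s in stats])
    tau_x = np.array([s[1] for s in stats])
    counts = np.array([s.count for s in scheme.subunits])
    p_open = float(np.prod(x_inf**counts))

    sigma_sq, tau = [], []
    for combo in itertools.product(*(range(c + 1) for c in counts)):
        if all(i == 0 for i in combo):
            continue
        coeff = 1.0
        inv_tau = 0.0
        for i, (k, x, t) in zip(combo, zip(counts, x_inf, tau_x)):
            coeff *= math.comb(int(k), i) * x ** (2 * (k - i)) * (x * (1.0 - x)) ** i
            inv_tau += i / t
        sigma_sq.append(coeff / n_channels)
        tau.append(1.0 / inv_tau)
    return _canonical(sigma_sq, tau, n_channels, p_open)


def covariance_spectrum_general(scheme: ChannelScheme, v, n_channels: int,
                                imag_tol: float = 1e-9) -> NoiseSpectrum:
    """Noise spectrum of a general M-state scheme by spectral decomposition.

    With ``A = V diag(lambda) V^{-1}``, the single-channel open-state
    autocovariance is ``p_k * sum_{lambda != 0} V[k,i] V^{-1}[i,k]
    e^{lambda_i t}``; time constants are ``1/|lambda_i|`` and the weights,
    scaled by 1/N, are the ``sigma_i^2``. Weights sharing a time constant
    (degenerate eigenvalues) are merged.

    Raises :class:`OscillatorySchemeError` for eigenvalues with a non-real
    part and :class:`DefectiveSchemeError` for non-diagonalizable matrices.
    """
    if scheme.is_composed:
        scheme = scheme.to_general()
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    a = transition_matrix(scheme, v)
    k = scheme.conducting_index
    p = stationary_distribution(a)
    p_open = float(p[k])

    lam, vec = scipy.linalg.eig(a)
    scale = np.abs(lam).max()
    if scale == 0:
        raise NonErgodicSchemeError("zero rate matrix")
    if np.any(np.abs(lam.imag) > imag_tol * scale):
        raise OscillatorySchemeError(
            f"scheme {scheme.name!r} has complex eigenvalues at v={v!r}; "
            "its autocovariance is not a sum of real decaying exponentials"
        )
    if np.linalg.cond(vec) > 1e10:
        raise DefectiveSchemeError(
            f"scheme {scheme.name!r} rate matrix is (numerically) defective at v={v!r}"
        )
    vinv = scipy.linalg.inv(vec)
    lam = lam.real
    weights = (vec[k, :] * vinv[:, k]).real * p_open / n_channels

    nonzero = np.abs(lam) > 1e-12 * scale
    lam, weights = lam[nonzero], weights[nonzero]
    taus = 1.0 / np.abs(lam)

    # merge degenerate eigenvalues
    order = np.argsort(-taus)
    taus, weights = taus[order], weights[order]
    merged_tau, merged_w = [], []
    for t, w in zip(taus, weights):
        if merged_tau and abs(t - merged_tau[-1]) <= 1e-9 * merged_tau[-1]:
            merged_w[-1] += w
        else:
            merged_tau.append(t)
            merged_w.append(w)
    merged_w = np.clip(np.array(merged_w), 0.0, None)  # numerical dust only
    return _canonical(merged_w, merged_tau, n_channels, p_open)


def covariance_spectrum(scheme: ChannelScheme, v, n_channels: int) -> NoiseSpectrum:
    """Dispatch to the composed or general covariance path."""
    if scheme.is_composed:
        return covariance_spectrum_composed(scheme, v, n_channels)
    return covariance_spectrum_general(scheme, v, n_channels)


def reduce_to_single_term(spectrum: NoiseSpectrum, method: str = "taylor",
                          fit_grid: Optional[np.ndarray] = None) -> tuple:
    """Collapse a multi-exponential spectrum to a single ``(sigma_sq, tau)``.

    ``taylor``: match the value and first derivative of the summed
    autocovariance at lag 0 — ``sigma_sq = sum sigma_i^2`` and
    ``tau = sum sigma_i^2 / sum(sigma_i^2 / tau_i)``.

    ``best_fit``: keep ``sigma_sq = sum sigma_i^2`` (exact lag-0 variance)
    and choose tau by least squares of ``sigma_sq e^{-t/tau}`` against the
    full sum on ``fit_grid`` (default: 200 lags up to 5x the slowest tau).
    """
    if len(spectrum) == 0:
        raise ValueError("empty noise spectrum")
    s2 = spectrum.total_variance
    if method == "taylor":
        tau = s2 / float((spectrum.sigma_sq / spectrum.tau).sum())
        return s2, tau
    if method == "best_fit":
        if fit_grid is None:
            fit_grid = np.linspace(0.0, 5.0 * spectrum.tau.max(), 200)
        fit_grid = np.asarray(fit_grid, dtype=float)
        target = spectrum.autocovariance(fit_grid)

        def loss(tau):
            return float(((s2 * np.exp(-fit_grid / tau) - target) ** 2).sum())

        res = scipy.optimize.minimize_scalar(
            loss, bounds=(spectrum.tau.min() / 10.0, spectrum.tau.max() * 10.0),
            method="bounded",
        )
        return s2, float(res.x)
    raise ValueError(f"unknown reduction method {method!r}")
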