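"""Exact Monte-Carlo simulation of finite channel populations.

Rather than tracking individual channels, the number of channels occupying
each state of the kinetic scheme is tracked and updated every time step with
multinomial transition draws — statistically identical for independent
channels and far cheaper. Channel count is conserved exactly at every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import StepSizeError
from .kinetics import ChannelScheme, stationary_distribution, transition_matrix

__all__ = [
    "ChannelPopulation",
    "PopulationState",
    "step_population",
    "open_fraction",
    "sample_stationary_counts",
    "run_voltage_clamp_micro",
]


@dataclass(frozen=True)
class ChannelPopulation:
    """N identical channels of one scheme with single-channel conductance
    ``gamma`` (pS) and reversal potential ``e_rev`` (mV)."""

    scheme: ChannelScheme
    n_channels: int
    gamma: float = 10.0
    e_rev: float = 0.0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    @classmethod
    def from_density(cls, scheme, density_per_um2, area_um2, gamma=10.0, e_rev=0.0):
        """N = round(density x area), round-half-to-even for determinism."""
        n = int(round(density_per_um2 * area_um2))
        return cls(scheme=scheme, n_channels=max(n, 1), gamma=gamma, e_rev=e_rev)

    def g_max_ms_cm2(self, area_um2: float) -> float:
        """Maximal specific conductance gamma*N/area in mS/cm^2."""
        # pS/um^2 = 1e-12 S / 1e-8 cm^2 = 1e-4 S/cm^2 = 0.1 mS/cm^2
        return 0.1 * self.gamma * self.n_channels / area_um2


@dataclass
class PopulationState:
    """Integer occupancy of every scheme state; sums to n_channels."""

    counts: np.ndarray
    n_channels: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0) or self.counts.sum() != self.n_channels:
            raise ValueError("counts must be >= 0 and sum to n_channels")


def sample_stationary_counts(scheme: ChannelScheme, v, n_channels: int,
                             rng: np.random.Generator) -> PopulationState:
    """Initial occupancy drawn multinomially from the stationary distribution."""
    p = stationary_distribution(transition_matrix(scheme, v))
    counts = rng.multinomial(n_channels, p)
    return PopulationState(counts=counts, n_channels=n_channels)


def step_population(state: PopulationState, a: np.ndarray, dt: float,
                    rng: np.random.Generator) -> PopulationState:
    """Advance all channels one step of size ``dt`` under rate matrix ``a``.

    Each channel in state s moves to state s' with probability
    ``a[s', s] * dt``; the number of movers is drawn multinomially per source
    state, so the total channel count is conserved exactly.

    Raises
    ------
    StepSizeError
        If some state's total exit probability ``>= 1`` at this dt (the
        error names the offending state).
    """
    m = state.counts.size
    exit_prob = -np.diag(a) * dt
    if np.any(exit_prob >= 1.0):
        s = int(np.argmax(exit_prob))
        raise StepSizeError(
            f"total exit probability {exit_prob[s]:.3f} >= 1 for state {s} "
            f"at dt={dt}; reduce dt"
        )
    # move probabilities with the stay probability in the trailing slot
    p_ext = np.empty((m, m + 1))
    p_ext[:, :m] = a.T * dt
    np.fill_diagonal(p_ext[:, :m], 0.0)
    p_ext[:, m] = 1.0 - p_ext[:, :m].sum(axis=1)
    transfers = rng.multinomial(state.counts, p_ext)
    new_counts = transfers[:, :m].sum(axis=0) + transfers[:, m]
    return PopulationState(counts=new_counts, n_channels=state.n_channels)


def open_fraction(state: PopulationState, scheme: ChannelScheme) -> float:
    """Fraction of channels in the conducting state."""
    return float(state.counts[scheme.conducting_index]) / state.n_channels


def run_voltage_clamp_micro(pop: ChannelPopulation, v_hold: float,
                            duration: float, dt: float = 0.01,
                            seed=0, burn_in: float = 0.0):
    """Voltage-clamped microscopic simulation of the open fraction.

    The initial occupancy is drawn from the stationary distribution at
    ``v_hold``; the first ``burn_in`` ms are discarded. Returns
    ``(t, z)`` with one post-burn-in sample of the open fraction per dt.
    Results are reproducible bit-for-bit for a given seed.
    """
    if duration <= burn_in:
        raise ValueError("duration must exceed burn_in")
    rng = np.random.default_rng(seed)
    kernel_seed = int(np.random.SeedSequence(seed).generate_state(1, np.uint32)[0] % (2**31))
    state0 = sample_stationary_counts(pop.scheme, v_hold, pop.n_channels, rng)

    table = _kernels.RateTable()
    packed = _kernels.PackedMicro([pop], table)
    tbl = table.build()
    # fixed voltage: per-transition probabilities are constants
    rates = np.array([
        _kernels._rate.py_func(tbl, int(r), float(v_hold), table.v_min, table.dv, table.n_v)
        for r in packed.tr_row
    ]) if len(packed.tr_row) else np.empty(0)
    p_tr = packed.tr_mult * rates * dt

    n_steps = int(round(duration / dt))
    burn_steps = int(round(burn_in / dt))
    z, _counts, err, err_info = _kernels.micro_vclamp_kernel(
        state0.counts, packed.tr_off, packed.tr_to, p_tr,
        packed.open_idx[0], pop.n_channels, n_steps, burn_steps, kernel_seed,
    )
    if err == 1:
        raise StepSizeError(
            f"total exit probability >= 1 for state {err_info} at dt={dt}"
        )
    t = (burn_steps + 1 + np.arange(z.size)) * dt
    return t, z
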