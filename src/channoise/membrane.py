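"""Single-compartment current-balance integration and protocol execution.

The membrane obeys ``C_m dV/dt = I_ext - g_L (V - E_L) - sum_p g_p z_p (V -
E_p)`` with ``g_p = gamma_p N_p / area`` and ``z_p`` the fraction of open
channels of population p, advanced each step by the chosen backend:

- ``deterministic`` — gate products, exponential (Rush-Larsen) gate update;
- ``microscopic``  — exact Monte-Carlo occupancy counts;
- ``effective``    — deterministic gates + OU noise terms (diffusion
  approximation);
- ``reduced``      — effective with a single OU term per population;
- ``fox``          — Fox-Lu Langevin comparator.

Swapping backends changes only the channel-state update; voltage update,
stimulus handling and initial conditions are shared. Voltage is integrated
by the exponential-Euler update (exact for conductances frozen over one
step, matching the exponential updates used for gates and OU terms) with a
default dt of 0.01 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.optimize

from . import _kernels
from .errors import ConfigError, IntegrationFailureError, StepSizeError
from .kinetics import covariance_spectrum, stationary_distribution, transition_matrix
from .microscopic import ChannelPopulation
from .rates import subunit_steady_state

__all__ = [
    "MembraneParams",
    "Geometry",
    "Stimulus",
    "SimulationResult",
    "resting_potential",
    "integrate",
    "fi_curve",
    "pulse_trials",
    "reliability_trials",
    "run_protocol_suite",
    "BACKENDS",
]

BACKENDS = ("deterministic", "microscopic", "effective", "reduced", "fox")


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane constants (per-area units)."""

    c_m: float = 1.0  # uF/cm^2
    g_leak: float = 0.3  # mS/cm^2
    e_leak: float = -54.4  # mV

    def __post_init__(self):
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")
        if self.g_leak < 0:
            raise ValueError("g_leak must be >= 0")


@dataclass(frozen=True)
class Geometry:
    """Cylindrical compartment; area is the lateral surface (no end caps,
    the NEURON convention)."""

    length: float = 30.0  # um
    diameter: float = 30.0  # um

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("geometry dimensions must be > 0")

    @property
    def area_um2(self) -> float:
        return float(np.pi * self.diameter * self.length)


@dataclass(frozen=True)
class Stimulus:
    """Current stimulus waveform specification (amplitudes in uA/cm^2).

    kinds:
      ``dc``               — constant ``amplitude`` from ``onset`` for ``duration``
      ``monophasic_pulse`` — same as dc (a short rectangular pulse)
      ``biphasic_pulse``   — ``amplitude``/``duration`` then
                             ``amplitude2``/``duration2``
      ``ou_noise``         — exponentially filtered white noise with ``mean``,
                             ``sd`` and correlation time ``tau`` (ms), frozen
                             by ``stim_seed``
    """

    kind: str = "dc"
    amplitude: float = 0.0
    onset: float = 0.0
    duration: Optional[float] = None
    amplitude2: float = 0.0
    duration2: float = 0.0
    mean: float = 0.0
    sd: float = 0.0
    tau: float = 3.0
    stim_seed: int = 0

    def waveform(self, n_steps: int, dt: float) -> np.ndarray:
        t = (np.arange(n_steps) + 1) * dt
        i = np.zeros(n_steps)
        if self.kind in ("dc", "monophasic_pulse"):
            end = np.inf if self.duration is None else self.onset + self.duration
            i[(t >= self.onset) & (t < end)] = self.amplitude
        elif self.kind == "biphasic_pulse":
            e1 = self.onset + (self.duration or 0.0)
            e2 = e1 + self.duration2
            i[(t >= self.onset) & (t < e1)] = self.amplitude
            i[(t >= e1) & (t < e2)] = self.amplitude2
        elif self.kind == "ou_noise":
            from .effective import simulate_ou

            rng = np.random.default_rng(self.stim_seed)
            i = self.mean + simulate_ou(self.sd, self.tau, dt, n_steps, rng)
            if self.onset > 0:
                i[t < self.onset] = 0.0
        else:
            raise ConfigError(f"unknown stimulus kind {self.kind!r}")
        return i


@dataclass
class SimulationResult:
    """Recorded trajectory plus resolved metadata."""

    t: np.ndarray
    v: np.ndarray
    open_fractions: dict
    spike_times: np.ndarray
    metadata: dict = field(default_factory=dict)


def _gate_product_inf(pop: ChannelPopulation, v: float) -> float:
    out = 1.0
    for s in pop.scheme.subunits:
        out *= subunit_steady_state(s.rates, v)[0] ** s.count
    return out


def _open_prob_inf(pop: ChannelPopulation, v: float) -> float:
    if pop.scheme.is_composed:
        return _gate_product_inf(pop, v)
    p = stationary_distribution(transition_matrix(pop.scheme, v))
    return float(p[pop.scheme.conducting_index])


def resting_potential(membrane: MembraneParams, populations: Sequence[ChannelPopulation],
                      area_um2: float, i_hold: float = 0.0,
                      bracket=(-90.0, -40.0)) -> float:
    """Deterministic resting potential: root of the steady-state current.

    ``i_hold`` (uA/cm^2) finds the stable fixed point under a holding
    current instead of true rest."""

    def net_current(v):
        i = i_hold - membrane.g_leak * (v - membrane.e_leak)
        for pop in populations:
            i -= pop.g_max_ms_cm2(area_um2) * _open_prob_inf(pop, v) * (v - pop.e_rev)
        return i

    return float(scipy.optimize.brentq(net_current, *bracket, xtol=1e-10))


def _kernel_seed(seed_seq_or_int, index: int = 0) -> int:
    ss = (seed_seq_or_int if isinstance(seed_seq_or_int, np.random.SeedSequence)
          else np.random.SeedSequence(seed_seq_or_int))
    return int(ss.generate_state(index + 1, np.uint32)[index] % (2**31))


def integrate(membrane: MembraneParams, geometry: Geometry,
              populations: Sequence[ChannelPopulation], backend: str,
              stimulus: Stimulus, duration: float, dt: float = 0.01,
              seed=0, record_stride: int = 1, noise_scale: float = 1.0,
              clip: bool = True, v_init: Optional[float] = None,
              spike_threshold: float = 0.0,
              spike_refractory: float = 2.0) -> SimulationResult:
    """Integrate the current-balance equation with the chosen channel backend.

    Initial voltage is the deterministic resting potential (unless
    ``v_init`` is given), gates/occupancies start at the steady state there.
    Raises :class:`IntegrationFailureError` if |V| exceeds 200 mV.
    """
    from .analysis import detect_spikes

    if backend not in BACKENDS:
        raise ConfigError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    area = geometry.area_um2
    if v_init is None:
        v_init = resting_potential(membrane, populations, area)
    n_steps = int(round(duration / dt))
    i_ext = stimulus.waveform(n_steps, dt)
    gbar = np.array([p.g_max_ms_cm2(area) for p in populations])
    erev = np.array([p.e_rev for p in populations])
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    kseed = _kernel_seed(ss)

    table = _kernels.RateTable()
    if backend == "microscopic" and noise_scale == 0.0:
        backend = "deterministic"  # the N -> inf limit of the count process
    if backend == "microscopic":
        packed = _kernels.PackedMicro(populations, table)
        tbl = table.build()
        counts0 = np.concatenate([
            rng.multinomial(
                p.n_channels,
                stationary_distribution(transition_matrix(p.scheme, v_init)),
            )
            for p in populations
        ]).astype(np.int64)
        v_tr, z_tr, _counts, err, info = _kernels.micro_membrane_kernel(
            counts0, packed.state_off, packed.open_idx, packed.n_ch,
            packed.tr_off, packed.tr_to, packed.tr_row, packed.tr_mult,
            tbl, table.v_min, table.dv, table.n_v,
            gbar, erev, membrane.c_m, membrane.g_leak, membrane.e_leak,
            i_ext, dt, v_init, record_stride, kseed,
        )
        if err == 1:
            raise StepSizeError(
                f"total exit probability >= 1 for state {info} at dt={dt}"
            )
    elif backend in ("deterministic", "effective", "reduced"):
        packed = _kernels.PackedEffective(populations, table)
        tbl = table.build()
        x0 = np.concatenate([
            [subunit_steady_state(s.rates, v_init)[0] for s in p.scheme.subunits]
            for p in populations
        ])
        scale = 0.0 if backend == "deterministic" else noise_scale
        if backend == "reduced":
            zeta0 = np.zeros(len(populations))
            if scale > 0:
                from .kinetics import reduce_to_single_term

                for i, p in enumerate(populations):
                    s2, _ = reduce_to_single_term(
                        covariance_spectrum(p.scheme, v_init, p.n_channels)
                    )
                    zeta0[i] = np.sqrt(s2) * rng.standard_normal()
            v_tr, z_tr, _x, _zeta, err, info = _kernels.eff_membrane_reduced_kernel(
                x0, zeta0, packed.sub_off, packed.sub_k, packed.sub_arow,
                packed.sub_brow, packed.term_off, packed.term_binom,
                packed.expo, packed.n_ch,
                tbl, table.v_min, table.dv, table.n_v,
                gbar, erev, membrane.c_m, membrane.g_leak, membrane.e_leak,
                i_ext, dt, v_init, record_stride, scale, clip, kseed,
            )
        else:
            # stationary initial noise values, term-by-term in packing order
            zeta0 = np.zeros(packed.term_off[-1])
            if scale > 0:
                for ip, p in enumerate(populations):
                    lo, hi = packed.term_off[ip], packed.term_off[ip + 1]
                    var = _packed_term_variances(packed, ip, p, v_init)
                    zeta0[lo:hi] = np.sqrt(var) * rng.standard_normal(hi - lo)
            v_tr, z_tr, _x, _zeta, err, info = _kernels.eff_membrane_kernel(
                x0, zeta0, packed.sub_off, packed.sub_k, packed.sub_arow,
                packed.sub_brow, packed.term_off, packed.term_binom,
                packed.expo, packed.n_ch,
                tbl, table.v_min, table.dv, table.n_v,
                gbar, erev, membrane.c_m, membrane.g_leak, membrane.e_leak,
                i_ext, dt, v_init, record_stride, scale, clip, kseed,
            )
    else:  # fox
        packed = _kernels.PackedEffective(populations, table)
        tbl = table.build()
        x0 = np.concatenate([
            [subunit_steady_state(s.rates, v_init)[0] for s in p.scheme.subunits]
            for p in populations
        ])
        v_tr, z_tr, _x, err, info = _kernels.fox_membrane_kernel(
            x0, packed.sub_off, packed.sub_k, packed.sub_arow, packed.sub_brow,
            packed.n_ch,
            tbl, table.v_min, table.dv, table.n_v,
            gbar, erev, membrane.c_m, membrane.g_leak, membrane.e_leak,
            i_ext, dt, v_init, record_stride, noise_scale, kseed,
        )

    if err == 2:
        raise IntegrationFailureError(
            f"membrane potential diverged (|V| > 200 mV) at step {info}", step=int(info)
        )
    t = (np.arange(v_tr.size) + 1) * dt * record_stride
    spikes = detect_spikes(v_tr, dt * record_stride,
                           threshold=spike_threshold, refractory=spike_refractory)
    meta = {
        "backend": backend, "seed": repr(seed) if isinstance(seed, np.random.SeedSequence) else seed,
        "dt_ms": dt, "duration_ms": duration,
        "record_stride": record_stride, "noise_scale": noise_scale,
        "clip_policy": "conductance" if clip else "off",
        "v_init_mv": float(v_init), "area_um2": float(area),
        "n_channels": [int(p.n_channels) for p in populations],
        "stimulus": {"kind": stimulus.kind, "amplitude_ua_cm2": stimulus.amplitude},
    }
    zdict = {p.scheme.name: z_tr[i] for i, p in enumerate(populations)}
    return SimulationResult(t=t, v=v_tr, open_fractions=zdict,
                            spike_times=spikes, metadata=meta)


def _packed_term_variances(packed: "_kernels.PackedEffective", ip: int,
                           pop: ChannelPopulation, v: float) -> np.ndarray:
    """Term variances at voltage v, in the packing (not canonical) order."""
    stats = [subunit_steady_state(s.rates, v) for s in pop.scheme.subunits]
    lo, hi = packed.term_off[ip], packed.term_off[ip + 1]
    slo = packed.sub_off[ip]
    var = np.empty(hi - lo)
    for q in range(lo, hi):
        val = packed.term_binom[q] / pop.n_channels
        for j, (x, _tau) in enumerate(stats):
            i_e = packed.expo[q, j]
            k = packed.sub_k[slo + j]
            val *= x ** (2 * (k - i_e)) * (x * (1.0 - x)) ** i_e
        var[q - lo] = val
    return var


# ---------------------------------------------------------------------------
# protocols


def fi_curve(membrane, geometry, populations, backend, amplitudes,
             duration: float = 5000.0, n_repetitions: int = 3, dt: float = 0.01,
             seed=0, record_stride: int = 2, discard: float = 500.0):
    """Mean firing rate vs DC amplitude; per-trial seeds, rate averaged over
    repetitions. Returns dict with amplitudes, mean rates (Hz) and SDs."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(amplitudes) * n_repetitions)
    rates = np.empty((len(amplitudes), n_repetitions))
    for i, amp in enumerate(amplitudes):
        for r in range(n_repetitions):
            trial_seed = children[i * n_repetitions + r]
            res = integrate(membrane, geometry, populations, backend,
                            Stimulus(kind="dc", amplitude=float(amp)),
                            duration=duration, dt=dt, seed=trial_seed,
                            record_stride=record_stride)
            spikes = res.spike_times[res.spike_times >= discard]
            rates[i, r] = spikes.size / (duration - discard) * 1000.0
    return {
        "amplitudes": np.asarray(amplitudes, dtype=float),
        "rate_mean_hz": rates.mean(axis=1),
        "rate_sd_hz": rates.std(axis=1, ddof=1) if n_repetitions > 1 else np.zeros(len(amplitudes)),
        "rates_hz": rates,
    }


def pulse_trials(membrane, geometry, populations, backend, stimulus: Stimulus,
                 n_trials: int, duration: float, dt: float = 0.001, seed=0,
                 record_stride: int = 1):
    """Repeated identical-stimulus trials; returns a SpikeTrainSet."""
    from .analysis import SpikeTrainSet

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trials)
    trials = []
    for trial_seed in children:
        res = integrate(membrane, geometry, populations, backend, stimulus,
                        duration=duration, dt=dt, seed=trial_seed,
                        record_stride=record_stride)
        trials.append(res.spike_times)
    return SpikeTrainSet(
        trials=trials, duration=duration,
        metadata={"backend": backend, "stimulus_kind": stimulus.kind,
                  "amplitude": stimulus.amplitude, "seed": seed},
    )


def reliability_trials(membrane, geometry, populations, backend,
                       stimulus: Stimulus, n_trials: int, duration: float,
                       dt: float = 0.01, seed=0, record_stride: int = 1):
    """Frozen-stimulus repeated trials (the stimulus realisation is fixed by
    its own seed; channel noise varies per trial)."""
    return pulse_trials(membrane, geometry, populations, backend, stimulus,
                        n_trials, duration, dt=dt, seed=seed,
                        record_stride=record_stride)


def run_protocol_suite(protocol: str, config: dict) -> dict:
    """Dispatch a named protocol with a keyword-argument config."""
    if protocol == "fI_curve":
        return fi_curve(**config)
    if protocol == "pulse_trials":
        return {"trains": pulse_trials(**config)}
    if protocol == "reliability_trials":
        return {"trains": reliability_trials(**config)}
    if protocol == "voltage_clamp":
        from .microscopic import run_voltage_clamp_micro

        t, z = run_voltage_clamp_micro(**config)
        return {"t": t, "z": z}
    if protocol == "psd_recording":
        res = integrate(**config)
        return {"result": res}
    raise ConfigError(f"unknown protocol {protocol!r}")
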