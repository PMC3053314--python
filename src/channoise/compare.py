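"""Side-by-side backend comparisons for the standard experiments.

Each experiment runs the microscopic, effective and (where meaningful) Fox
backends under matched per-trial seed policies and returns a tidy summary
with pass/fail flags at documented tolerances. These are the protocols used
throughout the validation of the diffusion approximation: voltage-clamp
statistics, spontaneous firing, pulse responses, reliability, f-I curves
and subthreshold voltage spectra.
"""

from __future__ import annotations

import numpy as np
import scipy.stats

from .analysis import reliability_precision, stationary_stats, welch_psd
from .effective import run_voltage_clamp_effective
from .errors import ConfigError
from .fixtures import build_hh_fixture
from .fox import run_voltage_clamp_fox
from .kinetics import covariance_spectrum
from .membrane import Stimulus, fi_curve, integrate, reliability_trials
from .microscopic import ChannelPopulation, run_voltage_clamp_micro

__all__ = ["compare_backends", "block_sem", "block_variances",
           "analytic_se_mean", "analytic_se_variance"]

EXPERIMENTS = ("vclamp_stats", "spontaneous", "pulse_response", "reliability",
               "fi", "psd")


def block_sem(x: np.ndarray, n_blocks: int = 20):
    """Block-based mean/variance estimates with standard errors, robust to
    the autocorrelation of simulation traces."""
    n = x.size // n_blocks
    blocks = x[: n * n_blocks].reshape(n_blocks, n)
    means = blocks.mean(axis=1)
    var_blocks = blocks.var(axis=1, ddof=1)
    return (
        float(means.mean()), float(means.std(ddof=1) / np.sqrt(n_blocks)),
        float(var_blocks.mean()), float(var_blocks.std(ddof=1) / np.sqrt(n_blocks)),
    )


def block_variances(x: np.ndarray, n_blocks: int = 20) -> np.ndarray:
    n = x.size // n_blocks
    return x[: n * n_blocks].reshape(n_blocks, n).var(axis=1, ddof=1)


def analytic_se_mean(spectrum, duration_ms: float) -> float:
    """Exact standard error of the time-averaged mean of a stationary
    process with autocovariance ``sum_i s2_i e^{-t/tau_i}`` observed for
    ``duration_ms``: sqrt(2 sum_i s2_i tau_i / T)."""
    s2, tau = spectrum.sigma_sq, spectrum.tau
    return float(np.sqrt(2.0 * np.sum(s2 * tau) / duration_ms))


def analytic_se_variance(spectrum, duration_ms: float) -> float:
    """Standard error of the sample variance of the same process (Gaussian
    approximation): Var(var_hat) = (4/T) int_0^inf C(t)^2 dt."""
    s2, tau = spectrum.sigma_sq, spectrum.tau
    integral = np.sum(
        s2[:, None] * s2[None, :]
        * (tau[:, None] * tau[None, :]) / (tau[:, None] + tau[None, :])
    )
    return float(np.sqrt(4.0 * integral / duration_ms))


def _vclamp_stats(config):
    scheme_name = config.get("scheme", "k")
    fix = build_hh_fixture()
    scheme = fix.potassium if scheme_name == "k" else fix.sodium
    n = int(config.get("n_channels", 1800))
    v = float(config.get("v_hold_mv", -30.0))
    duration = float(config.get("duration_ms", 20000.0))
    seed = int(config.get("seed", 0))
    spec = covariance_spectrum(scheme, v, n)
    out = {"analytic": {"mean": spec.p_open, "variance": spec.total_variance}}
    _, z_mic = run_voltage_clamp_micro(ChannelPopulation(scheme, n), v, duration,
                                       seed=seed, burn_in=500.0)
    _, z_eff = run_voltage_clamp_effective(scheme, v, n, duration, seed=seed + 1,
                                           burn_in=500.0)
    _, z_fox = run_voltage_clamp_fox(scheme, v, n, duration, seed=seed + 2,
                                     burn_in=500.0)
    for name, z in [("microscopic", z_mic), ("effective", z_eff), ("fox", z_fox)]:
        m, sem, var, sev = block_sem(z)
        _, _, acf = stationary_stats(z, 0.01)
        out[name] = {"mean": m, "mean_se": sem, "variance": var,
                     "variance_se": sev, "acf_tau_ms": acf.tau}
    out["pass"] = {
        "micro_mean_3se": abs(out["microscopic"]["mean"] - spec.p_open)
        < 3 * out["microscopic"]["mean_se"],
        "eff_var_vs_micro_3se": abs(out["effective"]["variance"]
                                    - out["microscopic"]["variance"])
        < 3 * np.hypot(out["effective"]["variance_se"],
                       out["microscopic"]["variance_se"]),
    }
    return out


def _spontaneous(config):
    diameters = config.get("diameters_um", (1.5, 3.0))
    duration = float(config.get("duration_ms", 20000.0))
    seed = int(config.get("seed", 0))
    out = {"diameters_um": list(diameters), "rates_hz": {}}
    for backend in ("microscopic", "effective", "fox"):
        rates = []
        for d in diameters:
            fix = build_hh_fixture(length_um=10.0, diameter_um=float(d))
            res = integrate(fix.membrane, fix.geometry, fix.populations(), backend,
                            Stimulus(kind="dc", amplitude=0.0), duration,
                            seed=seed)
            rates.append(res.spike_times.size / duration * 1000.0)
        out["rates_hz"][backend] = rates
    largest = -1
    out["pass"] = {
        "fox_collapses": out["rates_hz"]["fox"][largest] == 0.0,
        "micro_eff_persist": out["rates_hz"]["microscopic"][largest] > 0
        and out["rates_hz"]["effective"][largest] > 0,
    }
    return out


def _pulse_response(config):
    from .analysis import efficacy_latency_jitter
    from .membrane import pulse_trials

    fix = build_hh_fixture(length_um=10.0, diameter_um=10.0)
    pops = fix.populations()
    amp = float(config.get("amplitude_ua_cm2", 8.0))
    n_trials = int(config.get("n_trials", 200))
    seed = int(config.get("seed", 0))
    stim = Stimulus(kind="monophasic_pulse", amplitude=amp, onset=5.0, duration=1.0)
    out = {}
    for backend in ("microscopic", "effective", "fox"):
        tr = pulse_trials(fix.membrane, fix.geometry, pops, backend, stim,
                          n_trials, 25.0, dt=0.001, seed=seed)
        r = efficacy_latency_jitter(tr, 5.0, 20.0)
        out[backend] = {"efficacy": r.efficacy, "latency_ms": r.latency_mean,
                        "jitter_ms": r.latency_sd}
    se = np.sqrt(out["microscopic"]["efficacy"]
                 * (1 - out["microscopic"]["efficacy"]) / n_trials)
    out["pass"] = {
        "micro_eff_3se": abs(out["microscopic"]["efficacy"]
                             - out["effective"]["efficacy"]) < 3 * max(se, 1e-3)
    }
    return out


def _reliability(config):
    fix = build_hh_fixture(length_um=10.0, diameter_um=10.0)
    pops = fix.populations()
    mean = float(config.get("mean_ua_cm2", 6.5))
    n_trials = int(config.get("n_trials", 20))
    duration = float(config.get("duration_ms", 1000.0))
    seed = int(config.get("seed", 0))
    stim_seed = int(config.get("stim_seed", 77))
    dc = Stimulus(kind="dc", amplitude=mean)
    ou = Stimulus(kind="ou_noise", mean=mean, sd=mean,
                  tau=float(config.get("tau_ms", 3.0)), stim_seed=stim_seed)
    out = {}
    for backend in ("microscopic", "effective"):
        row = {}
        for label, stim in [("dc", dc), ("ou", ou)]:
            tr = reliability_trials(fix.membrane, fix.geometry, pops, backend,
                                    stim, n_trials, duration, seed=seed)
            rel, prec = reliability_precision(tr)
            row[label] = {"reliability": rel, "precision_ms": prec}
        out[backend] = row
    out["pass"] = {
        f"{b}_noise_gt_dc": out[b]["ou"]["reliability"] > out[b]["dc"]["reliability"]
        for b in ("microscopic", "effective")
    }
    return out


def _fi(config):
    fix = build_hh_fixture(length_um=14.0, diameter_um=14.0)
    pops = fix.populations()
    amps = np.asarray(config.get("amplitudes_ua_cm2", (4.4, 4.7, 5.0, 5.3, 5.6)))
    seed = int(config.get("seed", 0))
    out = {"amplitudes_ua_cm2": amps.tolist()}
    for backend in ("deterministic", "microscopic", "effective"):
        res = fi_curve(fix.membrane, fix.geometry, pops, backend, amps,
                       duration=float(config.get("duration_ms", 5000.0)),
                       n_repetitions=int(config.get("n_repetitions", 10)),
                       seed=seed)
        out[backend] = {"rate_mean_hz": res["rate_mean_hz"].tolist(),
                        "rate_sd_hz": res["rate_sd_hz"].tolist()}
    mic = np.array(out["microscopic"]["rate_mean_hz"])
    eff = np.array(out["effective"]["rate_mean_hz"])
    mic_sd = np.array(out["microscopic"]["rate_sd_hz"])
    eff_sd = np.array(out["effective"]["rate_sd_hz"])
    out["pass"] = {
        "stochastic_graded": bool(np.all(np.diff(mic) > 0) and np.all(np.diff(eff) > 0)),
        "bands_overlap": bool(np.all(np.abs(mic - eff) <= mic_sd + eff_sd)),
    }
    return out


def _psd(config):
    fix = build_hh_fixture(length_um=10.0, diameter_um=10.0)
    pops = fix.populations()
    duration = float(config.get("duration_ms", 100000.0))
    seed = int(config.get("seed", 0))
    hold = float(config.get("holding_ua_cm2", 1.0))
    out = {}
    spectra = {}
    for backend in ("microscopic", "effective"):
        res = integrate(fix.membrane, fix.geometry, pops, backend,
                        Stimulus(kind="dc", amplitude=hold), duration,
                        seed=seed, record_stride=5)
        wr = welch_psd(res.v, 0.05, window_ms=1000.0,
                       spike_times=res.spike_times)
        spectra[backend] = wr
        out[backend] = {"n_segments": wr.n_segments,
                        "n_spikes": int(res.spike_times.size)}
    f, p_mic, n_mic, _ = spectra["microscopic"]
    _, p_eff, n_eff, _ = spectra["effective"]
    band = (f >= 1.0) & (f <= 1000.0)
    lo = 2 * n_mic / scipy.stats.chi2.ppf(0.975, 2 * n_mic)
    hi = 2 * n_mic / scipy.stats.chi2.ppf(0.025, 2 * n_mic)
    ratio = p_mic[band] / p_eff[band]
    frac = float(np.mean((ratio > lo * lo) & (ratio < hi * hi)))
    out["band_hz"] = [1.0, 1000.0]
    out["fraction_within_joint_ci"] = frac
    out["pass"] = {"spectra_agree": frac >= 0.95}
    return out


def compare_backends(experiment: str, config: dict | None = None) -> dict:
    """Run one named comparison experiment; see :data:`EXPERIMENTS`."""
    config = dict(config or {})
    if experiment == "vclamp_stats":
        return _vclamp_stats(config)
    if experiment == "spontaneous":
        return _spontaneous(config)
    if experiment == "pulse_response":
        return _pulse_response(config)
    if experiment == "reliability":
        return _reliability(config)
    if experiment == "fi":
        return _fi(config)
    if experiment == "psd":
        return _psd(config)
    raise ConfigError(f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}")
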