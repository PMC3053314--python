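"""Current-balance integration: equilibrium, backend equivalence, stimuli,
error handling and protocol plumbing."""

import numpy as np
import pytest

from channoise.errors import ConfigError, IntegrationFailureError
from channoise.membrane import (
    Geometry,
    MembraneParams,
    Stimulus,
    fi_curve,
    integrate,
    pulse_trials,
    resting_potential,
)


class TestGeometry:
    def test_cylinder_lateral_area(self):
        g = Geometry(length=10.0, diameter=10.0)
        assert g.area_um2 == pytest.approx(np.pi * 100.0)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            Geometry(length=0.0, diameter=10.0)


class TestStimulus:
    def test_dc_and_pulse_waveforms(self):
        dc = Stimulus(kind="dc", amplitude=2.0).waveform(100, 0.1)
        assert np.all(dc == 2.0)
        pulse = Stimulus(kind="monophasic_pulse", amplitude=5.0, onset=2.0,
                         duration=1.0).waveform(100, 0.1)
        assert pulse.sum() == pytest.approx(5.0 * 10)

    def test_biphasic_pulse_segments(self):
        s = Stimulus(kind="biphasic_pulse", amplitude=-2.0, onset=1.0,
                     duration=2.0, amplitude2=6.0, duration2=1.0)
        w = s.waveform(60, 0.1)
        assert w.min() == -2.0 and w.max() == 6.0
        assert np.sum(w == -2.0) == 20 and np.sum(w == 6.0) == 10

    def test_frozen_ou_stimulus_reproducible(self):
        s = Stimulus(kind="ou_noise", mean=3.0, sd=1.0, tau=3.0, stim_seed=9)
        w1 = s.waveform(5000, 0.01)
        w2 = s.waveform(5000, 0.01)
        assert np.array_equal(w1, w2)
        assert w1.mean() == pytest.approx(3.0, abs=0.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            Stimulus(kind="ramp").waveform(10, 0.1)


class TestIntegrate:
    def test_deterministic_rest_is_stable_and_silent(self, small_fixture):
        pops = small_fixture.populations()
        vr = resting_potential(small_fixture.membrane, pops,
                               small_fixture.geometry.area_um2)
        res = integrate(small_fixture.membrane, small_fixture.geometry, pops,
                        "deterministic", Stimulus(kind="dc", amplitude=0.0),
                        500.0, seed=0)
        assert res.spike_times.size == 0
        assert res.v[-1] == pytest.approx(vr, abs=0.01)
        assert np.abs(res.v - vr).max() < 1.0

    @pytest.mark.parametrize("backend", ["microscopic", "effective", "reduced", "fox"])
    def test_noise_off_reproduces_deterministic_trace(self, small_fixture, backend):
        """Backend-agnostic harness: with noise zeroed every stochastic
        backend follows the deterministic voltage trajectory exactly."""
        pops = small_fixture.populations()
        stim = Stimulus(kind="dc", amplitude=4.0)
        det = integrate(small_fixture.membrane, small_fixture.geometry, pops,
                        "deterministic", stim, 500.0, seed=0)
        res = integrate(small_fixture.membrane, small_fixture.geometry, pops,
                        backend, stim, 500.0, seed=0, noise_scale=0.0)
        assert np.abs(res.v - det.v).max() < 0.01

    def test_dt_halving_shifts_spikes_below_tenth_ms(self, small_fixture):
        pops = small_fixture.populations()
        stim = Stimulus(kind="dc", amplitude=8.0)
        r1 = integrate(small_fixture.membrane, small_fixture.geometry, pops,
                       "deterministic", stim, 500.0, dt=0.01)
        r2 = integrate(small_fixture.membrane, small_fixture.geometry, pops,
                       "deterministic", stim, 500.0, dt=0.005)
        assert r1.spike_times.size == r2.spike_times.size
        assert np.abs(r1.spike_times - r2.spike_times).max() < 0.1

    def test_subthreshold_dc_silent_noisy_backends_fire(self, small_fixture):
        """A DC below the deterministic repetitive-firing threshold elicits
        no deterministic spikes but sustained irregular firing with channel
        noise (either stochastic backend)."""
        pops = small_fixture.populations()
        stim = Stimulus(kind="dc", amplitude=4.0)
        vh = resting_potential(small_fixture.membrane, pops,
                               small_fixture.geometry.area_um2, i_hold=4.0)
        det = integrate(small_fixture.membrane, small_fixture.geometry, pops,
                        "deterministic", stim, 5000.0, seed=0, v_init=vh)
        assert det.spike_times.size == 0
        for backend in ("microscopic", "effective"):
            res = integrate(small_fixture.membrane, small_fixture.geometry,
                            pops, backend, stim, 5000.0, seed=1, v_init=vh)
            assert res.spike_times.size > 0

    def test_divergence_raises_with_step_index(self, small_fixture):
        pops = small_fixture.populations()
        bad = MembraneParams(c_m=1e-6, g_leak=0.0, e_leak=-54.4)
        with pytest.raises(IntegrationFailureError) as exc:
            integrate(bad, small_fixture.geometry, pops, "deterministic",
                      Stimulus(kind="dc", amplitude=100.0), 100.0, seed=0)
        assert exc.value.step is not None

    def test_unknown_backend_rejected(self, small_fixture):
        with pytest.raises(ConfigError):
            integrate(small_fixture.membrane, small_fixture.geometry,
                      small_fixture.populations(), "gillespie",
                      Stimulus(), 10.0)

    def test_stochastic_run_reproducible_from_seed(self, small_fixture):
        pops = small_fixture.populations()
        stim = Stimulus(kind="dc", amplitude=4.0)
        r1 = integrate(small_fixture.membrane, small_fixture.geometry, pops,
                       "effective", stim, 200.0, seed=7)
        r2 = integrate(small_fixture.membrane, small_fixture.geometry, pops,
                       "effective", stim, 200.0, seed=7)
        assert np.array_equal(r1.v, r2.v)

    def test_micro_vs_effective_subthreshold_voltage_power(self, small_fixture):
        """Matched total fluctuation power in the subthreshold regime
        (integrated spike-blanked Welch spectrum, so rare spontaneous spikes
        do not dominate the variance)."""
        from channoise.analysis import welch_psd

        pops = small_fixture.populations()
        stim = Stimulus(kind="dc", amplitude=1.0)
        out = {}
        for backend in ("microscopic", "effective"):
            res = integrate(small_fixture.membrane, small_fixture.geometry,
                            pops, backend, stim, 20000.0, seed=3,
                            record_stride=5)
            wr = welch_psd(res.v, 0.05, window_ms=500.0,
                           spike_times=res.spike_times)
            out[backend] = np.trapezoid(wr.psd, wr.frequencies)
        ratio = out["microscopic"] / out["effective"]
        assert 0.8 < ratio < 1.25


class TestProtocols:
    def test_run_protocol_suite_dispatch(self, small_fixture, k_scheme):
        from channoise.membrane import run_protocol_suite
        from channoise.microscopic import ChannelPopulation

        out = run_protocol_suite("voltage_clamp", {
            "pop": ChannelPopulation(k_scheme, 360), "v_hold": -40.0,
            "duration": 200.0, "seed": 1, "burn_in": 50.0,
        })
        assert out["z"].size == 15000
        with pytest.raises(ConfigError):
            run_protocol_suite("unknown", {})

    def test_fi_deterministic_onset_is_step_like(self, small_fixture):
        pops = small_fixture.populations()
        res = fi_curve(small_fixture.membrane, small_fixture.geometry, pops,
                       "deterministic", [4.0, 6.5], duration=1000.0,
                       n_repetitions=1, seed=0, discard=200.0)
        assert res["rate_mean_hz"][0] == 0.0
        assert res["rate_mean_hz"][1] > 30.0

    def test_pulse_far_above_threshold_saturates_efficacy(self, small_fixture):
        from channoise.analysis import efficacy_latency_jitter

        pops = small_fixture.populations()
        stim = Stimulus(kind="monophasic_pulse", amplitude=30.0, onset=2.0,
                        duration=1.0)
        trains = pulse_trials(small_fixture.membrane, small_fixture.geometry,
                              pops, "effective", stim, 20, 15.0, dt=0.005,
                              seed=5)
        r = efficacy_latency_jitter(trains, 2.0, 13.0)
        assert r.efficacy == 1.0
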