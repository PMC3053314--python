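"""Analytic open-fraction statistics: transition matrices, stationary laws,
covariance spectra by both derivation paths, and the single-term reduction."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from channoise.errors import (
    DefectiveSchemeError,
    NonErgodicSchemeError,
    OscillatorySchemeError,
)
from channoise.kinetics import (
    ChannelScheme,
    NoiseSpectrum,
    SubunitSpec,
    covariance_spectrum_composed,
    covariance_spectrum_general,
    reduce_to_single_term,
    stationary_distribution,
    transition_matrix,
)
from channoise.rates import RatePair, constant_rate

from .conftest import two_state_scheme


class TestTransitionMatrix:
    def test_two_state_direct_transcription(self):
        a = transition_matrix(two_state_scheme(1.0, 2.0), 0.0)
        assert np.allclose(a, [[-1.0, 2.0], [1.0, -2.0]])

    def test_n4_ladder_band_structure(self, k_scheme):
        """The aggregated n^4 chain is a 5-state ladder with super-diagonal
        4b,3b,2b,b and sub-diagonal a,2a,3a,4a."""
        v = -40.0
        al, be = k_scheme.subunits[0].rates(v)
        a = transition_matrix(k_scheme, v)
        assert a.shape == (5, 5)
        expected = np.zeros((5, 5))
        for i in range(4):
            expected[i + 1, i] = (4 - i) * al  # one more gate opens
            expected[i, i + 1] = (i + 1) * be  # one gate closes
        np.fill_diagonal(expected, -expected.sum(axis=0))
        assert np.allclose(a, expected)

    @pytest.mark.parametrize("v", [-80.0, -55.0, -40.0, -20.0, 20.0])
    def test_columns_conserve_probability(self, na_scheme, k_scheme, v):
        for scheme in (na_scheme, k_scheme):
            a = transition_matrix(scheme, v)
            assert np.max(np.abs(a.sum(axis=0))) < 1e-13


class TestStationaryDistribution:
    def test_two_state_closed_form(self):
        a = transition_matrix(two_state_scheme(1.0, 3.0), 0.0)
        assert np.allclose(stationary_distribution(a), [0.75, 0.25])

    def test_n4_conducting_mass_at_half_activation(self):
        scheme = ChannelScheme.from_subunits(
            "n4", [SubunitSpec("n", 4, RatePair(constant_rate(1.0), constant_rate(1.0)))]
        )
        p = stationary_distribution(transition_matrix(scheme, 0.0))
        assert p[scheme.conducting_index] == pytest.approx(0.5**4)

    @pytest.mark.parametrize("v", [-70.0, -40.0, -10.0])
    def test_matches_long_time_propagation(self, na_scheme, v):
        """Independent oracle: e^{At} P(0) for large t."""
        a = transition_matrix(na_scheme, v)
        p = stationary_distribution(a)
        p0 = np.zeros(a.shape[0])
        p0[0] = 1.0
        p_long = scipy.linalg.expm(a * 2000.0) @ p0
        assert np.allclose(p, p_long, atol=1e-9)
        assert a @ p == pytest.approx(np.zeros_like(p), abs=1e-10)

    def test_disconnected_scheme_rejected(self):
        a = np.zeros((4, 4))
        a[1, 0] = a[0, 1] = 1.0
        a[3, 2] = a[2, 3] = 1.0
        np.fill_diagonal(a, -a.sum(axis=0))
        with pytest.raises(NonErgodicSchemeError):
            stationary_distribution(a)


class TestCovarianceSpectrumComposed:
    def test_frozen_n4_example(self):
        """n^4 with n_inf = 1/2, tau_n = 1 ms, N = 100: the four-term
        binomial expansion, verified against direct numeric evaluation of
        the subunit-product autocovariance on a time grid."""
        scheme = ChannelScheme.from_subunits(
            "n4", [SubunitSpec("n", 4, RatePair(constant_rate(0.5), constant_rate(0.5)))]
        )
        spec = covariance_spectrum_composed(scheme, 0.0, 100)
        expected = [
            (1.5625e-4, 1.0),
            (2.34375e-4, 0.5),
            (1.5625e-4, 1.0 / 3.0),
            (3.90625e-5, 0.25),
        ]
        assert len(spec) == 4
        for (s2, tau), (es2, etau) in zip(spec.terms, expected):
            assert s2 == pytest.approx(es2, rel=1e-12)
            assert tau == pytest.approx(etau, rel=1e-12)
        assert spec.total_variance == pytest.approx(0.0625 * (1 - 0.0625) / 100, rel=1e-12)
        # numeric oracle: C(t) = (x^2 + x(1-x) e^{-t})^4 - x^8, x = 1/2
        t = np.linspace(0.0, 5.0, 50)
        direct = ((0.25 + 0.25 * np.exp(-t)) ** 4 - 0.5**8) / 100
        assert np.allclose(spec.autocovariance(t), direct, rtol=1e-12)

    def test_term_counts_na7_k4(self, na_scheme, k_scheme):
        assert len(covariance_spectrum_composed(na_scheme, -40.0, 1000)) == 7
        assert len(covariance_spectrum_composed(k_scheme, -40.0, 1000)) == 4

    def test_k_time_constants_are_submultiples(self, k_scheme):
        spec = covariance_spectrum_composed(k_scheme, -35.0, 1000)
        tau_n = 1.0 / sum(k_scheme.subunits[0].rates(-35.0))
        assert spec.tau == pytest.approx([tau_n, tau_n / 2, tau_n / 3, tau_n / 4])

    def test_single_subunit_recovers_two_state_law(self):
        spec = covariance_spectrum_composed(two_state_scheme(1.0, 3.0), 0.0, 50)
        assert len(spec) == 1
        assert spec.terms[0] == pytest.approx((0.25 * 0.75 / 50, 0.25))

    def test_variance_maximal_at_half_activation(self):
        """2-state sigma^2 = p(1-p)/N peaks where x_inf = 1/2."""
        totals = {
            beta: covariance_spectrum_composed(
                two_state_scheme(1.0, beta), 0.0, 10
            ).total_variance
            for beta in (0.25, 1.0, 4.0)
        }
        assert totals[1.0] > totals[0.25]
        assert totals[1.0] > totals[4.0]


class TestCovarianceSpectrumGeneral:
    @pytest.mark.parametrize("v", [-80.0, -60.0, -45.0, -30.0, -10.0, 20.0])
    def test_path_equivalence_na_k(self, na_scheme, k_scheme, v):
        """Composed (binomial expansion) and general (spectral decomposition)
        derivations agree term-by-term after canonical sorting."""
        for scheme, n in [(na_scheme, 1800), (k_scheme, 360)]:
            comp = covariance_spectrum_composed(scheme, v, n)
            gen = covariance_spectrum_general(scheme, v, n)
            assert len(comp) == len(gen)
            assert gen.sigma_sq == pytest.approx(comp.sigma_sq, abs=1e-8)
            assert gen.tau == pytest.approx(comp.tau, abs=1e-8)

    def test_two_state_single_term(self):
        spec = covariance_spectrum_general(two_state_scheme(1.0, 3.0), 0.0, 50)
        assert len(spec) == 1
        assert spec.terms[0] == pytest.approx((0.25 * 0.75 / 50, 0.25))

    def test_all_taus_positive(self, na_scheme):
        spec = covariance_spectrum_general(na_scheme, -25.0, 100)
        assert np.all(spec.tau > 0)

    def test_oscillatory_cycle_rejected(self):
        """A unidirectional 3-cycle has complex eigenvalues: reported, not
        silently truncated."""

        def build(v):
            a = np.zeros((3, 3))
            a[1, 0] = a[2, 1] = a[0, 2] = 1.0
            np.fill_diagonal(a, -a.sum(axis=0))
            return a

        scheme = ChannelScheme.from_rate_matrix("cycle", ["a", "b", "c"], build, 2)
        with pytest.raises(OscillatorySchemeError):
            covariance_spectrum_general(scheme, 0.0, 10)

    def test_defective_matrix_rejected(self):
        """An absorbing chain with a repeated eigenvalue and a single
        eigenvector is outside the spectral derivation."""

        def build(v):
            return np.array([[-1.0, 0.0, 0.0], [1.0, -1.0, 0.0], [0.0, 1.0, 0.0]])

        scheme = ChannelScheme.from_rate_matrix("jordan", ["a", "b", "c"], build, 2)
        with pytest.raises(DefectiveSchemeError):
            covariance_spectrum_general(scheme, 0.0, 10)


@settings(max_examples=40, deadline=None)
@given(
    alpha=st.floats(0.05, 20.0),
    beta=st.floats(0.05, 20.0),
    count=st.integers(1, 5),
    n=st.integers(1, 10000),
)
def test_conservation_property(alpha, beta, count, n):
    """Spectrum sums to p(1-p)/N for any single-subunit-type scheme."""
    scheme = ChannelScheme.from_subunits(
        "s", [SubunitSpec("x", count, RatePair(constant_rate(alpha), constant_rate(beta)))]
    )
    spec = covariance_spectrum_composed(scheme, 0.0, n)
    p = (alpha / (alpha + beta)) ** count
    assert spec.total_variance == pytest.approx(p * (1 - p) / n, rel=1e-10)
    gen = covariance_spectrum_general(scheme, 0.0, n)
    assert gen.total_variance == pytest.approx(p * (1 - p) / n, rel=1e-8)


@settings(max_examples=25, deadline=None)
@given(
    a1=st.floats(0.1, 10.0), b1=st.floats(0.1, 10.0),
    a2=st.floats(0.1, 10.0), b2=st.floats(0.1, 10.0),
    c1=st.integers(1, 3), c2=st.integers(1, 2),
)
def test_path_equivalence_property(a1, b1, a2, b2, c1, c2):
    """Composed and general covariance paths agree for random two-subunit
    schemes (up to accidental eigenvalue degeneracy, which merges terms)."""
    scheme = ChannelScheme.from_subunits(
        "rand",
        [
            SubunitSpec("u", c1, RatePair(constant_rate(a1), constant_rate(b1))),
            SubunitSpec("w", c2, RatePair(constant_rate(a2), constant_rate(b2))),
        ],
    )
    comp = covariance_spectrum_composed(scheme, 0.0, 100)
    gen = covariance_spectrum_general(scheme, 0.0, 100)
    assert gen.total_variance == pytest.approx(comp.total_variance, rel=1e-8)
    t = np.linspace(0.0, 3.0, 30)
    assert np.allclose(gen.autocovariance(t), comp.autocovariance(t),
                       rtol=1e-6, atol=1e-12)


class TestNoiseSpectrum:
    def test_canonical_order_descending_tau(self, na_scheme):
        spec = covariance_spectrum_composed(na_scheme, -30.0, 100)
        assert np.all(np.diff(spec.tau) < 0)

    def test_negligible_terms_pruned(self):
        spec = NoiseSpectrum(
            sigma_sq=np.array([1.0, 1e-20]), tau=np.array([1.0, 0.5]),
            n_channels=1, p_open=0.5,
        )
        # construction does not prune; the derivation paths do
        scheme = two_state_scheme(1e-9, 1.0)
        derived = covariance_spectrum_composed(scheme, 0.0, 1)
        assert len(derived) == 1  # the tiny-variance term survives as the only term
        assert spec.total_variance == pytest.approx(1.0)


class TestReduceToSingleTerm:
    def test_single_term_identity(self):
        spec = NoiseSpectrum(np.array([0.3]), np.array([2.0]), 1, 0.5)
        assert reduce_to_single_term(spec, "taylor") == pytest.approx((0.3, 2.0))
        s2, tau = reduce_to_single_term(spec, "best_fit")
        assert (s2, tau) == pytest.approx((0.3, 2.0), rel=1e-3)

    def test_equal_weights_give_harmonic_mean_tau(self):
        """Matching value and slope at lag 0: tau = 2/(1/t1 + 1/t2)."""
        spec = NoiseSpectrum(np.array([0.1, 0.1]), np.array([4.0, 1.0]), 1, 0.5)
        s2, tau = reduce_to_single_term(spec, "taylor")
        assert s2 == pytest.approx(0.2)
        assert tau == pytest.approx(2.0 / (1.0 / 4.0 + 1.0 / 1.0))

    def test_best_fit_beats_kinetic_time_constant(self, k_scheme):
        """Using the subunit tau_n as the single time constant fits the
        multi-exponential autocovariance worse than the fitted tau."""
        spec = covariance_spectrum_composed(k_scheme, -35.0, 100)
        tau_n = spec.tau[0]
        grid = np.linspace(0.0, 5.0 * tau_n, 200)
        target = spec.autocovariance(grid)
        s2, tau_fit = reduce_to_single_term(spec, "best_fit", fit_grid=grid)
        res_fit = np.sum((s2 * np.exp(-grid / tau_fit) - target) ** 2)
        res_kin = np.sum((s2 * np.exp(-grid / tau_n) - target) ** 2)
        assert res_fit < res_kin

    def test_empty_spectrum_rejected(self):
        spec = NoiseSpectrum(np.empty(0), np.empty(0), 1, 0.5)
        with pytest.raises(ValueError):
            reduce_to_single_term(spec)
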