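# Methods

## The problem

Ion channels open and close stochastically. In a membrane patch carrying a
finite number N of channels, the fraction of open channels z(t) fluctuates
around its deterministic value, and these conductance fluctuations (*channel
noise*) shape spontaneous firing, spike-time reliability and subthreshold
voltage spectra. Exact simulation tracks the Markov state of the channel
population by Monte-Carlo updating — accurate but expensive. `channoise`
implements the *diffusion approximation*: an effective stochastic model in
which z(t) is the deterministic gate product plus a sum of Ornstein-Uhlenbeck
(OU) processes whose variances and time constants are derived analytically
from the kinetic scheme, so that the mean and the full autocovariance of the
microscopic process are matched. The Fox-Lu Langevin model — white noise
added to the gating-variable equations — is included as a comparator, because
its variance and autocorrelation errors for gate-product channels are the
motivating failure case.

## Analytic open-fraction statistics (`kinetics`)

A single channel is an M-state Markov scheme with one conducting state and
gating-variable-dependent transition rates (per ms). For N independent
channels clamped at a fixed gating value, the number of open channels is
binomial, so

- mean: `p_open`, the stationary occupancy of the conducting state;
- stationary autocovariance: `C(t) = sum_{i=1}^{M-1} sigma_i^2 e^{-t/tau_i}`
  with `sum_i sigma_i^2 = p_open (1 - p_open) / N`.

Two derivation paths are implemented and cross-checked:

**Composed path.** For channels built from independent 2-state subunits
(x_inf = alpha/(alpha+beta), tau_x = 1/(alpha+beta)), the single-channel
autocovariance is the product over subunit types of
`(x_inf^2 + x_inf(1-x_inf) e^{-t/tau_x})^k` minus the constant term.
Binomial expansion yields one term per non-zero exponent combination, with
`1/tau_term = sum_j i_j / tau_j`. The m^3 h sodium channel gives exactly 7
terms, the n^4 potassium channel 4 terms with time constants
tau_n/{1,2,3,4}.

**General path.** For an arbitrary rate matrix A (columns summing to zero),
the conducting-state autocovariance is obtained from the spectral
decomposition `A = V diag(lambda) V^-1`: time constants are `1/|lambda_i|`
over the non-zero eigenvalues, and the weights are
`p_open * V[k,i] V^-1[i,k] / N`. Degenerate eigenvalues are merged.
Matrices with genuinely complex eigenvalues (e.g. unidirectional cycles) or
non-diagonalizable matrices are rejected with explicit errors: the
sum-of-real-exponentials form the method rests on does not exist there.

Terms are canonically ordered (descending tau, ties by descending
sigma^2) and terms below 1e-15 of the total variance are pruned. Aggregating
a composed scheme by open-gate counts (8 states for m^3 h, 5 for n^4) is
exact for occupancy statistics and is what the general path operates on.

**Single-term reduction.** The multi-term spectrum can be collapsed to one
OU term. The first-order (Taylor) reduction matches the value and slope of
C(t) at lag 0: `sigma^2 = sum sigma_i^2`,
`tau = sigma^2 / sum(sigma_i^2/tau_i)`. The best-fit reduction keeps
`sigma^2 = sum sigma_i^2` — so the reduced model's stationary variance is
exact by construction — and chooses tau by least squares against the full
sum on a lag grid (default 0..5x the slowest tau). Both are biased
descriptions of the ACF shape; that is the price of one noise term, and the
voltage-clamp tests quantify it. Neither the subunit time constant tau_x nor
its submultiples are good single time constants; the tests demonstrate this.

## Microscopic simulation (`microscopic`)

Per-state occupancy counts are updated every step: each channel in state s
moves to neighbour s' with probability `rate(s->s') * dt`, drawn as chained
binomials (equivalent to a multinomial draw per source state). Channel count
is conserved exactly. The update is valid when each state's total exit
probability is below 1 — exceeding that raises a `StepSizeError` naming the
state. As an accuracy guideline the exit probability should stay below
~0.1; at the default dt = 0.01 ms the HH sodium ladder reaches ~0.25 near
the spike peak, which shortens the effective dwell times by a few per cent
for those (sub-millisecond) states but leaves stationary occupancies exact
(the discrete chain `I + A dt` has the same null vector as A). Initial
occupancies are drawn multinomially from the stationary distribution at the
initial voltage.

## Effective simulation (`effective`)

Deterministic gates follow the exponential (Rush-Larsen) update
`x <- x_inf + (x - x_inf) e^{-dt/tau_x}`, exact for frozen voltage. Each OU
term uses the exact update
`zeta <- zeta e^{-dt/tau} + sigma sqrt(1 - e^{-2dt/tau}) xi`, correct for
any dt. The coefficients (sigma_i, tau_i) are refreshed from the covariance
spectrum at the instantaneous voltage before each OU step — the
slow-gating assumption. The open fraction is
`z = prod x_j^{k_j} + sum zeta_i`, clipped to [0, 1] at the conductance
evaluation only (state variables are never modified, preserving the OU
statistics; without clipping the mean is unbiased, and both policies are
available). With all sigma_i = 0 the deterministic model is recovered
exactly — in this implementation, bitwise.

## Fox-Lu comparator (`fox`)

Each gating variable gets a white-noise term with covariance
`2 alpha beta / (N (alpha + beta)) delta(t-t')` (the stationary coefficient
of Fox 1997), i.e. the gate is an OU process around x_inf with time constant
1/(alpha+beta) and stationary variance x_inf(1-x_inf)/N. It is integrated
with the same exact exponential update (same SDE, better discretization than
Euler-Maruyama) and gates are clipped to [0,1] after each step. For a single
2-state gate this coincides exactly with the diffusion approximation; for
gate products (n^4, m^3 h) it overestimates the potassium variance,
underestimates the sodium variance, and mis-shapes the autocorrelation —
the comparisons in `compare` and the test suite reproduce all three effects.

## Membrane integration (`membrane`)

Single cylindrical compartment (lateral area only, the NEURON convention):
`C_m dV/dt = I_ext - g_L (V - E_L) - sum_p g_p z_p (V - E_p)` with
`g_p = gamma_p N_p / area`, so the deterministic and stochastic descriptions
share one maximal conductance by construction. The voltage update is
exponential-Euler (exact for conductances frozen over one step): with
forward Euler at dt = 0.01 ms, deterministic spike times drift ~0.4 ms over
500 ms when dt is halved; exponential-Euler reduces this to ~0.01 ms at the
same cost, and it matches the exponential updates used for gates and OU
terms. Default dt is 0.01 ms (0.001 ms for pulse-latency protocols).
Backends share everything except the channel-state update; "noise off"
(`noise_scale=0`) makes every backend follow the deterministic trajectory
exactly (for the microscopic backend this is the N -> infinity limit, which
for composed schemes *is* the gate-product model, so it runs the
deterministic kernel).

Inner loops are numba kernels; voltage-dependent rates enter them via dense
lookup tables (0.02 mV grid, linear interpolation) built from the exact rate
functions — the interpolation error (~1e-8 relative) is far below
Monte-Carlo error. The pure-NumPy single-step functions (`step_population`,
`ou_step_exact`, `step_effective_channels`, `step_fox`) define the semantics
and are tested against the same contracts.

## Parameters and defaults

| parameter | default | note |
| --- | --- | --- |
| C_m | 1 uF/cm^2 | standard squid-axon value |
| g_L, E_L | 0.3 mS/cm^2, -54.4 mV | leak |
| E_Na, E_K | +50, -77 mV | reversal potentials |
| rate laws | canonical squid-axon alpha/beta | modern convention, rest ~ -63 mV |
| gamma | 10 pS | single-channel conductance, both currents |
| densities | 60 (Na), 18 (K) um^-2 | with gamma = 10 pS these give g_Na = 60, g_K = 18 mS/cm^2 |
| geometry | 30 x 30 um cylinder | configurable; protocols below use smaller cells |
| dt | 0.01 ms | 0.001 ms for pulse trials |

With these conductances the deterministic model rests at -63.1 mV and the
repetitive-firing onset (type-II jump) lies between 5.0 and 5.3 uA/cm^2.
The removable singularities of the linear-exponential rate laws (at -40 mV
for the m gate, -55 mV for the n gate) are evaluated by a guarded series
expansion.

Protocol defaults (chosen once as a realistic operating regime; they are
package choices, configurable throughout):

- **Spontaneous/subthreshold firing:** 10 x 10 um cell (~18,850 Na and
  5,655 K channels), DC 4.0 uA/cm^2, initial voltage at the holding-current
  fixed point. The deterministic model is silent there (a DC *step* from
  rest would fire a single onset spike, which is a stimulus-transient
  artifact, hence the fixed-point initialisation); both stochastic backends
  fire irregularly (CV ~ 1).
- **f-I:** 14 x 14 um cell, amplitudes 4.4-5.6 uA/cm^2 bracketing the
  deterministic jump, 10 repetitions of 5 s.
- **Reliability:** 10 x 10 um cell, 20 trials of 1 s; DC 6.5 uA/cm^2 vs a
  frozen OU current with mean = SD = 6.5 uA/cm^2 and 3 ms correlation time.
- **Voltage spectra:** 100 s at 0.05 ms sampling under 1.0 uA/cm^2 holding
  current; Welch with 1 s Hann windows, 50% overlap; spikes blanked 2 ms
  before to 8 ms after. The integrated PSD is checked against the mean
  variance of the analyzed (detrended, unblanked) segments.

## Statistical methodology

Voltage-clamp comparisons use either block-based standard errors (20 blocks)
or, where the autocovariance is known analytically, the exact sampling
errors `SE_mean^2 = 2 sum_i sigma_i^2 tau_i / T` and the Gaussian
approximation `Var(var_hat) = (4/T) integral C(t)^2 dt`. Directional Fox
claims use one-sided Welch t-tests on block variances at the 5% level.
ACF time constants come from a least-squares single-exponential fit on lags
up to 5x the dominant tau (initialised at the 1/e crossing); the fitted
lag-0 value equals the sample variance exactly by construction of the
estimator. Spike detection: upward 0 mV crossings, linearly interpolated,
2 ms refractory. Reliability/precision follow the event-based construction:
Gaussian-smoothed PSTH (SD 2 ms), events where the smoothed rate exceeds
2x the session-mean rate, reliability = mean fraction of trials spiking per
event, precision = mean within-event first-spike SD.

## What the synthetic conditions do and do not show

All validation is against the package's own exact microscopic simulator on
the standard two-current single-compartment model — the appropriate oracle,
since the diffusion approximation's claim is agreement with the microscopic
description. Passing tests show the approximation reproduces microscopic
first- and second-order statistics and current-clamp phenomenology at
N ~ 10^3-10^5 channels. They do not establish accuracy for real neurons
(no multi-compartment morphology, no synaptic conductances — the OU current
stimulus stands in for fluctuating drive), nor for schemes violating the
assumptions below.

## Assumptions and known limitations

- Channels identical and independent; one conducting state; N large enough
  for the Gaussian approximation. At very small N (very small cells) the
  effective model over-estimates spontaneous rates; the bias shrinks as the
  area grows.
- Gating variables slow compared with channel kinetics. During the spike
  upstroke this is violated; consequences here: pulse-evoked efficacy of the
  effective model slightly exceeds the microscopic one at intermediate
  amplitudes, and driven firing rates fall ~15-20% below microscopic ones at
  high rates in small cells. Subthreshold statistics and the f-I region
  around the onset are unaffected.
- Schemes whose rate matrix has complex eigenvalues (irreversible cycles)
  or is defective are rejected rather than approximated.
- The reduced (single-OU) backend preserves variance exactly but distorts
  the autocorrelation shape by construction.
- Voltage-clamp drivers at fixed holding value use the AR(1) form of the OU
  recursion; microscopic voltage-clamp precomputes constant transition
  probabilities. Both are exact specializations, not extra approximations.
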