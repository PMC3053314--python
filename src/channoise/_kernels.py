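"""Compiled integration kernels and their packing helpers.

All membrane and voltage-clamp inner loops run as numba kernels over packed
array representations of the channel schemes. Voltage-dependent rates enter
the kernels through dense lookup tables (uniform voltage grid, linear
interpolation) built from the exact rate functions; the grid is fine enough
(0.02 mV) for the interpolation error to be far below Monte-Carlo error.

The pure-NumPy single-step operations in :mod:`channoise.microscopic` and
:mod:`channoise.effective` define the semantics these kernels reproduce.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# rate lookup tables


class RateTable:
    """Dense per-rate lookup table over a uniform voltage grid."""

    def __init__(self, v_min: float = -150.0, v_max: float = 100.0, dv: float = 0.02):
        self.v_min = float(v_min)
        self.dv = float(dv)
        self.n_v = int(round((v_max - v_min) / dv)) + 1
        self.v_grid = v_min + self.dv * np.arange(self.n_v)
        self._fns = []

    def add(self, fn) -> int:
        for i, f in enumerate(self._fns):
            if f is fn:
                return i
        self._fns.append(fn)
        return len(self._fns) - 1

    def add_samples(self, values: np.ndarray) -> int:
        self._fns.append(np.asarray(values, dtype=float))
        return len(self._fns) - 1

    def build(self) -> np.ndarray:
        rows = []
        for f in self._fns:
            if isinstance(f, np.ndarray):
                rows.append(f)
            else:
                rows.append(np.asarray(f(self.v_grid), dtype=float))
        table = np.array(rows, dtype=float)
        if not np.all(np.isfinite(table)) or np.any(table < 0):
            raise ValueError("rate table contains negative or non-finite entries")
        return table


@njit(cache=True, inline="always")
def _rate(table, row, v, v0, dv, nv):
    x = (v - v0) / dv
    if x <= 0.0:
        return table[row, 0]
    if x >= nv - 1:
        return table[row, nv - 1]
    i = int(x)
    f = x - i
    return table[row, i] * (1.0 - f) + table[row, i + 1] * f


# ---------------------------------------------------------------------------
# packing


class PackedMicro:
    """Array form of one or more microscopic channel populations.

    States of all populations are concatenated; ``state_off[p]`` is the
    first global state index of population p. Transitions are stored per
    source state, each with a destination, a rate-table row, and a
    multiplicity (the combinatorial gate factor).
    """

    def __init__(self, populations, table: RateTable):
        state_off = [0]
        open_idx = []
        n_ch = []
        tr_off = []
        tr_to, tr_row, tr_mult = [], [], []
        for pop in populations:
            scheme = pop.scheme
            base = state_off[-1]
            if scheme.is_composed:
                subs = scheme.subunits
                tuples = scheme._state_tuples()
                index = {t: i for i, t in enumerate(tuples)}
                arow = [table.add(s.rates.alpha) for s in subs]
                brow = [table.add(s.rates.beta) for s in subs]
                for t in tuples:
                    tr_off.append(len(tr_to))
                    for jj, spec in enumerate(subs):
                        i_open = t[jj]
                        if i_open < spec.count:
                            up = list(t)
                            up[jj] += 1
                            tr_to.append(base + index[tuple(up)])
                            tr_row.append(arow[jj])
                            tr_mult.append(float(spec.count - i_open))
                        if i_open > 0:
                            dn = list(t)
                            dn[jj] -= 1
                            tr_to.append(base + index[tuple(dn)])
                            tr_row.append(brow[jj])
                            tr_mult.append(float(i_open))
                open_global = base + index[tuple(s.count for s in subs)]
            else:
                m = scheme.n_states
                grid = table.v_grid
                # tabulate every off-diagonal entry over the grid
                mats = np.empty((grid.size, m, m))
                for g, vg in enumerate(grid):
                    mats[g] = scheme.rate_builder(vg)
                for j in range(m):
                    tr_off.append(len(tr_to))
                    for i in range(m):
                        if i == j:
                            continue
                        col = mats[:, i, j]
                        if np.any(col != 0.0):
                            tr_to.append(base + i)
                            tr_row.append(table.add_samples(col))
                            tr_mult.append(1.0)
                open_global = base + scheme.conducting_index
            state_off.append(base + scheme.n_states)
            open_idx.append(open_global)
            n_ch.append(pop.n_channels)
        tr_off.append(len(tr_to))
        self.state_off = np.array(state_off, dtype=np.int64)
        self.open_idx = np.array(open_idx, dtype=np.int64)
        self.n_ch = np.array(n_ch, dtype=np.int64)
        self.tr_off = np.array(tr_off, dtype=np.int64)
        self.tr_to = np.array(tr_to, dtype=np.int64)
        self.tr_row = np.array(tr_row, dtype=np.int64)
        self.tr_mult = np.array(tr_mult, dtype=np.float64)


class PackedEffective:
    """Array form of composed populations for the effective / Fox backends."""

    def __init__(self, populations, table: RateTable):
        import itertools as _it

        sub_off = [0]
        sub_k, sub_arow, sub_brow = [], [], []
        term_off = [0]
        term_binom = []
        expo_rows = []
        n_ch = []
        max_sub = max(len(p.scheme.subunits) for p in populations)
        for pop in populations:
            scheme = pop.scheme
            if not scheme.is_composed:
                raise ValueError(
                    "effective/fox kernels require subunit-composed schemes; "
                    "use the general-scheme analysis path instead"
                )
            for s in scheme.subunits:
                sub_k.append(s.count)
                sub_arow.append(table.add(s.rates.alpha))
                sub_brow.append(table.add(s.rates.beta))
            sub_off.append(len(sub_k))
            counts = [s.count for s in scheme.subunits]
            for combo in _it.product(*(range(c + 1) for c in counts)):
                if all(i == 0 for i in combo):
                    continue
                term_binom.append(
                    float(np.prod([math.comb(k, i) for k, i in zip(counts, combo)]))
                )
                row = list(combo) + [0] * (max_sub - len(combo))
                expo_rows.append(row)
            term_off.append(len(term_binom))
            n_ch.append(pop.n_channels)
        self.sub_off = np.array(sub_off, dtype=np.int64)
        self.sub_k = np.array(sub_k, dtype=np.int64)
        self.sub_arow = np.array(sub_arow, dtype=np.int64)
        self.sub_brow = np.array(sub_brow, dtype=np.int64)
        self.term_off = np.array(term_off, dtype=np.int64)
        self.term_binom = np.array(term_binom, dtype=np.float64)
        self.expo = np.array(expo_rows, dtype=np.int64)
        self.n_ch = np.array(n_ch, dtype=np.int64)


# ---------------------------------------------------------------------------
# microscopic kernels


@njit(cache=True)
def micro_vclamp_kernel(counts0, tr_off, tr_to, p_tr,
                        open_idx, n_channels, n_steps, burn_steps, seed):
    """Fixed-voltage Monte-Carlo occupancy updating; returns the post-burn-in
    open-fraction trace, the final counts and an error flag."""
    np.random.seed(seed)
    n_states = counts0.shape[0]
    counts = counts0.copy()
    new_counts = np.zeros(n_states, dtype=np.int64)
    z = np.empty(n_steps - burn_steps)
    # validity: total exit probability < 1 for every state
    for s in range(n_states):
        ptot = 0.0
        for k in range(tr_off[s], tr_off[s + 1]):
            ptot += p_tr[k]
        if ptot >= 1.0:
            return z, counts, 1, s
    for t in range(n_steps):
        for s in range(n_states):
            new_counts[s] = 0
        for s in range(n_states):
            n = counts[s]
            if n == 0:
                continue
            remaining = n
            cum = 1.0
            for k in range(tr_off[s], tr_off[s + 1]):
                p = p_tr[k]
                pc = p / cum
                if pc > 1.0:
                    pc = 1.0
                b = np.random.binomial(remaining, pc)
                new_counts[tr_to[k]] += b
                remaining -= b
                cum -= p
                if remaining == 0:
                    break
            new_counts[s] += remaining
        tmp = counts
        counts = new_counts
        new_counts = tmp
        if t >= burn_steps:
            z[t - burn_steps] = counts[open_idx] / n_channels
    return z, counts, 0, -1


@njit(cache=True)
def micro_membrane_kernel(counts0, state_off, open_idx, n_ch,
                          tr_off, tr_to, tr_row, tr_mult,
                          table, v0g, dvg, nvg,
                          gbar, erev, cm, gl, el,
                          i_ext, dt, v_init, rec_stride, seed):
    """Current-clamp integration with microscopic channel populations.

    Exponential-Euler voltage update on the current balance; per-state
    chained-binomial (multinomial) transition draws at the instantaneous
    voltage.
    Returns (v_trace, z_traces, err, err_info): err 1 = step-size violation
    (err_info = global state index), err 2 = divergence (err_info = step).
    """
    np.random.seed(seed)
    n_steps = i_ext.shape[0]
    n_pop = n_ch.shape[0]
    n_states = state_off[n_pop]
    counts = counts0.copy()
    new_counts = np.zeros(n_states, dtype=np.int64)
    n_rec = n_steps // rec_stride
    v_out = np.empty(n_rec)
    z_out = np.empty((n_pop, n_rec))
    p_buf = np.empty(tr_to.shape[0])
    v = v_init
    i_rec = 0
    for t in range(n_steps):
        # exponential-Euler voltage update with conductances frozen over dt
        g_tot = gl
        ge_tot = gl * el + i_ext[t]
        for p in range(n_pop):
            g = gbar[p] * counts[open_idx[p]] / n_ch[p]
            g_tot += g
            ge_tot += g * erev[p]
        v_inf = ge_tot / g_tot
        v_next = v_inf + (v - v_inf) * math.exp(-dt * g_tot / cm)
        for s in range(n_states):
            new_counts[s] = 0
        for s in range(n_states):
            n = counts[s]
            if n == 0:
                continue
            ptot = 0.0
            for k in range(tr_off[s], tr_off[s + 1]):
                p_buf[k] = tr_mult[k] * _rate(table, tr_row[k], v, v0g, dvg, nvg) * dt
                ptot += p_buf[k]
            if ptot >= 1.0:
                return v_out, z_out, counts, 1, s
            remaining = n
            cum = 1.0
            for k in range(tr_off[s], tr_off[s + 1]):
                pc = p_buf[k] / cum
                if pc > 1.0:
                    pc = 1.0
                b = np.random.binomial(remaining, pc)
                new_counts[tr_to[k]] += b
                remaining -= b
                cum -= p_buf[k]
                if remaining == 0:
                    break
            new_counts[s] += remaining
        tmp = counts
        counts = new_counts
        new_counts = tmp
        v = v_next
        if not np.isfinite(v) or abs(v) > 200.0:
            return v_out, z_out, counts, 2, t
        if (t + 1) % rec_stride == 0:
            v_out[i_rec] = v
            for p in range(n_pop):
                z_out[p, i_rec] = counts[open_idx[p]] / n_ch[p]
            i_rec += 1
    return v_out, z_out, counts, 0, -1


# ---------------------------------------------------------------------------
# effective / deterministic kernels


@njit(cache=True)
def eff_membrane_kernel(x0, zeta0, sub_off, sub_k, sub_arow, sub_brow,
                        term_off, term_binom, expo, n_ch,
                        table, v0g, dvg, nvg,
                        gbar, erev, cm, gl, el,
                        i_ext, dt, v_init, rec_stride, noise_scale, clip, seed):
    """Current-clamp integration of the diffusion-approximation model.

    Deterministic gates advance by the exponential (Rush-Larsen) update;
    every OU term's (sigma_i, tau_i) is refreshed from the instantaneous
    voltage and stepped with the exact OU update. ``noise_scale = 0``
    recovers the deterministic model exactly. With ``clip`` the open
    fraction is clipped to [0, 1] at the conductance evaluation only.
    """
    np.random.seed(seed)
    n_steps = i_ext.shape[0]
    n_pop = n_ch.shape[0]
    n_sub = sub_off[n_pop]
    x = x0.copy()
    zeta = zeta0.copy()
    xinf = np.empty(n_sub)
    rtot = np.empty(n_sub)
    n_rec = n_steps // rec_stride
    v_out = np.empty(n_rec)
    z_out = np.empty((n_pop, n_rec))
    v = v_init
    i_rec = 0
    z_pop = np.empty(n_pop)
    for t in range(n_steps):
        # channel update at the instantaneous voltage
        for p in range(n_pop):
            z_det = 1.0
            for j in range(sub_off[p], sub_off[p + 1]):
                a = _rate(table, sub_arow[j], v, v0g, dvg, nvg)
                b = _rate(table, sub_brow[j], v, v0g, dvg, nvg)
                r = a + b
                xi = a / r
                xinf[j] = xi
                rtot[j] = r
                x[j] = xi + (x[j] - xi) * math.exp(-dt * r)
                z_det *= x[j] ** sub_k[j]
            z = z_det
            for q in range(term_off[p], term_off[p + 1]):
                var = term_binom[q] / n_ch[p]
                inv_tau = 0.0
                for j in range(sub_off[p], sub_off[p + 1]):
                    i_e = expo[q, j - sub_off[p]]
                    k = sub_k[j]
                    xi = xinf[j]
                    var *= xi ** (2 * (k - i_e)) * (xi * (1.0 - xi)) ** i_e
                    inv_tau += i_e * rtot[j]
                sd = noise_scale * math.sqrt(var)
                e1 = math.exp(-dt * inv_tau)
                zeta[q] = zeta[q] * e1 + sd * math.sqrt(1.0 - e1 * e1) * np.random.normal()
                z += zeta[q]
            if clip:
                if z < 0.0:
                    z = 0.0
                elif z > 1.0:
                    z = 1.0
            z_pop[p] = z
        # exponential-Euler voltage update with conductances frozen over dt
        g_tot = gl
        ge_tot = gl * el + i_ext[t]
        for p in range(n_pop):
            g = gbar[p] * z_pop[p]
            g_tot += g
            ge_tot += g * erev[p]
        v_inf = ge_tot / g_tot
        v = v_inf + (v - v_inf) * math.exp(-dt * g_tot / cm)
        if not np.isfinite(v) or abs(v) > 200.0:
            return v_out, z_out, x, zeta, 2, t
        if (t + 1) % rec_stride == 0:
            v_out[i_rec] = v
            for p in range(n_pop):
                z_out[p, i_rec] = z_pop[p]
            i_rec += 1
    return v_out, z_out, x, zeta, 0, -1


@njit(cache=True)
def eff_membrane_reduced_kernel(x0, zeta0, sub_off, sub_k, sub_arow, sub_brow,
                                term_off, term_binom, expo, n_ch,
                                table, v0g, dvg, nvg,
                                gbar, erev, cm, gl, el,
                                i_ext, dt, v_init, rec_stride, noise_scale,
                                clip, seed):
    """Single-OU-term reduction of the effective model (first-order matching
    of the summed autocovariance at lag 0: sigma^2 = sum sigma_i^2,
    tau = sigma^2 / sum(sigma_i^2 / tau_i)). One zeta per population."""
    np.random.seed(seed)
    n_steps = i_ext.shape[0]
    n_pop = n_ch.shape[0]
    n_sub = sub_off[n_pop]
    x = x0.copy()
    zeta = zeta0.copy()
    xinf = np.empty(n_sub)
    rtot = np.empty(n_sub)
    n_rec = n_steps // rec_stride
    v_out = np.empty(n_rec)
    z_out = np.empty((n_pop, n_rec))
    v = v_init
    i_rec = 0
    z_pop = np.empty(n_pop)
    for t in range(n_steps):
        for p in range(n_pop):
            z_det = 1.0
            for j in range(sub_off[p], sub_off[p + 1]):
                a = _rate(table, sub_arow[j], v, v0g, dvg, nvg)
                b = _rate(table, sub_brow[j], v, v0g, dvg, nvg)
                r = a + b
                xi = a / r
                xinf[j] = xi
                rtot[j] = r
                x[j] = xi + (x[j] - xi) * math.exp(-dt * r)
                z_det *= x[j] ** sub_k[j]
            var_tot = 0.0
            slope = 0.0
            for q in range(term_off[p], term_off[p + 1]):
                var = term_binom[q] / n_ch[p]
                inv_tau = 0.0
                for j in range(sub_off[p], sub_off[p + 1]):
                    i_e = expo[q, j - sub_off[p]]
                    k = sub_k[j]
                    xi = xinf[j]
                    var *= xi ** (2 * (k - i_e)) * (xi * (1.0 - xi)) ** i_e
                    inv_tau += i_e * rtot[j]
                var_tot += var
                slope += var * inv_tau
            inv_tau_eff = slope / var_tot if var_tot > 0.0 else 1.0 / dt
            sd = noise_scale * math.sqrt(var_tot)
            e1 = math.exp(-dt * inv_tau_eff)
            zeta[p] = zeta[p] * e1 + sd * math.sqrt(1.0 - e1 * e1) * np.random.normal()
            z = z_det + zeta[p]
            if clip:
                if z < 0.0:
                    z = 0.0
                elif z > 1.0:
                    z = 1.0
            z_pop[p] = z
        # exponential-Euler voltage update with conductances frozen over dt
        g_tot = gl
        ge_tot = gl * el + i_ext[t]
        for p in range(n_pop):
            g = gbar[p] * z_pop[p]
            g_tot += g
            ge_tot += g * erev[p]
        v_inf = ge_tot / g_tot
        v = v_inf + (v - v_inf) * math.exp(-dt * g_tot / cm)
        if not np.isfinite(v) or abs(v) > 200.0:
            return v_out, z_out, x, zeta, 2, t
        if (t + 1) % rec_stride == 0:
            v_out[i_rec] = v
            for p in range(n_pop):
                z_out[p, i_rec] = z_pop[p]
            i_rec += 1
    return v_out, z_out, x, zeta, 0, -1


@njit(cache=True)
def fox_membrane_kernel(x0, sub_off, sub_k, sub_arow, sub_brow, n_ch,
                        table, v0g, dvg, nvg,
                        gbar, erev, cm, gl, el,
                        i_ext, dt, v_init, rec_stride, noise_scale, seed):
    """Current-clamp integration of the Fox-Lu Langevin comparator.

    Each gating variable carries its own noise term with white-noise
    covariance 2 alpha beta / (N (alpha + beta)) (Fox 1997), i.e. the gate
    is an OU process around x_inf with time constant 1/(alpha+beta) and
    stationary variance x_inf(1-x_inf)/N; gates are clipped to [0, 1] after
    each step. The conductance is the plain gate product.
    """
    np.random.seed(seed)
    n_steps = i_ext.shape[0]
    n_pop = n_ch.shape[0]
    x = x0.copy()
    n_rec = n_steps // rec_stride
    v_out = np.empty(n_rec)
    z_out = np.empty((n_pop, n_rec))
    v = v_init
    i_rec = 0
    z_pop = np.empty(n_pop)
    for t in range(n_steps):
        for p in range(n_pop):
            z = 1.0
            for j in range(sub_off[p], sub_off[p + 1]):
                a = _rate(table, sub_arow[j], v, v0g, dvg, nvg)
                b = _rate(table, sub_brow[j], v, v0g, dvg, nvg)
                r = a + b
                xi = a / r
                sd = noise_scale * math.sqrt(xi * (1.0 - xi) / n_ch[p])
                e1 = math.exp(-dt * r)
                xn = xi + (x[j] - xi) * e1 + sd * math.sqrt(1.0 - e1 * e1) * np.random.normal()
                if xn < 0.0:
                    xn = 0.0
                elif xn > 1.0:
                    xn = 1.0
                x[j] = xn
                z *= xn ** sub_k[j]
            z_pop[p] = z
        # exponential-Euler voltage update with conductances frozen over dt
        g_tot = gl
        ge_tot = gl * el + i_ext[t]
        for p in range(n_pop):
            g = gbar[p] * z_pop[p]
            g_tot += g
            ge_tot += g * erev[p]
        v_inf = ge_tot / g_tot
        v = v_inf + (v - v_inf) * math.exp(-dt * g_tot / cm)
        if not np.isfinite(v) or abs(v) > 200.0:
            return v_out, z_out, x, 2, t
        if (t + 1) % rec_stride == 0:
            v_out[i_rec] = v
            for p in range(n_pop):
                z_out[p, i_rec] = z_pop[p]
            i_rec += 1
    return v_out, z_out, x, 0, -1
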