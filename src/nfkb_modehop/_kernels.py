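"""Numba-compiled numerical kernels.

Everything here works on plain float64/int64 arrays; the public modules wrap
these in the dataclass API.  Parameter vectors follow ``model.PARAM_NAMES``
order, signal vectors are (period, amplitude, baseline, duty, constant_flag).

All kernels are deterministic given their inputs; the Gillespie kernel seeds
numba's internal generator itself so that a seed fully determines the event
sequence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the parameter vector (model.PARAM_NAMES order)
P_KNIN, P_KIIN, P_KT, P_KTL, P_KI, P_KN, P_GM, P_ALPHA, P_NTOT, P_KA, P_KIRATE, P_KP, P_KA20, P_IKKTOT, P_A20 = range(15)

N_CHANNELS_TERM = 10
N_CHANNELS_PHYSICAL = 9


@njit(cache=True)
def tnf_kernel(t, sig):
    """Square-pulse TNF value at time t."""
    period, amp, base, duty, const = sig[0], sig[1], sig[2], sig[3], sig[4]
    if const != 0.0 or amp == 0.0:
        return base
    phase = t % period
    if phase < duty * period:
        return base + amp
    v = base - amp
    return v if v > 0.0 else 0.0


@njit(cache=True, inline="always")
def _deriv(Nn, Im, I, IKKa, IKKi, tnf, p):
    dNn = p[P_KNIN] * (p[P_NTOT] - Nn) * p[P_KI] / (p[P_KI] + I) \
        - p[P_KIIN] * I * Nn / (p[P_KN] + Nn)
    dIm = p[P_KT] * Nn * Nn - p[P_GM] * Im
    dI = p[P_KTL] * Im - p[P_ALPHA] * IKKa * (p[P_NTOT] - Nn) * I / (p[P_KI] + I)
    dIKKa = p[P_KA] * tnf * (p[P_IKKTOT] - IKKa - IKKi) - p[P_KIRATE] * IKKa
    dIKKi = p[P_KIRATE] * IKKa - p[P_KP] * IKKi * p[P_KA20] / (p[P_KA20] + p[P_A20] * tnf)
    return dNn, dIm, dI, dIKKa, dIKKi


@njit(cache=True, inline="always")
def _rk4_step(y, t, dt, p, sig):
    """One classic RK4 step, forcing evaluated at sub-stage times. In place."""
    tnf1 = tnf_kernel(t, sig)
    tnf2 = tnf_kernel(t + 0.5 * dt, sig)
    tnf4 = tnf_kernel(t + dt, sig)
    a0, a1, a2, a3, a4 = _deriv(y[0], y[1], y[2], y[3], y[4], tnf1, p)
    b0, b1, b2, b3, b4 = _deriv(y[0] + 0.5 * dt * a0, y[1] + 0.5 * dt * a1,
                                y[2] + 0.5 * dt * a2, y[3] + 0.5 * dt * a3,
                                y[4] + 0.5 * dt * a4, tnf2, p)
    c0, c1, c2, c3, c4 = _deriv(y[0] + 0.5 * dt * b0, y[1] + 0.5 * dt * b1,
                                y[2] + 0.5 * dt * b2, y[3] + 0.5 * dt * b3,
                                y[4] + 0.5 * dt * b4, tnf2, p)
    d0, d1, d2, d3, d4 = _deriv(y[0] + dt * c0, y[1] + dt * c1,
                                y[2] + dt * c2, y[3] + dt * c3,
                                y[4] + dt * c4, tnf4, p)
    y[0] += dt * (a0 + 2.0 * b0 + 2.0 * c0 + d0) / 6.0
    y[1] += dt * (a1 + 2.0 * b1 + 2.0 * c1 + d1) / 6.0
    y[2] += dt * (a2 + 2.0 * b2 + 2.0 * c2 + d2) / 6.0
    y[3] += dt * (a3 + 2.0 * b3 + 2.0 * c3 + d3) / 6.0
    y[4] += dt * (a4 + 2.0 * b4 + 2.0 * c4 + d4) / 6.0


@njit(cache=True)
def rk4_kernel(y0, p, sig, t0, n_rec, n_sub, dt):
    """Integrate from t0 with n_rec records, n_sub RK4 steps of size dt each.

    Returns (states, status, fail_time): states has n_rec+1 rows (row 0 is the
    initial state); status 0 = ok, 1 = non-finite state encountered at
    fail_time (remaining rows undefined).
    """
    out = np.empty((n_rec + 1, 5))
    y = y0.copy()
    out[0] = y
    rec_len = n_sub * dt
    for r in range(n_rec):
        t_rec = t0 + r * rec_len
        for s in range(n_sub):
            _rk4_step(y, t_rec + s * dt, dt, p, sig)
        ok = True
        for k in range(5):
            if not np.isfinite(y[k]):
                ok = False
        if not ok:
            return out, 1, t_rec + rec_len
        out[r + 1] = y
    return out, 0, 0.0


@njit(cache=True, inline="always")
def _propensities(a, counts, p, tnf, f, n_ntot, n_ikktot, physical):
    """Fill propensity vector ``a`` (events/min); returns total.

    One channel per ODE term (10 channels); in physical mode the two ki·IKKa
    terms are fused into a single IKKa→IKKi conversion channel (9 channels).
    Channels whose reactant pool is exhausted get zero propensity, and the
    conserved-pool guards keep Nn ≤ Ntot and IKKa+IKKi ≤ IKKtot exactly.
    """
    cN = counts[0] / f
    cIm = counts[1] / f
    cI = counts[2] / f
    cA = counts[3] / f
    cIi = counts[4] / f
    free_n = p[P_NTOT] - cN
    if free_n < 0.0:
        free_n = 0.0
    free_ikk = p[P_IKKTOT] - cA - cIi
    if free_ikk < 0.0:
        free_ikk = 0.0

    a[0] = 0.0 if counts[0] >= n_ntot else p[P_KNIN] * free_n * p[P_KI] / (p[P_KI] + cI) * f
    a[1] = p[P_KIIN] * cI * cN / (p[P_KN] + cN) * f
    a[2] = p[P_KT] * cN * cN * f
    a[3] = p[P_GM] * cIm * f
    a[4] = p[P_KTL] * cIm * f
    a[5] = p[P_ALPHA] * cA * free_n * cI / (p[P_KI] + cI) * f
    a[6] = 0.0 if counts[3] + counts[4] >= n_ikktot else p[P_KA] * tnf * free_ikk * f
    a[7] = p[P_KIRATE] * cA * f
    if physical:
        # fused IKKa −1 / IKKi +1 channel at index 7; shift the tail up
        a[8] = p[P_KP] * cIi * p[P_KA20] / (p[P_KA20] + p[P_A20] * tnf) * f
        a[9] = 0.0
        total = 0.0
        for j in range(9):
            total += a[j]
        return total
    a[8] = 0.0 if counts[3] + counts[4] >= n_ikktot else p[P_KIRATE] * cA * f
    a[9] = p[P_KP] * cIi * p[P_KA20] / (p[P_KA20] + p[P_A20] * tnf) * f
    total = 0.0
    for j in range(10):
        total += a[j]
    return total


@njit(cache=True, inline="always")
def _apply_channel(counts, j, physical):
    """Apply stoichiometry of channel j to the count vector."""
    if physical and j == 7:
        counts[3] -= 1
        counts[4] += 1
        return
    if physical and j == 8:
        counts[4] -= 1
        return
    if j == 0:
        counts[0] += 1
    elif j == 1:
        counts[0] -= 1
    elif j == 2:
        counts[1] += 1
    elif j == 3:
        counts[1] -= 1
    elif j == 4:
        counts[2] += 1
    elif j == 5:
        counts[2] -= 1
    elif j == 6:
        counts[3] += 1
    elif j == 7:
        counts[3] -= 1
    elif j == 8:
        counts[4] += 1
    else:
        counts[4] -= 1


@njit(cache=True)
def _next_switch(t, sig):
    """Next TNF square-wave switching time strictly after t (inf if none)."""
    period, amp, _, duty, const = sig[0], sig[1], sig[2], sig[3], sig[4]
    if const != 0.0 or amp == 0.0:
        return np.inf
    eps = 1e-9
    m = np.floor(t / period)
    for k in range(3):
        c1 = (m + k + duty) * period
        if c1 > t + eps:
            return c1
        c2 = (m + k + 1.0) * period
        if c2 > t + eps:
            return c2
    return (m + 3.0) * period  # unreachable


@njit(cache=True)
def gillespie_kernel(n0, p, sig, f, t_end, record_every, seed, physical):
    """Exact SSA with piecewise-constant forcing.

    The square wave is constant between switching times, so waiting times are
    exponential per segment: if the drawn event would cross a switch, the
    clock advances to the switch and the draw is repeated with the new
    propensities (exactness preserved).  Recording is sample-and-hold on a
    uniform grid.  Returns (times, counts_out, n_events, stalled).
    """
    np.random.seed(seed)
    n_rec = int(round(t_end / record_every))
    times = np.empty(n_rec + 1)
    for i in range(n_rec + 1):
        times[i] = i * record_every
    out = np.zeros((n_rec + 1, 5), dtype=np.int64)
    counts = n0.copy()
    out[0] = counts
    rec_i = 1
    n_ntot = int(round(p[P_NTOT] * f))
    n_ikktot = int(round(p[P_IKKTOT] * f))
    a = np.zeros(10)
    t = 0.0
    n_events = 0
    stalled = False
    while t < t_end:
        tnf = tnf_kernel(t, sig)
        a0 = _propensities(a, counts, p, tnf, f, n_ntot, n_ikktot, physical)
        t_sw = _next_switch(t, sig)
        if a0 <= 0.0:
            if not np.isfinite(t_sw):
                stalled = True
                break
            t_new = t_sw
            event = False
        else:
            u = np.random.random()
            while u <= 0.0:  # guard against log(0)
                u = np.random.random()
            tau = -np.log(u) / a0
            t_new = t + tau
            if t_new > t_sw:
                t_new = t_sw
                event = False
            else:
                event = True
        # state is `counts` on [t, t_new): record grid points in that window
        while rec_i <= n_rec and times[rec_i] < t_new:
            out[rec_i] = counts
            rec_i += 1
        if t_new >= t_end:
            t = t_new
            break
        t = t_new
        if event:
            r = np.random.random() * a0
            acc = 0.0
            nch = 9 if physical else 10
            j = nch - 1
            for k in range(nch):
                acc += a[k]
                if r < acc:
                    j = k
                    break
            _apply_channel(counts, j, physical)
            n_events += 1
    # hold the final state over any remaining grid points
    while rec_i <= n_rec:
        out[rec_i] = counts
        rec_i += 1
    return times, out, n_events, stalled


@njit(cache=True)
def benettin_kernel(y0, p, sig, delta0, tau, n_blocks, dt, transient):
    """Two-trajectory Benettin method: per-block ln separation growth.

    Integrates a reference and a copy perturbed by delta0 in Nn; every tau
    minutes the separation is renormalised to delta0 and ln(growth) recorded.
    """
    y = y0.copy()
    n_tr = int(round(transient / dt))
    for s in range(n_tr):
        _rk4_step(y, s * dt, dt, p, sig)
    t0 = n_tr * dt
    z = y.copy()
    z[0] += delta0
    logs = np.empty(n_blocks)
    n_sub = int(round(tau / dt))
    for b in range(n_blocks):
        tb = t0 + b * n_sub * dt
        for s in range(n_sub):
            _rk4_step(y, tb + s * dt, dt, p, sig)
            _rk4_step(z, tb + s * dt, dt, p, sig)
        d2 = 0.0
        for k in range(5):
            d2 += (z[k] - y[k]) ** 2
        d = np.sqrt(d2)
        if d <= 0.0:
            d = 1e-300
        logs[b] = np.log(d / delta0)
        scale = delta0 / d
        for k in range(5):
            z[k] = y[k] + (z[k] - y[k]) * scale
    return logs


@njit(cache=True)
def gene_kernel(N_half, dt, K, h, gamma, delta, Gamma, Delta, m0, P0):
    """RK4 for one gene's mRNA/protein pair driven by N(t).

    ``N_half`` holds the NF-κB input sampled at dt/2 (2n+1 points for n
    steps), so every RK4 sub-stage uses an exact sample.
    """
    n = (N_half.shape[0] - 1) // 2
    m_out = np.empty(n + 1)
    P_out = np.empty(n + 1)
    m = m0
    P = P0
    m_out[0] = m
    P_out[0] = P
    for i in range(n):
        N1 = N_half[2 * i]
        N2 = N_half[2 * i + 1]
        N4 = N_half[2 * i + 2]
        h1 = N1 ** h / (K ** h + N1 ** h) if N1 > 0 else 0.0
        h2 = N2 ** h / (K ** h + N2 ** h) if N2 > 0 else 0.0
        h4 = N4 ** h / (K ** h + N4 ** h) if N4 > 0 else 0.0
        # stage derivatives for (m, P)
        am = gamma * h1 - delta * m
        aP = Gamma * m - Delta * P
        bm = gamma * h2 - delta * (m + 0.5 * dt * am)
        bP = Gamma * (m + 0.5 * dt * am) - Delta * (P + 0.5 * dt * aP)
        cm = gamma * h2 - delta * (m + 0.5 * dt * bm)
        cP = Gamma * (m + 0.5 * dt * bm) - Delta * (P + 0.5 * dt * bP)
        dm = gamma * h4 - delta * (m + dt * cm)
        dP = Gamma * (m + dt * cm) - Delta * (P + dt * cP)
        m += dt * (am + 2 * bm + 2 * cm + dm) / 6.0
        P += dt * (aP + 2 * bP + 2 * cP + dP) / 6.0
        m_out[i + 1] = m
        P_out[i + 1] = P
    return m_out, P_out
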