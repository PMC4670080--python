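"""Numba fast path for the depth-0 (Markov) tract-model likelihood.

The model-selection calibration refits both nested models on thousands of
simulated cohorts, so the composite likelihood must evaluate in tens of
microseconds.  This module re-implements, for the standard three-ancestry
models, the chain construction and the phase-type bin expectations using
a Taylor-series propagation of ``e^{A h}`` and its first two running
integrals (no eigendecomposition, stable for defective generators).  The
generic numpy implementation in :mod:`admixkit.model` remains the
reference; equality of the two paths is asserted in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 1e-9


@njit(cache=True)
def _props_of_rates(rates):
    G0 = rates.shape[0] - 1
    a = np.zeros(3)
    surv = 1.0
    for t in range(2, G0 + 1):
        M = rates[t, 0] + rates[t, 1] + rates[t, 2]
        for p in range(3):
            a[p] += rates[t, p] * surv
        surv *= 1.0 - M
    return a


@njit(cache=True)
def _assemble(G0, phi0, fa, wa, has_pulse, pulse_pop, fp, wp, m_pulse, mA, fE, rates):
    rates[:] = 0.0
    rates[G0, 0] = fE
    rates[G0, 1] = 1.0 - fE
    if phi0 > _EPS:
        rates[G0 - 1, 0] += (1.0 - phi0) * fE
        rates[G0 - 1, 1] += (1.0 - phi0) * (1.0 - fE)
    rates[fa, 2] += (1.0 - wa) * mA
    if wa > _EPS:
        rates[fa + 1, 2] += wa * mA
    if has_pulse:
        rates[fp, pulse_pop] += (1.0 - wp) * m_pulse
        if wp > _EPS:
            rates[fp + 1, pulse_pop] += wp * m_pulse


@njit(cache=True)
def build_rates(model_code, t0, t_afr, t_pulse, m_pulse, pE, pN, pA):
    """Discretised migration-rate table for a model parameterisation.

    ``model_code``: 0 = base, 1 = base+eur_pulse, 2 = base+afr_pulse.
    Returns ``(rates, ok)``; ``ok`` is False for infeasible parameters.
    """
    bad = np.zeros((3, 3))
    if not (t_afr > 1.0 and t_afr < t0):
        return bad, False
    G0 = int(math.ceil(t0 - _EPS))
    if G0 < 2 or G0 > 60:
        return bad, False
    phi0 = t0 - math.floor(t0 + _EPS)
    fa = int(math.floor(t_afr + _EPS))
    wa = t_afr - fa
    if fa < 2 or (fa + (1 if wa > _EPS else 0)) >= G0:
        return bad, False
    has_pulse = model_code > 0
    pulse_pop = 0 if model_code == 1 else 2
    fp = 2
    wp = 0.0
    if has_pulse:
        if not (t_pulse > 1.0 and t_pulse < t0):
            return bad, False
        if m_pulse < 0.0 or m_pulse > 1.0:
            return bad, False
        fp = int(math.floor(t_pulse + _EPS))
        wp = t_pulse - fp
        if fp < 2 or (fp + (1 if wp > _EPS else 0)) >= G0:
            return bad, False
    rates = np.zeros((G0 + 1, 3))
    # a_AFR(mA) is quadratic in mA; fit it exactly through 3 points
    h0 = h1 = h2 = 0.0
    for k in range(3):
        _assemble(G0, phi0, fa, wa, has_pulse, pulse_pop, fp, wp, m_pulse, 0.5 * k, 0.5, rates)
        v = _props_of_rates(rates)[2]
        if k == 0:
            h0 = v
        elif k == 1:
            h1 = v
        else:
            h2 = v
    qa = 2.0 * h2 + 2.0 * h0 - 4.0 * h1
    qb = h2 - h0 - qa
    qc = h0 - pA
    mA = np.nan
    if abs(qa) < 1e-12:
        if abs(qb) < 1e-12:
            if abs(qc) < 1e-10:
                mA = 0.0
        else:
            mA = -qc / qb
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc >= 0.0:
            r1 = (-qb + math.sqrt(disc)) / (2.0 * qa)
            r2 = (-qb - math.sqrt(disc)) / (2.0 * qa)
            lo = min(r1, r2)
            hi = max(r1, r2)
            if -1e-10 <= lo <= 1.0 + 1e-10:
                mA = lo
            elif -1e-10 <= hi <= 1.0 + 1e-10:
                mA = hi
    if not (mA == mA) or mA < -1e-10 or mA > 1.0 + 1e-10:
        return bad, False
    mA = min(max(mA, 0.0), 1.0)
    _assemble(G0, phi0, fa, wa, has_pulse, pulse_pop, fp, wp, m_pulse, mA, 0.0, rates)
    g0v = _props_of_rates(rates)[1]
    _assemble(G0, phi0, fa, wa, has_pulse, pulse_pop, fp, wp, m_pulse, mA, 1.0, rates)
    g1v = _props_of_rates(rates)[1]
    if abs(g1v - g0v) < 1e-12:
        return bad, False
    fE = (pN - g0v) / (g1v - g0v)
    if fE < -1e-10 or fE > 1.0 + 1e-10:
        return bad, False
    fE = min(max(fE, 0.0), 1.0)
    _assemble(G0, phi0, fa, wa, has_pulse, pulse_pop, fp, wp, m_pulse, mA, fE, rates)
    for t in range(2, G0):
        if rates[t, 0] + rates[t, 1] + rates[t, 2] > 1.0 + 1e-9:
            return bad, False
    a = _props_of_rates(rates)
    if abs(a[0] - pE) > 1e-8:
        return bad, False
    return rates, True


@njit(cache=True)
def chain0(rates):
    """Depth-0 ancestry chain: state ancestries, stationary weights and
    the per-Morgan generator (matches ``ancestry_chain(..., depth=0)``)."""
    G0 = rates.shape[0] - 1
    S = 0
    for t in range(2, G0 + 1):
        for p in range(3):
            if rates[t, p] > 0.0:
                S += 1
    st_t = np.empty(S, np.int64)
    st_p = np.empty(S, np.int64)
    j = 0
    for t in range(2, G0 + 1):
        for p in range(3):
            if rates[t, p] > 0.0:
                st_t[j] = t
                st_p[j] = p
                j += 1
    M = np.zeros(G0 + 1)
    for t in range(G0 + 1):
        M[t] = rates[t, 0] + rates[t, 1] + rates[t, 2]
    fresh = np.zeros((G0 + 2, S))
    for g in range(2, G0 + 1):
        for j in range(S):
            u = st_t[j]
            if u >= g:
                prod = 1.0
                for s in range(g, u):
                    prod *= 1.0 - M[s]
                fresh[g, j] = rates[u, st_p[j]] * prod
    pi = fresh[2].copy()
    Q = np.zeros((S, S))
    for i in range(S):
        t = st_t[i]
        tot = 0.0
        for g in range(3, t + 1):
            for j in range(S):
                Q[i, j] += fresh[g, j]
        Q[i, i] = 0.0
        for j in range(S):
            if j != i:
                tot += Q[i, j]
        Q[i, i] = -tot
    return st_p, pi, Q


@njit(cache=True)
def _taylor_EFF(A, h, E, F0, F00, F000):
    """``E = e^{Ah}``, ``F0 = int_0^h e^{As} ds``, ``F00 = int_0^h F0``,
    ``F000 = int_0^h F00`` by Taylor series in ``A h``; the caller keeps
    ``||A|| h`` below ~1.5 so ~20 terms reach machine precision."""
    S = A.shape[0]
    for i in range(S):
        for j in range(S):
            d = 1.0 if i == j else 0.0
            E[i, j] = d
            F0[i, j] = h * d
            F00[i, j] = 0.5 * h * h * d
            F000[i, j] = h * h * h / 6.0 * d
    term = np.eye(S)
    nxt = np.empty((S, S))
    for k in range(1, 26):
        c = h / k
        for i in range(S):
            for j in range(S):
                acc = 0.0
                for l in range(S):
                    acc += term[i, l] * A[l, j]
                nxt[i, j] = acc * c
        mx = 0.0
        c1 = h / (k + 1)
        c2 = h * h / ((k + 1) * (k + 2))
        c3 = h * h * h / ((k + 1) * (k + 2) * (k + 3))
        for i in range(S):
            for j in range(S):
                t = nxt[i, j]
                term[i, j] = t
                E[i, j] += t
                F0[i, j] += t * c1
                F00[i, j] += t * c2
                F000[i, j] += t * c3
                if abs(t) > mx:
                    mx = abs(t)
        if mx < 1e-16:
            break


@njit(cache=True)
def _class_counts(A, alpha0, beta, r, xs, L, cum, mass):
    """Cumulative tract counts and first-moment length mass at the points
    ``xs`` (ascending, clipped at L, last element == L) for one ancestry
    class; returns the whole-chromosome expectation.  All quantities per
    haplotype, lengths in Morgans.

    Tracks ``F0(x) v``, ``F00(x) v``, ``F000(x) v`` for ``v in (r, 1)``
    via the composition identities F0(x+h) = F0_h + E_h F0(x) etc., so no
    eigendecomposition is needed and defective generators are handled."""
    S = A.shape[0]
    anorm = 0.0
    for i in range(S):
        s = 0.0
        for j in range(S):
            s += abs(A[i, j])
        if s > anorm:
            anorm = s
    vec = np.zeros((6, S))  # F0r, F00r, F000r, F01, F001, E1
    vec[5] = 1.0
    new = np.empty((6, S))
    E = np.empty((S, S))
    F0 = np.empty((S, S))
    F00 = np.empty((S, S))
    F000 = np.empty((S, S))
    step = np.empty((5, S))  # F0_h r, F00_h r, F000_h r, F0_h 1, F00_h 1
    h_cached = -1.0
    x = 0.0
    for k in range(xs.size):
        target = xs[k]
        if target > x + 1e-15:
            n_sub = int(anorm * (target - x) / 1.5) + 1
            h = (target - x) / n_sub
            if abs(h - h_cached) > 1e-13:
                _taylor_EFF(A, h, E, F0, F00, F000)
                for i in range(S):
                    a0 = a1 = a2 = a3 = a4 = 0.0
                    for j in range(S):
                        a0 += F0[i, j] * r[j]
                        a1 += F00[i, j] * r[j]
                        a2 += F000[i, j] * r[j]
                        a3 += F0[i, j]
                        a4 += F00[i, j]
                    step[0, i] = a0
                    step[1, i] = a1
                    step[2, i] = a2
                    step[3, i] = a3
                    step[4, i] = a4
                h_cached = h
            for _ in range(n_sub):
                x2 = 0.5 * x * x
                for i in range(S):
                    e0 = e1 = e2 = e3 = e4 = e5 = 0.0
                    for j in range(S):
                        eij = E[i, j]
                        e0 += eij * vec[0, j]
                        e1 += eij * vec[1, j]
                        e2 += eij * vec[2, j]
                        e3 += eij * vec[3, j]
                        e4 += eij * vec[4, j]
                        e5 += eij * vec[5, j]
                    new[0, i] = step[0, i] + e0
                    new[1, i] = step[1, i] + x * step[0, i] + e1
                    new[2, i] = step[2, i] + x * step[1, i] + x2 * step[0, i] + e2
                    new[3, i] = step[3, i] + e3
                    new[4, i] = step[4, i] + x * step[3, i] + e4
                    new[5, i] = e5
                for i in range(S):
                    for q in range(6):
                        vec[q, i] = new[q, i]
                x += h
            x = target
        c = 0.0
        m = 0.0
        for i in range(S):
            f0r = vec[0, i]
            f00r = vec[1, i]
            f000r = vec[2, i]
            i1r = x * f0r - f00r
            i2r = x * x * f0r - 2.0 * x * f00r + 2.0 * f000r
            i11 = x * vec[3, i] - vec[4, i]
            c += beta[i] * ((L - x) * f0r + f00r) + beta[i] * vec[3, i] + alpha0[i] * f0r
            m += beta[i] * (L * i1r - i2r) + beta[i] * i11 + alpha0[i] * i1r
        cum[k] = c
        mass[k] = m
    whole = 0.0
    for i in range(S):
        whole += alpha0[i] * vec[5, i]
    return whole


@njit(cache=True)
def expected_mu(rates, edgesM, uniqL, nrepL, n_haplotypes):
    """Expected bin counts ``mu`` (3, B), whole-chromosome expectations
    per unique chromosome length (3, nL) and total length mass in Morgans
    (3,) under the depth-0 chain."""
    st_p, pi, Q = chain0(rates)
    S = st_p.size
    B = edgesM.size
    nL = uniqL.size
    mu = np.zeros((3, B))
    fullmu = np.zeros((3, nL))
    mass = np.zeros(3)
    cum = np.empty(B + 1)
    mss = np.empty(B + 1)
    xs = np.empty(B + 1)
    for p in range(3):
        np_cls = 0
        for i in range(S):
            if st_p[i] == p:
                np_cls += 1
        if np_cls == 0:
            continue
        idx = np.empty(np_cls, np.int64)
        j = 0
        for i in range(S):
            if st_p[i] == p:
                idx[j] = i
                j += 1
        A = np.empty((np_cls, np_cls))
        alpha0 = np.empty(np_cls)
        beta = np.zeros(np_cls)
        for a in range(np_cls):
            alpha0[a] = pi[idx[a]]
            for b in range(np_cls):
                A[a, b] = Q[idx[a], idx[b]]
            for i in range(S):
                if st_p[i] != p:
                    beta[a] += pi[i] * Q[i, idx[a]]
        r = np.zeros(np_cls)
        for a in range(np_cls):
            rowsum = 0.0
            for b in range(np_cls):
                rowsum += A[a, b]
            r[a] = -rowsum
        for li in range(nL):
            L = uniqL[li]
            for k in range(B):
                xs[k] = edgesM[k] if edgesM[k] < L else L
            xs[B] = L
            whole = _class_counts(A, alpha0, beta, r, xs, L, cum, mss)
            for k in range(B):
                mu[p, k] += nrepL[li] * n_haplotypes * (cum[k + 1] - cum[k])
            fullmu[p, li] = n_haplotypes * whole
            mass[p] += nrepL[li] * n_haplotypes * (mss[B] + whole * L)
    return mu, fullmu, mass


@njit(cache=True)
def loglike0(
    model_code,
    t0,
    t_afr,
    t_pulse,
    m_pulse,
    props,
    edgesM,
    uniqL,
    nrepL,
    n_haplotypes,
    obs_counts,
    obs_full_sum,
    obs_full_lgam,
    obs_bin_lgam,
):
    """Poisson composite log-likelihood of an observed spectrum under a
    model parameterisation; -1e18 when parameters are infeasible or a
    zero-expectation cell has observations.

    ``obs_full_sum``/``obs_full_lgam`` aggregate the per-chromosome
    whole-chromosome cells over chromosomes of identical length (their
    expected counts coincide); ``obs_bin_lgam`` is the constant
    ``sum ln o!`` over the bin cells.
    """
    rates, ok = build_rates(
        model_code, t0, t_afr, t_pulse, m_pulse, props[0], props[1], props[2]
    )
    if not ok:
        return -1e18
    mu, fullmu, _mass = expected_mu(rates, edgesM, uniqL, nrepL, n_haplotypes)
    ll = -obs_bin_lgam
    for p in range(3):
        for k in range(edgesM.size):
            m = mu[p, k]
            o = obs_counts[p, k]
            if m > 0.0:
                ll += o * math.log(m) - m
            elif o > 0:
                return -1e18
        for li in range(uniqL.size):
            m = fullmu[p, li]
            o = obs_full_sum[p, li]
            if m > 0.0:
                ll += o * math.log(m) - nrepL[li] * m - obs_full_lgam[p, li]
            elif o > 0:
                return -1e18
            else:
                ll -= nrepL[li] * m
    return ll
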