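"""Numba kernels for the ODE and Gillespie engines.

These are jitted twins of the reference rate-law evaluators in
:mod:`p53combo.network`; a unit test pins them against each other.  The
stoichiometry is carried in compressed form (ptr/species/delta triplets)
so that the inner loops touch only species a reaction actually changes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

REG_NONE, REG_HILL, REG_INHIB, REG_POW = 0, 1, 2, 3


@njit(cache=True, inline="always")
def _reg_factor(kind, x, K, n):
    if kind == REG_NONE:
        return 1.0
    if x < 0.0:
        x = 0.0
    if kind == REG_POW:
        return (x / K) ** n
    xn = (x / K) ** n
    if kind == REG_HILL:
        return xn / (1.0 + xn)
    return 1.0 / (1.0 + xn)  # REG_INHIB


@njit(cache=True)
def flux_vector(y, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n, out):
    """Deterministic per-reaction fluxes (concentration rate laws)."""
    for j in range(k.shape[0]):
        v = k[j]
        for m in range(ma_idx.shape[1]):
            i = ma_idx[j, m]
            if i >= 0:
                x = y[i]
                if x < 0.0:
                    x = 0.0
                v *= x
        for m in range(reg_idx.shape[1]):
            i = reg_idx[j, m]
            if i >= 0:
                v *= _reg_factor(reg_kind[j, m], y[i], reg_K[j, m], reg_n[j, m])
        out[j] = v


@njit(cache=True)
def propensity_vector(y, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
                      discrete_sp, out):
    """Stochastic propensities: falling factorials on discrete species."""
    for j in range(k.shape[0]):
        a = k[j]
        for m in range(ma_idx.shape[1]):
            i = ma_idx[j, m]
            if i >= 0:
                x = y[i]
                if discrete_sp[i]:
                    # subtract one per previous occurrence of the same species
                    r = 0.0
                    for mm in range(m):
                        if ma_idx[j, mm] == i:
                            r += 1.0
                    x = x - r
                if x < 0.0:
                    x = 0.0
                a *= x
        for m in range(reg_idx.shape[1]):
            i = reg_idx[j, m]
            if i >= 0:
                a *= _reg_factor(reg_kind[j, m], y[i], reg_K[j, m], reg_n[j, m])
        out[j] = a


@njit(cache=True)
def _apply_stoich(y, j, st_ptr, st_sp, st_dl, scale):
    for p in range(st_ptr[j], st_ptr[j + 1]):
        y[st_sp[p]] += scale * st_dl[p]


@njit(cache=True)
def _rhs(y, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
         st_ptr, st_sp, st_dl, flux, dy):
    flux_vector(y, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n, flux)
    for i in range(dy.shape[0]):
        dy[i] = 0.0
    for j in range(k.shape[0]):
        f = flux[j]
        for p in range(st_ptr[j], st_ptr[j + 1]):
            dy[st_sp[p]] += st_dl[p] * f


@njit(cache=True)
def _rk4_advance(y, t_span, dt, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
                 st_ptr, st_sp, st_dl, buf):
    """Advance y in place over t_span seconds with fixed-step RK4
    (final partial step shortened), clamping at zero."""
    n = y.shape[0]
    k1, k2, k3, k4, yt, flux = buf
    remaining = t_span
    while remaining > 1e-12:
        h = dt if remaining > dt else remaining
        _rhs(y, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
             st_ptr, st_sp, st_dl, flux, k1)
        for i in range(n):
            yt[i] = y[i] + 0.5 * h * k1[i]
        _rhs(yt, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
             st_ptr, st_sp, st_dl, flux, k2)
        for i in range(n):
            yt[i] = y[i] + 0.5 * h * k2[i]
        _rhs(yt, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
             st_ptr, st_sp, st_dl, flux, k3)
        for i in range(n):
            yt[i] = y[i] + h * k3[i]
        _rhs(yt, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
             st_ptr, st_sp, st_dl, flux, k4)
        for i in range(n):
            y[i] += h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if y[i] < 0.0:
                y[i] = 0.0
        remaining -= h


@njit(cache=True)
def ode_segment(y, t0, t1, dt, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
                st_ptr, st_sp, st_dl, sample_t, out, out_row0):
    """Integrate [t0, t1], writing states at the (absolute, sorted) sample
    times contained in the segment into ``out`` starting at ``out_row0``.
    Returns the number of samples written."""
    n = y.shape[0]
    buf = (np.empty(n), np.empty(n), np.empty(n), np.empty(n), np.empty(n),
           np.empty(k.shape[0]))
    t = t0
    written = 0
    for s in range(sample_t.shape[0]):
        ts = sample_t[s]
        if ts < t0 - 1e-9 or ts > t1 + 1e-9:
            continue
        if ts > t:
            _rk4_advance(y, ts - t, dt, k, ma_idx, reg_idx, reg_kind, reg_K,
                         reg_n, st_ptr, st_sp, st_dl, buf)
            t = ts
        for i in range(n):
            out[out_row0 + written, i] = y[i]
        written += 1
    if t1 > t:
        _rk4_advance(y, t1 - t, dt, k, ma_idx, reg_idx, reg_kind, reg_K,
                     reg_n, st_ptr, st_sp, st_dl, buf)
    return written


EV_IRRADIATE, EV_DOSE, EV_INFUSION = 0, 1, 2


@njit(cache=True)
def euler_fast(y, t_span, dt, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
               st_ptr, st_sp, st_dl, fast_rxn, flux):
    """Advance the scalable (high-copy) layer by explicit Euler over t_span,
    holding discrete species fixed (their reactions are excluded)."""
    remaining = t_span
    while remaining > 1e-12:
        h = dt if remaining > dt else remaining
        flux_vector(y, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n, flux)
        for jj in range(fast_rxn.shape[0]):
            j = fast_rxn[jj]
            f = flux[j] * h
            for p in range(st_ptr[j], st_ptr[j + 1]):
                i = st_sp[p]
                y[i] += st_dl[p] * f
                if y[i] < 0.0:
                    y[i] = 0.0
        remaining -= h


@njit(cache=True)
def hybrid_ssa_run(
    y0, k_in, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
    st_ptr, st_sp, st_dl,
    discrete_sp,        # (n_species,) bool: exact-SSA species
    disc_rxn,           # indices of reactions handled by exact SSA
    fast_rxn,           # indices of reactions advanced deterministically
    ev_t, ev_kind, ev_mag,   # protocol events (seconds, kind codes, magnitudes)
    dsb_idx, depot_idx, inf_rxn_idx, dsb_per_gy, poisson_ir,
    t_end, dt_fast, cap,
    commit_idx, commit_thr, stop_on_commit,
    seed,
    sample_t, out,      # thinned trajectory (may be empty)
):
    """One seeded hybrid Gillespie run with protocol events.

    Exact SSA over ``disc_rxn`` with propensities frozen over steps capped at
    ``cap`` seconds; ``fast_rxn`` advanced by Euler with step ``dt_fast``.
    With all species marked discrete and ``fast_rxn`` restricted to the
    drug pools this is the exact-SSA reference path.
    Returns (committed, commit_time_s, n_samples_written, y_final).
    """
    np.random.seed(seed)
    n = y0.shape[0]
    y = y0.copy()
    k = k_in.copy()
    n_r = k.shape[0]
    flux = np.empty(n_r)
    prop = np.empty(n_r)
    committed = False
    commit_time = -1.0

    t = 0.0
    ev_i = 0
    s_i = 0
    written = 0
    n_ev = ev_t.shape[0]
    n_samp = sample_t.shape[0]

    while True:
        # next hard stop: protocol event, sample point, or horizon
        stop = t_end
        is_event = False
        is_sample = False
        if ev_i < n_ev and ev_t[ev_i] <= stop + 1e-9:
            stop = ev_t[ev_i]
            is_event = True
        if s_i < n_samp and sample_t[s_i] <= stop + 1e-9:
            if sample_t[s_i] < stop - 1e-9:
                is_event = False
            stop = sample_t[s_i]
            is_sample = True

        # advance to the stop with capped-step SSA + fast layer
        while t < stop - 1e-9 and not (committed and stop_on_commit):
            propensity_vector(y, k, ma_idx, reg_idx, reg_kind, reg_K, reg_n,
                              discrete_sp, prop)
            a_sum = 0.0
            for jj in range(disc_rxn.shape[0]):
                a_sum += prop[disc_rxn[jj]]
            window = stop - t
            if window > cap:
                window = cap
            if a_sum > 0.0:
                tau = np.random.exponential(1.0 / a_sum)
            else:
                tau = window + 1.0
            if tau < window:
                euler_fast(y, tau, dt_fast, k, ma_idx, reg_idx, reg_kind,
                           reg_K, reg_n, st_ptr, st_sp, st_dl, fast_rxn, flux)
                # choose and fire a discrete reaction
                r = np.random.random() * a_sum
                acc = 0.0
                jfire = disc_rxn[disc_rxn.shape[0] - 1]
                for jj in range(disc_rxn.shape[0]):
                    acc += prop[disc_rxn[jj]]
                    if acc >= r:
                        jfire = disc_rxn[jj]
                        break
                _apply_stoich(y, jfire, st_ptr, st_sp, st_dl, 1.0)
                for i in range(n):
                    if y[i] < 0.0:
                        y[i] = 0.0
                t += tau
            else:
                euler_fast(y, window, dt_fast, k, ma_idx, reg_idx, reg_kind,
                           reg_K, reg_n, st_ptr, st_sp, st_dl, fast_rxn, flux)
                t += window
            if not committed and y[commit_idx] >= commit_thr:
                committed = True
                commit_time = t
        t = stop

        if is_event and ev_i < n_ev and abs(ev_t[ev_i] - stop) <= 1e-9:
            while ev_i < n_ev and abs(ev_t[ev_i] - stop) <= 1e-9:
                kind = ev_kind[ev_i]
                mag = ev_mag[ev_i]
                if kind == EV_IRRADIATE:
                    mean = mag * dsb_per_gy
                    if poisson_ir:
                        y[dsb_idx] += np.random.poisson(mean)
                    else:
                        y[dsb_idx] += mean
                elif kind == EV_DOSE:
                    y[depot_idx] += mag
                else:  # infusion on: IC50/day -> IC50/s
                    k[inf_rxn_idx] = mag / 86400.0
                ev_i += 1
        if is_sample and s_i < n_samp and abs(sample_t[s_i] - stop) <= 1e-9:
            for i in range(n):
                out[written, i] = y[i]
            written += 1
            s_i += 1
        if not committed and y[commit_idx] >= commit_thr:
            committed = True
            commit_time = t
        if stop >= t_end - 1e-9 or (committed and stop_on_commit):
            break

    return committed, commit_time, written, y
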