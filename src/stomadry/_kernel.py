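"""Fixed-step RK4 integrator for the two-compartment drying ODEs.

The system is piecewise smooth: the leaf loss coefficient k2 jumps at every
light/dark transition and the soil uptake coefficient k1 switches off
irreversibly at the wilting event.  Integration therefore proceeds segment by
segment between light transitions (so no step straddles a k2 jump) and the
wilting crossing is located inside a step and used to split it.

Two cumulative loss integrals (leaf transpiration and soil evaporation) are
carried as extra states, so water-budget closure can be checked to solver
accuracy from the output alone.

The kernel is numba-compiled; a single simulation of a two-week drying run
takes on the order of a millisecond, which is what makes per-plant
least-squares fitting with multi-start affordable.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _k2_at(t, t0, period, bright, k2_os, k2_cs, tau, gamma, wilted, wilt_mult,
           day_mult):
    """Piecewise stomatal loss coefficient at absolute time t (hours)."""
    phase = (t - t0) % period
    if phase < bright:
        day = int(math.floor((t - t0) / period))
        if day < 0:
            day = 0
        m = 1.0
        if day_mult.size > 0:
            idx = day if day < day_mult.size else day_mult.size - 1
            m = day_mult[idx]
        k2 = (k2_os * m - k2_cs) * math.exp(-phase / tau) + k2_cs
    else:
        k2 = gamma * k2_cs
    if wilted:
        k2 *= wilt_mult
    return k2


@njit(cache=True)
def _k1_at(a_l, a_s, k2, k1_max, wilted):
    if wilted:
        return 0.0
    if a_s > a_l:
        demand = k2 * a_l / (a_s - a_l)
        return demand if demand < k1_max else k1_max
    return k1_max


@njit(cache=True)
def _rhs(t, a_l, a_s, t0, period, bright, k1_max, k3, k2_os, k2_cs, tau,
         gamma, wilted, wilt_mult, day_mult):
    k2 = _k2_at(t, t0, period, bright, k2_os, k2_cs, tau, gamma, wilted,
                wilt_mult, day_mult)
    k1 = _k1_at(a_l, a_s, k2, k1_max, wilted)
    flow = k1 * (a_s - a_l)
    d_al = flow - k2 * a_l
    d_as = -flow - k3 * a_s
    d_cl = k2 * a_l       # cumulative leaf transpiration
    d_cs = k3 * a_s       # cumulative soil evaporation
    return d_al, d_as, d_cl, d_cs


@njit(cache=True)
def _rk4_step(t, h, a_l, a_s, c_l, c_s, t0, period, bright, k1_max, k3,
              k2_os, k2_cs, tau, gamma, wilted, wilt_mult, day_mult):
    k1a, k1b, k1c, k1d = _rhs(t, a_l, a_s, t0, period, bright, k1_max, k3,
                              k2_os, k2_cs, tau, gamma, wilted, wilt_mult,
                              day_mult)
    k2a, k2b, k2c, k2d = _rhs(t + 0.5 * h, a_l + 0.5 * h * k1a,
                              a_s + 0.5 * h * k1b, t0, period, bright,
                              k1_max, k3, k2_os, k2_cs, tau, gamma, wilted,
                              wilt_mult, day_mult)
    k3a, k3b, k3c, k3d = _rhs(t + 0.5 * h, a_l + 0.5 * h * k2a,
                              a_s + 0.5 * h * k2b, t0, period, bright,
                              k1_max, k3, k2_os, k2_cs, tau, gamma, wilted,
                              wilt_mult, day_mult)
    k4a, k4b, k4c, k4d = _rhs(t + h, a_l + h * k3a, a_s + h * k3b, t0,
                              period, bright, k1_max, k3, k2_os, k2_cs, tau,
                              gamma, wilted, wilt_mult, day_mult)
    a_l_new = a_l + h / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
    a_s_new = a_s + h / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
    c_l_new = c_l + h / 6.0 * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
    c_s_new = c_s + h / 6.0 * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)
    if a_l_new < 0.0:
        a_l_new = 0.0
    if a_s_new < 0.0:
        a_s_new = 0.0
    return a_l_new, a_s_new, c_l_new, c_s_new


@njit(cache=True)
def integrate(seg_bounds, n_sub, k1_max, k3, k2_os, k2_cs, tau, gamma,
              theta_wilt, a_l0, a_s0, period, bright, t0, wilt_mult,
              day_mult):
    """Integrate over segments; returns dense state arrays and wilt time.

    seg_bounds : (n_seg + 1,) segment boundary times in hours
    n_sub      : (n_seg,) RK4 substeps per segment
    Returns (t, a_l, a_s, k1, k2, cum_leaf, cum_soil, wilt_time); wilt_time
    is negative if the wilting point is never reached.
    """
    n_total = 1
    for i in range(n_sub.size):
        n_total += n_sub[i]

    t_out = np.empty(n_total)
    al_out = np.empty(n_total)
    as_out = np.empty(n_total)
    k1_out = np.empty(n_total)
    k2_out = np.empty(n_total)
    cl_out = np.empty(n_total)
    cs_out = np.empty(n_total)

    a_l = a_l0
    a_s = a_s0
    c_l = 0.0
    c_s = 0.0
    wilted = a_s0 <= theta_wilt
    wilt_time = 0.0 if wilted else -1.0

    idx = 0
    t_out[0] = seg_bounds[0]
    al_out[0] = a_l
    as_out[0] = a_s
    cl_out[0] = c_l
    cs_out[0] = c_s
    k2_now = _k2_at(seg_bounds[0], t0, period, bright, k2_os, k2_cs, tau,
                    gamma, wilted, wilt_mult, day_mult)
    k2_out[0] = k2_now
    k1_out[0] = _k1_at(a_l, a_s, k2_now, k1_max, wilted)

    for s in range(n_sub.size):
        ta = seg_bounds[s]
        tb = seg_bounds[s + 1]
        h = (tb - ta) / n_sub[s]
        for j in range(n_sub[s]):
            t = ta + j * h
            na_l, na_s, nc_l, nc_s = _rk4_step(
                t, h, a_l, a_s, c_l, c_s, t0, period, bright, k1_max, k3,
                k2_os, k2_cs, tau, gamma, wilted, wilt_mult, day_mult)
            if (not wilted) and na_s < theta_wilt:
                # locate the crossing linearly, split the step there
                denom = a_s - na_s
                frac = (a_s - theta_wilt) / denom if denom > 0 else 0.0
                if frac < 0.0:
                    frac = 0.0
                if frac > 1.0:
                    frac = 1.0
                h1 = frac * h
                if h1 > 0.0:
                    a_l, a_s, c_l, c_s = _rk4_step(
                        t, h1, a_l, a_s, c_l, c_s, t0, period, bright,
                        k1_max, k3, k2_os, k2_cs, tau, gamma, wilted,
                        wilt_mult, day_mult)
                wilted = True
                wilt_time = t + h1
                h2 = h - h1
                if h2 > 0.0:
                    a_l, a_s, c_l, c_s = _rk4_step(
                        t + h1, h2, a_l, a_s, c_l, c_s, t0, period, bright,
                        k1_max, k3, k2_os, k2_cs, tau, gamma, wilted,
                        wilt_mult, day_mult)
            else:
                a_l, a_s, c_l, c_s = na_l, na_s, nc_l, nc_s
            idx += 1
            t_out[idx] = t + h
            al_out[idx] = a_l
            as_out[idx] = a_s
            cl_out[idx] = c_l
            cs_out[idx] = c_s
            k2_now = _k2_at(t + h, t0, period, bright, k2_os, k2_cs, tau,
                            gamma, wilted, wilt_mult, day_mult)
            k2_out[idx] = k2_now
            k1_out[idx] = _k1_at(a_l, a_s, k2_now, k1_max, wilted)

    return t_out, al_out, as_out, k1_out, k2_out, cl_out, cs_out, wilt_time
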