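"""Numba-compiled integration kernel for the three-unit ODE model.

Classical fourth-order Runge-Kutta with step-doubling local-error control:
each trial step is taken once at h and twice at h/2; the maximum per-variable
difference is the local error estimate, accepted against an absolute
tolerance.  Protocol breakpoints and output sample times are hard restart
points, so no internal step ever straddles a discontinuity of I(t).
"""

import numpy as np
from numba import njit

# Smallest admissible internal step before the integrator gives up (stiffness
# guard); far below anything the model produces with valid parameters.
H_MIN = 1e-10


@njit(cache=True)
def _deriv(s, I, active, tau_d, tau_s, tau_a, D, Ys, Ya, A, ds):
    """Right-hand side; weights follow the sign-case table of the model."""
    xd = s[0]
    xs = s[1]
    xa = s[2]
    # Diffusion weights splitting somatic efflux between dendrite and axon.
    if xd > 0.0 and xa < 0.0:
        wd = 0.0
        wa = 1.0
    elif xd < 0.0 and xa > 0.0:
        wd = 1.0
        wa = 0.0
    elif xd == 0.0 and xa == 0.0:
        wd = 0.0
        wa = 0.0
    elif xd == 0.0:
        wd = 0.0
        wa = 1.0
    elif xa == 0.0:
        if xd > 0.0:
            wd = 0.0
            wa = 1.0
        else:
            wd = 1.0
            wa = 0.0
    else:  # same strict sign, both nonzero
        tot = abs(xd) + abs(xa)
        if xd > 0.0:
            wd = abs(xa) / tot
            wa = abs(xd) / tot
        else:
            wd = abs(xd) / tot
            wa = abs(xa) / tot
    ds[0] = (-xd + s[3] + D * (wd * xs - xd) + I) / tau_d
    ds[1] = (-xs + Ys * s[4] + D * (xd + xa - xs)) / tau_s
    ds[2] = (-xa + Ya * s[5] + D * (wa * xs - xa)) / tau_a
    if active:
        ds[3] = -A * xd
        ds[4] = -A * xs
        ds[5] = -A * xa
    else:
        ds[3] = 0.0
        ds[4] = 0.0
        ds[5] = 0.0


@njit(cache=True)
def _rk4_step(s, h, I, active, tau_d, tau_s, tau_a, D, Ys, Ya, A,
              k1, k2, k3, k4, tmp, out):
    _deriv(s, I, active, tau_d, tau_s, tau_a, D, Ys, Ya, A, k1)
    for q in range(6):
        tmp[q] = s[q] + 0.5 * h * k1[q]
    _deriv(tmp, I, active, tau_d, tau_s, tau_a, D, Ys, Ya, A, k2)
    for q in range(6):
        tmp[q] = s[q] + 0.5 * h * k2[q]
    _deriv(tmp, I, active, tau_d, tau_s, tau_a, D, Ys, Ya, A, k3)
    for q in range(6):
        tmp[q] = s[q] + h * k3[q]
    _deriv(tmp, I, active, tau_d, tau_s, tau_a, D, Ys, Ya, A, k4)
    h6 = h / 6.0
    for q in range(6):
        out[q] = s[q] + h6 * (k1[q] + 2.0 * (k2[q] + k3[q]) + k4[q])


@njit(cache=True)
def integrate_kernel(ev_t, ev_I, ev_active, ev_reset, is_sample,
                     tau_d, tau_s, tau_a, D, Ys, Ya, A,
                     tol, h_max, out):
    """Integrate from the all-zero state across pre-built event intervals.

    ev_t        : event times (breakpoints + output samples), strictly increasing
    ev_I[i]     : input level on [ev_t[i], ev_t[i+1])
    ev_active[i]: whether the stimulation epoch is active on that interval
    ev_reset[i] : hard-reset y to 0 on arrival at ev_t[i] (epoch-end gate)
    is_sample[i]: record the state at ev_t[i] into the next output row
    out         : (n_samples, 6) output buffer

    Returns (status, t_fail): status 0 = success, 1 = step-size underflow.
    """
    s = np.zeros(6)
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    tmp = np.empty(6)
    y_full = np.empty(6)
    y_half = np.empty(6)
    y_two = np.empty(6)

    n_ev = ev_t.shape[0]
    j = 0
    h = h_max  # persists across intervals; only clipped at boundaries
    for i in range(n_ev):
        if ev_reset[i]:
            s[3] = 0.0
            s[4] = 0.0
            s[5] = 0.0
        if is_sample[i]:
            for q in range(6):
                out[j, q] = s[q]
            j += 1
        if i == n_ev - 1:
            break
        t0 = ev_t[i]
        t1 = ev_t[i + 1]
        I = ev_I[i]
        active = ev_active[i]
        t = t0
        while t < t1 - 1e-12:
            h_try = h
            if h_try > t1 - t:
                h_try = t1 - t
            while True:
                _rk4_step(s, h_try, I, active, tau_d, tau_s, tau_a, D, Ys, Ya, A,
                          k1, k2, k3, k4, tmp, y_full)
                hh = 0.5 * h_try
                _rk4_step(s, hh, I, active, tau_d, tau_s, tau_a, D, Ys, Ya, A,
                          k1, k2, k3, k4, tmp, y_half)
                _rk4_step(y_half, hh, I, active, tau_d, tau_s, tau_a, D, Ys, Ya, A,
                          k1, k2, k3, k4, tmp, y_two)
                err = 0.0
                for q in range(6):
                    e = abs(y_full[q] - y_two[q])
                    if e > err:
                        err = e
                if err <= tol:
                    break
                # shrink with safety factor; never below the underflow guard
                fac = 0.9 * (tol / err) ** 0.2
                if fac < 0.2:
                    fac = 0.2
                h_try *= fac
                if h_try < H_MIN:
                    return 1, t
            for q in range(6):
                s[q] = y_two[q]
            t += h_try
            # grow for the next attempt (bounded), based on the same estimate
            if err > 0.0:
                fac = 0.9 * (tol / err) ** 0.2
                if fac > 5.0:
                    fac = 5.0
            else:
                fac = 5.0
            h = h_try * fac
            if h > h_max:
                h = h_max
            if h < H_MIN:
                h = H_MIN
    return 0, ev_t[n_ev - 1]
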