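"""Fixed-step RK4 kernel for the five-state delay system (numba-compiled).

The two fixed time lags are realized with history buffers on the
integration grid: at every accepted step the gastric glucose outflow
flux, the stomach glucose mass and the plasma insulin concentration are
recorded; lagged lookups interpolate linearly between grid entries and
clamp to the filled range.  The gastric-outflow code is evaluated once
per step at the step midpoint, so a step never mixes two outflow regimes
as long as schedule breakpoints lie on the step grid.

The outflow flux jumps where the schedule switches, so its history keeps
both one-sided limits at every grid point: a history segment
interpolates from the right limit at its left end to the left limit at
its right end, and a stage evaluating exactly at a jump chooses the side
consistent with its step (the terminal stage of a step sees the left
limit, the initial stage the right limit).  This keeps the integrator's
formal order across schedule switches.

Lag conventions (``lag_conv``):

* 0 — exogenous glucose appearance replays the recorded outflow flux
  ``(k_SP * Gl_S)(t - T_lag_SP)``: a pure transport delay that conserves
  hexose mass (package default).
* 1 — the current ``k_SP`` multiplies the lagged stomach mass
  ``Gl_S(t - T_lag_SP)`` (alternative reading, exposed for robustness
  checks).

The kernel also integrates the cumulative exogenous appearance
``∫ PGl_ex dt`` as a sixth state so mass-conservation checks do not
depend on post-hoc quadrature of a discontinuous flux.
"""

import numpy as np
from numba import njit

# state vector layout
_AC_S, _AC_P, _GL_S, _GL_P, _IN_P, _CUM = 0, 1, 2, 3, 4, 5

# stage sides at a history grid point that is a jump
RIGHT = 1
LEFT = -1


@njit(cache=True)
def _lookup(hist_r, hist_l, n_filled, dt, tau, before_value, side):
    """Piecewise-linear history lookup honouring one-sided limits.

    ``hist_r``/``hist_l`` hold the right/left limits at grid times i*dt
    (equal for continuous signals).  ``tau`` < 0 returns
    ``before_value``; lookups past the filled range clamp to the newest
    entry (only reachable when a lag is shorter than one step).
    """
    if tau < 0.0:
        return before_value
    x = tau / dt
    i = int(x)
    frac = x - i
    # snap float noise onto the grid so jump sides resolve exactly
    if frac > 0.5:
        if (1.0 - frac) * dt < 1e-9:
            i += 1
            frac = 0.0
    elif frac * dt < 1e-9:
        frac = 0.0
    if i >= n_filled:
        return hist_r[n_filled]
    if frac == 0.0:
        if side == LEFT:
            # the onset of the replayed signal is itself a jump: a stage
            # belonging to the step left of tau=0 sees the pre-lag value
            return before_value if i == 0 else hist_l[i]
        return hist_r[i]
    return hist_r[i] * (1.0 - frac) + hist_l[i + 1] * frac


@njit(cache=True)
def _lookup_smooth(hist, n_filled, dt, tau, before_value, side):
    """Cubic-Lagrange history lookup for continuous, smooth signals.

    Falls back to linear interpolation near the buffer edges.  Keeps the
    integrator's order for the delayed insulin signal, whose curvature
    would otherwise dominate the global error through linear
    interpolation at the half-step stages.
    """
    if tau < 0.0:
        return before_value
    x = tau / dt
    i = int(x)
    frac = x - i
    if frac > 0.5:
        if (1.0 - frac) * dt < 1e-9:
            i += 1
            frac = 0.0
    elif frac * dt < 1e-9:
        frac = 0.0
    if i >= n_filled:
        return hist[n_filled]
    if frac == 0.0:
        if side == LEFT and i == 0:
            return before_value    # pre-onset limit of a delayed signal
        return hist[i]
    if i < 1 or i + 2 > n_filled:
        return hist[i] * (1.0 - frac) + hist[i + 1] * frac
    w = frac
    return (
        hist[i - 1] * (-w * (w - 1.0) * (w - 2.0) / 6.0)
        + hist[i] * ((w + 1.0) * (w - 1.0) * (w - 2.0) / 2.0)
        + hist[i + 1] * (-(w + 1.0) * w * (w - 2.0) / 2.0)
        + hist[i + 2] * ((w + 1.0) * w * (w - 1.0) / 6.0)
    )


@njit(cache=True)
def _deriv(
    y, k_sp, t_stage, side,
    outflow_r, outflow_l, gls_hist, cin_hist, n_filled, dt,
    lag_sp, lag_is, i_is, lag_conv,
    bw_vd_gi, k_ac_uac, k_gl_ugl, k_is_ugl, ipgl_end,
    v_pin, km_pin, exp_pin, k_in_uin,
):
    dy = np.empty(6)
    c_gl = y[_GL_P] / bw_vd_gi
    c_in = y[_IN_P] / bw_vd_gi

    # acetaminophen
    dy[_AC_S] = -k_sp * y[_AC_S]
    dy[_AC_P] = k_sp * y[_AC_S] - k_ac_uac * y[_AC_P]

    # stomach hexose
    dy[_GL_S] = -k_sp * y[_GL_S]

    # exogenous appearance: lagged outflow (or current k x lagged mass)
    tau = t_stage - lag_sp
    if tau < 0.0:
        pgl_ex = 0.0
    elif lag_conv == 0:
        pgl_ex = _lookup(outflow_r, outflow_l, n_filled, dt, tau, 0.0, side)
    else:
        pgl_ex = k_sp * _lookup_smooth(gls_hist, n_filled, dt, tau, 0.0, side)

    # insulin signal: lagged plasma insulin concentration (continuous)
    i_sig = _lookup_smooth(cin_hist, n_filled, dt, t_stage - lag_is, i_is,
                           side)

    u_gl = k_gl_ugl * c_gl + k_is_ugl * i_sig * c_gl
    dy[_GL_P] = pgl_ex + ipgl_end - u_gl

    # Hill secretion; continuous limit 0 as c_gl -> 0+
    if c_gl <= 0.0:
        p_in = 0.0
    else:
        arg = exp_pin * np.log(km_pin / c_gl)
        p_in = 0.0 if arg > 700.0 else v_pin / (1.0 + np.exp(arg))
    dy[_IN_P] = p_in - k_in_uin * c_in

    dy[_CUM] = pgl_ex
    return dy


@njit(cache=True)
def integrate(
    y0,                  # (5,) initial masses [Ac_S, Ac_P, Gl_S, Gl_P, In_P]
    n_steps,             # total RK4 steps
    dt,                  # step, min
    report_stride,       # record every this many steps
    z_edges,             # (m,) left edges of schedule intervals, min
    z_rates,             # (m,) k_SP per interval, 1/min
    lag_sp, lag_is, i_is, lag_conv,
    bw_vd_gi, bw_vd_ac, k_ac_uac, k_gl_ugl, k_is_ugl, ipgl_end,
    v_pin, km_pin, exp_pin, k_in_uin,
):
    """Integrate the delay system; returns reported grids and a status.

    Returns (times, states, pglex, isig, ok) where ``states`` is
    (n_rep, 6) including the cumulative-appearance auxiliary state, and
    ``ok`` is False when a state mass went negative beyond round-off.
    """
    n_rep = n_steps // report_stride + 1
    times = np.empty(n_rep)
    states = np.empty((n_rep, 6))
    pglex_rep = np.empty(n_rep)
    isig_rep = np.empty(n_rep)

    outflow_r = np.empty(n_steps + 1)
    outflow_l = np.empty(n_steps + 1)
    gls_hist = np.empty(n_steps + 1)
    cin_hist = np.empty(n_steps + 1)

    y = np.empty(6)
    y[:5] = y0
    y[_CUM] = 0.0

    m = len(z_edges)
    zi = 0

    # record t=0 (the dose lands at t=0; outflow starts under interval 0)
    outflow_r[0] = z_rates[0] * y[_GL_S]
    outflow_l[0] = outflow_r[0]
    gls_hist[0] = y[_GL_S]
    cin_hist[0] = y[_IN_P] / bw_vd_gi

    times[0] = 0.0
    states[0] = y
    isig_rep[0] = i_is if lag_is > 0.0 else cin_hist[0]
    pglex_rep[0] = 0.0 if lag_sp > 0.0 else outflow_r[0]
    rep = 1

    ok = True
    tol = -1e-12
    for n in range(n_steps):
        t = n * dt
        t_mid = t + 0.5 * dt
        # advance schedule pointer to the interval containing the midpoint
        while zi + 1 < m and z_edges[zi + 1] <= t_mid:
            zi += 1
        k_sp = z_rates[zi]

        k1 = _deriv(y, k_sp, t, RIGHT, outflow_r, outflow_l, gls_hist,
                    cin_hist, n, dt, lag_sp, lag_is, i_is, lag_conv,
                    bw_vd_gi, k_ac_uac, k_gl_ugl, k_is_ugl, ipgl_end,
                    v_pin, km_pin, exp_pin, k_in_uin)
        y2 = y + 0.5 * dt * k1
        k2 = _deriv(y2, k_sp, t_mid, RIGHT, outflow_r, outflow_l, gls_hist,
                    cin_hist, n, dt, lag_sp, lag_is, i_is, lag_conv,
                    bw_vd_gi, k_ac_uac, k_gl_ugl, k_is_ugl, ipgl_end,
                    v_pin, km_pin, exp_pin, k_in_uin)
        y3 = y + 0.5 * dt * k2
        k3 = _deriv(y3, k_sp, t_mid, RIGHT, outflow_r, outflow_l, gls_hist,
                    cin_hist, n, dt, lag_sp, lag_is, i_is, lag_conv,
                    bw_vd_gi, k_ac_uac, k_gl_ugl, k_is_ugl, ipgl_end,
                    v_pin, km_pin, exp_pin, k_in_uin)
        y4 = y + dt * k3
        k4 = _deriv(y4, k_sp, t + dt, LEFT, outflow_r, outflow_l, gls_hist,
                    cin_hist, n, dt, lag_sp, lag_is, i_is, lag_conv,
                    bw_vd_gi, k_ac_uac, k_gl_ugl, k_is_ugl, ipgl_end,
                    v_pin, km_pin, exp_pin, k_in_uin)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

        if (y[_AC_S] < tol or y[_AC_P] < tol or y[_GL_S] < tol
                or y[_GL_P] < tol or y[_IN_P] < tol):
            ok = False
            break

        t_next = t + dt
        # record history at the new grid point: left limit under the
        # step's interval, right limit under the interval at t_next
        outflow_l[n + 1] = k_sp * y[_GL_S]
        while zi + 1 < m and z_edges[zi + 1] <= t_next:
            zi += 1
        outflow_r[n + 1] = z_rates[zi] * y[_GL_S]
        gls_hist[n + 1] = y[_GL_S]
        cin_hist[n + 1] = y[_IN_P] / bw_vd_gi

        if (n + 1) % report_stride == 0:
            times[rep] = t_next
            states[rep] = y
            tau = t_next - lag_sp
            if tau < 0.0:
                pglex_rep[rep] = 0.0
            elif lag_conv == 0:
                pglex_rep[rep] = _lookup(outflow_r, outflow_l, n + 1, dt, tau,
                                         0.0, RIGHT)
            else:
                pglex_rep[rep] = z_rates[zi] * _lookup_smooth(
                    gls_hist, n + 1, dt, tau, 0.0, RIGHT
                )
            isig_rep[rep] = _lookup_smooth(cin_hist, n + 1, dt,
                                           t_next - lag_is, i_is, RIGHT)
            rep += 1

    return times[:rep], states[:rep], pglex_rep[:rep], isig_rep[:rep], ok
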