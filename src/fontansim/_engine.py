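"""Compiled fixed-step RK4 kernel for the closed-loop circulation.

The public simulator packs the circuit into flat index/constant arrays and
drives this kernel one cardiac cycle at a time.  The state vector layout
is

    x = [ compartment pressures | segment flows | chamber volumes ] ,

with chamber pressures derived algebraically from the elastance law at
every evaluation.  Discrete valve modes are updated once per step at the
step boundary and held constant across the four RK4 stages; regurgitant
mitral constants are refreshed from the instantaneous left-atrial volume
at the same point.

The arithmetic here mirrors, element for element, the pure-Python
reference in :func:`fontansim.simulator.state_derivative`; the test suite
asserts the two agree to machine precision.
"""

import math

import numpy as np
from numba import njit

# valve mode encoding
OPEN = 1
CLOSED = 0
REGURGITANT = -1

# segment kinds
VESSEL = 0
MITRAL = 1
AORTIC = 2


@njit(cache=True)
def _activation_shape(tau, t_rise, t_fall):
    """Two-cosine normalized activation on [0, t_rise + t_fall], else 0."""
    if tau < 0.0:
        return 0.0
    if tau <= t_rise:
        return 0.5 * (1.0 - math.cos(math.pi * tau / t_rise))
    if tau <= t_rise + t_fall:
        return 0.5 * (1.0 + math.cos(math.pi * (tau - t_rise) / t_fall))
    return 0.0


@njit(cache=True)
def _chamber_pressures(
    t, x, net, p_ch,
    n_comp, ch_es, ch_ed, ch_ks, ch_pext,
    t0, tvcp, tvrp, ta_phase,
):
    """Fill p_ch[0:3] with RA, LA, LV luminal pressures at state x."""
    tau = t % t0  # non-negative phase in [0, t0)
    e_v = _activation_shape(tau, tvcp, tvrp)
    # atrial onset at t0 - 2*ta_phase so relaxation ends at ventricular onset
    tau_a = tau - (t0 - 2.0 * ta_phase)
    if tau_a < 0.0:
        tau_a += t0
    e_a = _activation_shape(tau_a, ta_phase, ta_phase)
    for c in range(3):
        e = e_v if c == 2 else e_a
        elastance = ch_es[c] * e + ch_ed[c]
        dvdt = net[n_comp + c]
        denom = 1.0 - ch_ks[c] * dvdt
        if denom < 0.5:
            denom = 0.5
        p_ch[c] = elastance * x[x.size - 3 + c] / denom + ch_pext


@njit(cache=True)
def _net_flows(x, net, n_comp, n_seg, seg_up, seg_dn):
    net[:] = 0.0
    for s in range(n_seg):
        q = x[n_comp + s]
        net[seg_up[s]] -= q
        net[seg_dn[s]] += q


@njit(cache=True)
def _rhs(
    t, x, dx, net, p_all, p_ch,
    n_comp, n_seg,
    seg_up, seg_dn, seg_r, seg_l, seg_b, seg_kind,
    comp_c, comp_pext,
    ch_es, ch_ed, ch_ks, ch_pext,
    t0, tvcp, tvrp, ta_phase,
    mv_mode, av_mode, mv_b_cur, mv_l_cur,
):
    _net_flows(x, net, n_comp, n_seg, seg_up, seg_dn)
    _chamber_pressures(
        t, x, net, p_ch,
        n_comp, ch_es, ch_ed, ch_ks, ch_pext,
        t0, tvcp, tvrp, ta_phase,
    )
    for i in range(n_comp):
        p_all[i] = x[i]
    for c in range(3):
        p_all[n_comp + c] = p_ch[c]
    # compartment pressures: mass conservation dP/dt = netQ / C
    for i in range(n_comp):
        dx[i] = net[i] / comp_c[i]
    # segment flows: momentum conservation dQ/dt = (Pup - RQ - BQ|Q| - Pdn)/L
    for s in range(n_seg):
        q = x[n_comp + s]
        kind = seg_kind[s]
        if kind == MITRAL:
            if mv_mode == CLOSED:
                dx[n_comp + s] = 0.0
                continue
            if mv_mode == REGURGITANT:
                b = mv_b_cur
                l = mv_l_cur
            else:
                b = seg_b[s]
                l = seg_l[s]
            r = seg_r[s]
        elif kind == AORTIC:
            if av_mode == CLOSED:
                dx[n_comp + s] = 0.0
                continue
            r = seg_r[s]
            b = seg_b[s]
            l = seg_l[s]
        else:
            r = seg_r[s]
            b = seg_b[s]
            l = seg_l[s]
        dp = p_all[seg_up[s]] - p_all[seg_dn[s]]
        dx[n_comp + s] = (dp - r * q - b * q * abs(q)) / l
    # chamber volumes
    for c in range(3):
        dx[n_comp + n_seg + c] = net[n_comp + c]


@njit(cache=True)
def run_cycle(
    x, t_start, n_steps, dt,
    n_comp, n_seg,
    seg_up, seg_dn, seg_r, seg_l, seg_b, seg_kind,
    comp_c, comp_pext,
    ch_es, ch_ed, ch_ks, ch_pext,
    t0, tvcp, tvrp, ta_phase,
    a_reg, breg_coef, lreg_coef,
    eps_q,
    mv_si, av_si, i_la_node, i_lv_node, i_ao_node,
    modes,
    record, do_record,
):
    """Advance the state through one cardiac cycle in place.

    Returns the vector of cycle means (simple average over the n_steps
    step-boundary samples).  ``modes`` (int64[2] = [mitral, aortic]) is
    updated in place; ``record``, when ``do_record``, receives the state
    at every step boundary.
    """
    nx = x.size
    sums = np.zeros(nx)
    dx = np.empty(nx)
    k1 = np.empty(nx)
    k2 = np.empty(nx)
    k3 = np.empty(nx)
    k4 = np.empty(nx)
    xt = np.empty(nx)
    net = np.empty(n_comp + 3)
    p_all = np.empty(n_comp + 3)
    p_ch = np.empty(3)
    i_v_la = nx - 2  # left-atrial volume slot

    for step in range(n_steps):
        t = t_start + step * dt

        # --- discrete valve-mode update at the step boundary
        _net_flows(x, net, n_comp, n_seg, seg_up, seg_dn)
        _chamber_pressures(
            t, x, net, p_ch,
            n_comp, ch_es, ch_ed, ch_ks, ch_pext,
            t0, tvcp, tvrp, ta_phase,
        )
        p_la = p_ch[1]
        p_lv = p_ch[2]
        p_ao = x[i_ao_node]

        mv_mode = modes[0]
        q_mv = x[n_comp + mv_si]
        dp_mv = p_la - p_lv
        if mv_mode == OPEN:
            if dp_mv < 0.0 and q_mv <= eps_q:
                modes[0] = REGURGITANT if a_reg > 0.0 else CLOSED
                x[n_comp + mv_si] = 0.0
        elif mv_mode == CLOSED:
            if dp_mv > 0.0:
                modes[0] = OPEN
            elif dp_mv < 0.0 and a_reg > 0.0:
                modes[0] = REGURGITANT
        else:  # REGURGITANT
            if dp_mv > 0.0 and q_mv >= -eps_q:
                modes[0] = OPEN
                if q_mv < 0.0:
                    x[n_comp + mv_si] = 0.0

        av_mode = modes[1]
        q_av = x[n_comp + av_si]
        dp_av = p_lv - p_ao
        if av_mode == OPEN:
            if dp_av < 0.0 and q_av <= eps_q:
                modes[1] = CLOSED
                x[n_comp + av_si] = 0.0
        else:
            if dp_av > 0.0:
                modes[1] = OPEN

        # regurgitant mitral constants from instantaneous LA volume
        mv_b_cur = 0.0
        mv_l_cur = 1.0
        if modes[0] == REGURGITANT:
            v_la = x[i_v_la]
            a_la = math.pi * (3.0 * v_la / (4.0 * math.pi)) ** (2.0 / 3.0)
            mv_b_cur = breg_coef * (1.0 / a_reg - 1.0 / a_la) ** 2
            mv_l_cur = lreg_coef * (1.0 / math.sqrt(a_reg) - 1.0 / math.sqrt(a_la))

        if do_record:
            for i in range(nx):
                record[step, i] = x[i]
        for i in range(nx):
            sums[i] += x[i]

        mv_m = modes[0]
        av_m = modes[1]

        # --- classical RK4 with modes frozen over the step
        _rhs(t, x, k1, net, p_all, p_ch,
             n_comp, n_seg, seg_up, seg_dn, seg_r, seg_l, seg_b, seg_kind,
             comp_c, comp_pext, ch_es, ch_ed, ch_ks, ch_pext,
             t0, tvcp, tvrp, ta_phase, mv_m, av_m, mv_b_cur, mv_l_cur)
        for i in range(nx):
            xt[i] = x[i] + 0.5 * dt * k1[i]
        _rhs(t + 0.5 * dt, xt, k2, net, p_all, p_ch,
             n_comp, n_seg, seg_up, seg_dn, seg_r, seg_l, seg_b, seg_kind,
             comp_c, comp_pext, ch_es, ch_ed, ch_ks, ch_pext,
             t0, tvcp, tvrp, ta_phase, mv_m, av_m, mv_b_cur, mv_l_cur)
        for i in range(nx):
            xt[i] = x[i] + 0.5 * dt * k2[i]
        _rhs(t + 0.5 * dt, xt, k3, net, p_all, p_ch,
             n_comp, n_seg, seg_up, seg_dn, seg_r, seg_l, seg_b, seg_kind,
             comp_c, comp_pext, ch_es, ch_ed, ch_ks, ch_pext,
             t0, tvcp, tvrp, ta_phase, mv_m, av_m, mv_b_cur, mv_l_cur)
        for i in range(nx):
            xt[i] = x[i] + dt * k3[i]
        _rhs(t + dt, xt, k4, net, p_all, p_ch,
             n_comp, n_seg, seg_up, seg_dn, seg_r, seg_l, seg_b, seg_kind,
             comp_c, comp_pext, ch_es, ch_ed, ch_ks, ch_pext,
             t0, tvcp, tvrp, ta_phase, mv_m, av_m, mv_b_cur, mv_l_cur)
        for i in range(nx):
            x[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

    return sums / n_steps
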