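"""Numba-compiled right-hand sides for the coupled ODE systems.

These kernels inline the same equations exposed piecewise in
:mod:`lsoloop.sensor`, :mod:`lsoloop.neurons`, :mod:`lsoloop.feedback`
and :mod:`lsoloop.stimulus`; a consistency test asserts that the
closed-loop kernel equals the composition of those module functions at
random states.  Parameters are packed into flat float64 arrays so the
kernels stay nopython-compatible.

Closed-loop state vector (14):
    y[0:5]   left sensor  (x, v, theta, u_ac, u_env)
    y[5:10]  right sensor
    y[10:14] q_left, r_left, q_right, r_right
where q_left is the MNTB unit inhibiting the left LSO; it is driven by
the *right* sensor envelope (contralateral relay).

Open-loop-table state vector (6):
    y = (u_env_left, u_env_right, q_left, r_left, q_right, r_right)
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- packed parameter layout ------------------------------------------------
# sensor block (12): omega0, Q0, alpha_s, beta_s, gamma_s, R, kappa_s,
#                    tau_hpf, tau_lpf, u_dc, a_f_crit, limiter(0=current,1=voltage)
# neural block (12): tau_q, alpha_q, beta_q, w_mntb, tau_r, alpha_r, beta_r,
#                    w_lso, gamma_r, kappa_r, alpha_sigma, beta_sigma
# feedback (4):      topology(0 none,1 ipsi,2 contra), k_inv, k_max, k_a_const
# stimulus (4):      amp_left, amp_right, omega, on(0/1)

N_SENSOR = 12
N_NEURAL = 12
CLOSED_LOOP_STATES = 14
OPEN_LOOP_STATES = 6


def pack_sensor(p) -> np.ndarray:
    """Flatten a CantileverParams into the 12-float sensor block."""
    return np.array(
        [
            p.omega0,
            p.Q0,
            p.alpha_s,
            p.beta_s,
            p.gamma_s,
            p.R,
            p.kappa_s,
            p.tau_hpf,
            p.tau_lpf,
            p.u_dc,
            p.a_f_crit,
            0.0 if p.limiter == "current" else 1.0,
        ]
    )


def pack_neural(n) -> np.ndarray:
    return np.array(
        [
            n.tau_q,
            n.alpha_q,
            n.beta_q,
            n.w_mntb_exc,
            n.tau_r,
            n.alpha_r,
            n.beta_r,
            n.w_lso_exc,
            n.gamma_r,
            n.kappa_r,
            n.alpha_sigma,
            n.beta_sigma,
        ]
    )


_TOPO_CODE = {"none": 0.0, "ipsi": 1.0, "contra": 2.0}


def pack_closed_loop(sensor_left, sensor_right, neural, fbcfg, amp_left, amp_right,
                     omega, stim_on) -> np.ndarray:
    """Full parameter vector for the 14-state closed-loop kernel."""
    fb = np.array(
        [_TOPO_CODE[fbcfg.topology], float(fbcfg.k_inv), fbcfg.k_max, fbcfg.k_a_const]
    )
    stim = np.array([amp_left, amp_right, omega, 1.0 if stim_on else 0.0])
    return np.concatenate(
        [pack_sensor(sensor_left), pack_sensor(sensor_right), pack_neural(neural), fb, stim]
    )


def pack_open_loop(tau_lpf_left, tau_lpf_right, uac_amp_left, uac_amp_right,
                   omega_left, omega_right, neural) -> np.ndarray:
    head = np.array(
        [tau_lpf_left, tau_lpf_right, uac_amp_left, uac_amp_right, omega_left, omega_right]
    )
    return np.concatenate([head, pack_neural(neural)])


def pack_single_sensor(sensor, a_f, amp, omega) -> np.ndarray:
    return np.concatenate([pack_sensor(sensor), np.array([a_f, amp, omega])])


@njit(cache=False)
def _heating(u_act, gamma_s, R, limiter):
    if limiter == 0.0:
        t = np.tanh(u_act / R)
        return gamma_s * t * t
    t = np.tanh(u_act)
    return gamma_s * t * t / (R * R)


@njit(cache=False)
def _dheating_du(u_act, gamma_s, R, limiter):
    if limiter == 0.0:
        t = np.tanh(u_act / R)
        return gamma_s * 2.0 * t * (1.0 - t * t) / R
    t = np.tanh(u_act)
    return gamma_s * 2.0 * t * (1.0 - t * t) / (R * R)


@njit(cache=False)
def closed_loop_rhs(t, y, p):
    dy = np.empty(14)
    aq = p[25]; bq = p[26]; wm = p[27]
    tq = p[24]; tr = p[28]; ar = p[29]; br = p[30]; wl = p[31]
    gr = p[32]; kr = p[33]; asig = p[34]; bsig = p[35]
    topo = p[36]; kinv = p[37]; kmax = p[38]; kac = p[39]
    amp_l = p[40]; amp_r = p[41]; om = p[42]; on = p[43]

    q_l = y[10]; r_l = y[11]; q_r = y[12]; r_r = y[13]
    sig_l = 1.0 / (1.0 + np.exp(-(r_l - bsig) * asig))
    sig_r = 1.0 / (1.0 + np.exp(-(r_r - bsig) * asig))

    s = np.sin(om * t) * on
    for side in range(2):
        o = N_SENSOR * side
        i0 = 5 * side
        w0 = p[o]; Q0 = p[o + 1]; als = p[o + 2]; bs = p[o + 3]
        gs = p[o + 4]; R = p[o + 5]; ks = p[o + 6]
        thp = p[o + 7]; tlp = p[o + 8]; udc = p[o + 9]
        acrit = p[o + 10]; lim = p[o + 11]

        if topo == 0.0:
            af = kac * acrit
        else:
            if topo == 1.0:  # ipsi
                src = sig_l if side == 0 else sig_r
            else:  # contra
                src = sig_r if side == 0 else sig_l
            af = kinv * min(src, kmax) * acrit

        F = (amp_l if side == 0 else amp_r) * s
        x = y[i0]; v = y[i0 + 1]; th = y[i0 + 2]; u = y[i0 + 3]; ue = y[i0 + 4]
        u_act = af * u + udc
        dy[i0] = v
        dy[i0 + 1] = -(w0 / Q0) * v - w0 * w0 * x + als * th + F
        dy[i0 + 2] = -bs * th + _heating(u_act, gs, R, lim)
        dy[i0 + 3] = ks * v - u / thp
        dy[i0 + 4] = (abs(u) - ue) / tlp

    ue_l = y[4]; ue_r = y[9]
    g_l = max(q_l, 0.0)
    g_r = max(q_r, 0.0)
    # MNTB units are driven by the contralateral ear's envelope
    dy[10] = (-aq * q_l + bq * ue_r * wm) / tq
    dy[11] = (-ar * r_l + (br - r_l) * ue_l * wl - (gr + kr * r_l) * g_l) / tr
    dy[12] = (-aq * q_r + bq * ue_l * wm) / tq
    dy[13] = (-ar * r_r + (br - r_r) * ue_r * wl - (gr + kr * r_r) * g_r) / tr
    return dy


@njit(cache=False)
def closed_loop_jac(t, y, p):
    """Analytic Jacobian of closed_loop_rhs (piecewise across the |u_ac|
    kink, the rectifier corner and the gain clamp)."""
    J = np.zeros((14, 14))
    tq = p[24]; aq = p[25]; bq = p[26]; wm = p[27]
    tr = p[28]; ar = p[29]; br = p[30]; wl = p[31]
    gr = p[32]; kr = p[33]; asig = p[34]; bsig = p[35]
    topo = p[36]; kinv = p[37]; kmax = p[38]; kac = p[39]

    q_l = y[10]; r_l = y[11]; q_r = y[12]; r_r = y[13]
    sig_l = 1.0 / (1.0 + np.exp(-(r_l - bsig) * asig))
    sig_r = 1.0 / (1.0 + np.exp(-(r_r - bsig) * asig))
    dsig_l = asig * sig_l * (1.0 - sig_l)
    dsig_r = asig * sig_r * (1.0 - sig_r)

    for side in range(2):
        o = N_SENSOR * side
        i0 = 5 * side
        w0 = p[o]; Q0 = p[o + 1]; als = p[o + 2]; bs = p[o + 3]
        gs = p[o + 4]; R = p[o + 5]; ks = p[o + 6]
        thp = p[o + 7]; tlp = p[o + 8]; udc = p[o + 9]
        acrit = p[o + 10]; lim = p[o + 11]

        daf_dr = 0.0
        ridx = -1
        if topo == 0.0:
            af = kac * acrit
        else:
            if topo == 1.0:
                src = sig_l if side == 0 else sig_r
                dsrc = dsig_l if side == 0 else dsig_r
                ridx = 11 if side == 0 else 13
            else:
                src = sig_r if side == 0 else sig_l
                dsrc = dsig_r if side == 0 else dsig_l
                ridx = 13 if side == 0 else 11
            if src < kmax:
                af = kinv * src * acrit
                daf_dr = kinv * dsrc * acrit
            else:
                af = kinv * kmax * acrit

        u = y[i0 + 3]
        u_act = af * u + udc
        dh = _dheating_du(u_act, gs, R, lim)
        J[i0, i0 + 1] = 1.0
        J[i0 + 1, i0] = -w0 * w0
        J[i0 + 1, i0 + 1] = -w0 / Q0
        J[i0 + 1, i0 + 2] = als
        J[i0 + 2, i0 + 2] = -bs
        J[i0 + 2, i0 + 3] = dh * af
        if ridx >= 0 and daf_dr != 0.0:
            J[i0 + 2, ridx] = dh * u * daf_dr
        J[i0 + 3, i0 + 1] = ks
        J[i0 + 3, i0 + 3] = -1.0 / thp
        J[i0 + 4, i0 + 3] = (1.0 if u >= 0.0 else -1.0) / tlp
        J[i0 + 4, i0 + 4] = -1.0 / tlp

    ue_l = y[4]; ue_r = y[9]
    g_l = max(q_l, 0.0)
    g_r = max(q_r, 0.0)
    J[10, 9] = bq * wm / tq
    J[10, 10] = -aq / tq
    J[12, 4] = bq * wm / tq
    J[12, 12] = -aq / tq
    J[11, 4] = (br - r_l) * wl / tr
    J[11, 10] = -(gr + kr * r_l) * (1.0 if q_l > 0.0 else 0.0) / tr
    J[11, 11] = (-ar - ue_l * wl - kr * g_l) / tr
    J[13, 9] = (br - r_r) * wl / tr
    J[13, 12] = -(gr + kr * r_r) * (1.0 if q_r > 0.0 else 0.0) / tr
    J[13, 13] = (-ar - ue_r * wl - kr * g_r) / tr
    return J


@njit(cache=False)
def open_loop_rhs(t, y, p):
    """Table-driven mode: prescribed sinusoidal u_ac into envelope + neurons."""
    dy = np.empty(6)
    tlp_l = p[0]; tlp_r = p[1]
    uamp_l = p[2]; uamp_r = p[3]
    om_l = p[4]; om_r = p[5]
    tq = p[6]; aq = p[7]; bq = p[8]; wm = p[9]
    tr = p[10]; ar = p[11]; br = p[12]; wl = p[13]
    gr = p[14]; kr = p[15]

    uac_l = uamp_l * np.sin(om_l * t)
    uac_r = uamp_r * np.sin(om_r * t)
    ue_l = y[0]; ue_r = y[1]
    q_l = y[2]; r_l = y[3]; q_r = y[4]; r_r = y[5]
    g_l = max(q_l, 0.0)
    g_r = max(q_r, 0.0)
    dy[0] = (abs(uac_l) - ue_l) / tlp_l
    dy[1] = (abs(uac_r) - ue_r) / tlp_r
    dy[2] = (-aq * q_l + bq * ue_r * wm) / tq
    dy[3] = (-ar * r_l + (br - r_l) * ue_l * wl - (gr + kr * r_l) * g_l) / tr
    dy[4] = (-aq * q_r + bq * ue_l * wm) / tq
    dy[5] = (-ar * r_r + (br - r_r) * ue_r * wl - (gr + kr * r_r) * g_r) / tr
    return dy


@njit(cache=False)
def single_sensor_rhs(t, y, p):
    """One 5-state sensor channel at fixed feedback factor with sinusoidal forcing."""
    dy = np.empty(5)
    w0 = p[0]; Q0 = p[1]; als = p[2]; bs = p[3]; gs = p[4]; R = p[5]; ks = p[6]
    thp = p[7]; tlp = p[8]; udc = p[9]; lim = p[11]
    af = p[12]; amp = p[13]; om = p[14]
    x = y[0]; v = y[1]; th = y[2]; u = y[3]; ue = y[4]
    u_act = af * u + udc
    dy[0] = v
    dy[1] = -(w0 / Q0) * v - w0 * w0 * x + als * th + amp * np.sin(om * t)
    dy[2] = -bs * th + _heating(u_act, gs, R, lim)
    dy[3] = ks * v - u / thp
    dy[4] = (abs(u) - ue) / tlp
    return dy
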