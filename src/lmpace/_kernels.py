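"""Jitted FTCS chunk integrators, one per cell model.

Each ``*_chunk`` function advances the tissue state in place by
``nsteps`` explicit FTCS steps: 5-point Laplacian with edge-replicated
(no-flux) boundaries, reaction term of the model, constant external
current field, and Rush-Larsen exponential updates for relaxation
gates (decay factors with constant time constants are precomputed in
the packed parameter vector ``p``).

The update order per step matches the reference numpy path in
:mod:`lmpace.tissue_sim`: the new potential is computed from the old
state, then gates are advanced using the old potential.

All kernels share one signature::

    chunk(u, g1, g2, g3, buf, ext, nsteps, dt, dfac, p)

``u`` is the potential field, ``g1..g3`` gate fields (unused ones may
be 1x1 dummies), ``buf`` an NxN scratch array, ``ext`` the external
current divided by C_m (1/ms), ``dfac = D*dt/dx**2``.

Numerical note: tanh factors in activation functions are saturated to
+/-1 beyond |argument| > 8 (error < 3e-7), so that model resting
states are exact fixed points of the discrete update.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TANH_SAT = 8.0

_OPT = dict(cache=True, fastmath=True, boundscheck=False)


def tanh_sat(x):
    """tanh saturated to +/-1 beyond |x| > 8; ufunc-friendly."""
    return np.where(x > TANH_SAT, 1.0, np.where(x < -TANH_SAT, -1.0, np.tanh(np.clip(x, -TANH_SAT, TANH_SAT))))


@njit(**_OPT)
def fk_chunk(u, g1f, g2f, g3f, buf, ext, nsteps, dt, dfac, p):
    u_c = p[0]; u_v = p[1]; u_csi = p[2]; kappa = p[3]
    tau_d = p[4]; tau_r = p[5]; tau_0 = p[6]; tau_si = p[7]
    e_vp = p[8]; e_v1m = p[9]; e_v2m = p[10]; e_wp = p[11]; e_wm = p[12]
    n = u.shape[0]
    cur = u
    nxt = buf
    for _ in range(nsteps):
        for i in range(n):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n - 1 else n - 1
            rm = cur[im]
            r0 = cur[i]
            rp = cur[ip]
            gv = g1f[i]
            gw = g2f[i]
            out = nxt[i]
            ex = ext[i]
            for j in range(n):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < n - 1 else n - 1
                uu = r0[j]
                vv = gv[j]
                ww = gw[j]
                lap = rm[j] + rp[j] + r0[jm] + r0[jp] - 4.0 * uu
                x = kappa * (uu - u_csi)
                if x < -8.0:
                    jsi = 0.0
                elif x > 8.0:
                    jsi = -ww / tau_si
                else:
                    # tanh via its exp identity (exact; vectorizes well)
                    e2 = math.exp(2.0 * x)
                    th = (e2 - 1.0) / (e2 + 1.0)
                    jsi = -ww * (1.0 + th) / (2.0 * tau_si)
                if uu >= u_c:
                    jfi = -vv * (1.0 - uu) * (uu - u_c) / tau_d
                    jso = 1.0 / tau_r
                    gv[j] = vv * e_vp
                    gw[j] = ww * e_wp
                else:
                    jfi = 0.0
                    jso = uu / tau_0
                    ev = e_v1m if uu >= u_v else e_v2m
                    gv[j] = 1.0 + (vv - 1.0) * ev
                    gw[j] = 1.0 + (ww - 1.0) * e_wm
                out[j] = uu + dfac * lap + dt * (-(jfi + jso + jsi) + ex[j])
        cur, nxt = nxt, cur
    if nsteps % 2 == 1:
        u[:, :] = cur


@njit(**_OPT)
def msa_chunk(u, g1f, g2f, g3f, buf, ext, nsteps, dt, dfac, p):
    tau_in = p[0]; tau_out = p[1]; v_gate = p[2]
    e_open = p[3]; e_close = p[4]
    n = u.shape[0]
    cur = u
    nxt = buf
    for _ in range(nsteps):
        for i in range(n):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n - 1 else n - 1
            rm = cur[im]
            r0 = cur[i]
            rp = cur[ip]
            gh = g1f[i]
            out = nxt[i]
            ex = ext[i]
            for j in range(n):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < n - 1 else n - 1
                uu = r0[j]
                hh = gh[j]
                lap = rm[j] + rp[j] + r0[jm] + r0[jp] - 4.0 * uu
                rate = hh * uu * uu * (1.0 - uu) / tau_in - uu / tau_out
                if uu < v_gate:
                    gh[j] = 1.0 + (hh - 1.0) * e_open
                else:
                    gh[j] = hh * e_close
                out[j] = uu + dfac * lap + dt * (rate + ex[j])
        cur, nxt = nxt, cur
    if nsteps % 2 == 1:
        u[:, :] = cur


@njit(**_OPT)
def ap_chunk(u, g1f, g2f, g3f, buf, ext, nsteps, dt, dfac, p):
    K = p[0]; a = p[1]; b = p[2]; eps0 = p[3]
    mu1 = p[4]; mu2 = p[5]; ts = p[6]
    n = u.shape[0]
    cur = u
    nxt = buf
    for _ in range(nsteps):
        for i in range(n):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n - 1 else n - 1
            rm = cur[im]
            r0 = cur[i]
            rp = cur[ip]
            gv = g1f[i]
            out = nxt[i]
            ex = ext[i]
            for j in range(n):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < n - 1 else n - 1
                uu = r0[j]
                vv = gv[j]
                lap = rm[j] + rp[j] + r0[jm] + r0[jp] - 4.0 * uu
                rate = (-K * uu * (uu - a) * (uu - 1.0) - uu * vv) / ts
                eps = eps0 + mu1 * vv / (uu + mu2)
                gv[j] = vv + dt * eps * (-vv - K * uu * (uu - b - 1.0)) / ts
                out[j] = uu + dfac * lap + dt * (rate + ex[j])
        cur, nxt = nxt, cur
    if nsteps % 2 == 1:
        u[:, :] = cur


@njit(**_OPT)
def bocf_chunk(u, g1f, g2f, g3f, buf, ext, nsteps, dt, dfac, p):
    u_o = p[0]; u_u = p[1]; theta_v = p[2]; theta_w = p[3]
    theta_vm = p[4]; theta_o = p[5]; tau_fi = p[6]
    tau_o1 = p[7]; tau_o2 = p[8]; tau_so1 = p[9]; tau_so2 = p[10]
    k_so = p[11]; u_so = p[12]; tau_si = p[13]; tau_winf = p[14]
    w_inf_star = p[15]; tau_w1m = p[16]; tau_w2m = p[17]
    k_wm = p[18]; u_wm = p[19]
    e_vp = p[20]; e_v1m = p[21]; e_v2m = p[22]; e_wp = p[23]
    e_s1 = p[24]; e_s2 = p[25]; k_s = p[26]; u_s = p[27]
    n = u.shape[0]
    cur = u
    nxt = buf
    for _ in range(nsteps):
        for i in range(n):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n - 1 else n - 1
            rm = cur[im]
            r0 = cur[i]
            rp = cur[ip]
            gv = g1f[i]
            gw = g2f[i]
            gs = g3f[i]
            out = nxt[i]
            ex = ext[i]
            for j in range(n):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < n - 1 else n - 1
                uu = r0[j]
                vv = gv[j]
                ww = gw[j]
                ss = gs[j]
                lap = rm[j] + rp[j] + r0[jm] + r0[jp] - 4.0 * uu
                if uu >= theta_v:
                    jfi = -vv * (uu - theta_v) * (u_u - uu) / tau_fi
                    gv[j] = vv * e_vp
                else:
                    jfi = 0.0
                    if uu < theta_vm:
                        gv[j] = 1.0 + (vv - 1.0) * e_v1m
                    else:
                        gv[j] = vv * e_v2m
                if uu >= theta_w:
                    x = k_so * (uu - u_so)
                    if x > 8.0:
                        th = 1.0
                    elif x < -8.0:
                        th = -1.0
                    else:
                        th = math.tanh(x)
                    tau_so = tau_so1 + (tau_so2 - tau_so1) * (1.0 + th) / 2.0
                    jso = 1.0 / tau_so
                    jsi = -ww * ss / tau_si
                    gw[j] = ww * e_wp
                else:
                    tau_o = tau_o2 if uu >= theta_o else tau_o1
                    jso = (uu - u_o) / tau_o
                    jsi = 0.0
                    w_inf = w_inf_star if uu >= theta_o else 1.0 - uu / tau_winf
                    x = k_wm * (uu - u_wm)
                    if x > 8.0:
                        th = 1.0
                    elif x < -8.0:
                        th = -1.0
                    else:
                        th = math.tanh(x)
                    tau_wm = tau_w1m + (tau_w2m - tau_w1m) * (1.0 + th) / 2.0
                    gw[j] = w_inf + (ww - w_inf) * math.exp(-dt / tau_wm)
                x = k_s * (uu - u_s)
                if x > 8.0:
                    s_inf = 1.0
                elif x < -8.0:
                    s_inf = 0.0
                else:
                    s_inf = (1.0 + math.tanh(x)) / 2.0
                e_s = e_s2 if uu >= theta_w else e_s1
                gs[j] = s_inf + (ss - s_inf) * e_s
                out[j] = uu + dfac * lap + dt * (-(jfi + jso + jsi) + ex[j])
        cur, nxt = nxt, cur
    if nsteps % 2 == 1:
        u[:, :] = cur


def _pack_fk(p, dt):
    return np.array(
        [
            p["u_c"], p["u_v"], p["u_csi"], p["kappa"],
            p["tau_d"], p["tau_r"], p["tau_0"], p["tau_si"],
            math.exp(-dt / p["tau_vp"]),
            math.exp(-dt / p["tau_v1m"]),
            math.exp(-dt / p["tau_v2m"]),
            math.exp(-dt / p["tau_wp"]),
            math.exp(-dt / p["tau_wm"]),
        ],
        dtype=np.float64,
    )


def _pack_msa(p, dt):
    return np.array(
        [
            p["tau_in"], p["tau_out"], p["v_gate"],
            math.exp(-dt / p["tau_open"]),
            math.exp(-dt / p["tau_close"]),
        ],
        dtype=np.float64,
    )


def _pack_ap(p, dt):
    return np.array(
        [p["K"], p["a"], p["b"], p["eps0"], p["mu1"], p["mu2"], p["time_scale"]],
        dtype=np.float64,
    )


def _pack_bocf(p, dt):
    return np.array(
        [
            p["u_o"], p["u_u"], p["theta_v"], p["theta_w"], p["theta_vm"],
            p["theta_o"], p["tau_fi"], p["tau_o1"], p["tau_o2"], p["tau_so1"],
            p["tau_so2"], p["k_so"], p["u_so"], p["tau_si"], p["tau_winf"],
            p["w_inf_star"], p["tau_w1m"], p["tau_w2m"], p["k_wm"], p["u_wm"],
            math.exp(-dt / p["tau_vp"]),
            math.exp(-dt / p["tau_v1m"]),
            math.exp(-dt / p["tau_v2m"]),
            math.exp(-dt / p["tau_wp"]),
            math.exp(-dt / p["tau_s1"]),
            math.exp(-dt / p["tau_s2"]),
            p["k_s"], p["u_s"],
        ],
        dtype=np.float64,
    )


KERNELS = {"FK": fk_chunk, "MSA": msa_chunk, "AP": ap_chunk, "BOCF": bocf_chunk}
PACKERS = {"FK": _pack_fk, "MSA": _pack_msa, "AP": _pack_ap, "BOCF": _pack_bocf}
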