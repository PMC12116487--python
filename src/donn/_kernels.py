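"""Inner per-sample loop of stage-1 training.

The online training rules touch every oscillator (and every lateral pair)
at every sample, which dominates runtime.  The loop is compiled with numba
when available; a NumPy implementation with identical semantics is the
fallback.  Scheme codes: 0 power, 1 complex, 2 linear (all-to-all or
masked nearest-neighbour — the mask already encodes the difference).
"""

from __future__ import annotations

import math

import numpy as np

from .dynamics import R_FLOOR

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(fn):
            return fn
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


SCHEME_CODES = {"power": 0, "complex": 1, "linear_all": 2, "linear_nn": 2}


@njit(cache=False)
def _epoch_jit(D, dt, mu, beta, eps, eta_w, eta_a, omega, r, theta, alpha,
               wre, wim, mask, xi_w, tau_w, scheme, hebb,
               omega_min, omega_hi, s_out, e_out, record):  # pragma: no cover
    n_t = D.shape[0]
    n = omega.shape[0]
    r_floor = R_FLOOR
    sq = 0.0
    dr_c = np.zeros(n)
    dth_c = np.zeros(n)
    for k in range(n_t):
        s = 0.0
        for i in range(n):
            s += alpha[i] * math.cos(theta[i])
        e = D[k] - s
        for i in range(n):
            dr_c[i] = 0.0
            dth_c[i] = 0.0
        if scheme == 0:
            for i in range(n):
                acc_r = 0.0
                acc_t = 0.0
                for j in range(n):
                    if mask[i, j]:
                        a = math.sqrt(wre[i, j] ** 2 + wim[i, j] ** 2)
                        if a > 0.0:
                            phi = math.atan2(wim[i, j], wre[i, j])
                            rho = omega[i] / omega[j]
                            pw = r[j] ** rho if r[j] > 0.0 else 0.0
                            arg = (omega[i] * (theta[j] / omega[j]
                                               - theta[i] / omega[i])
                                   + phi / omega[j])
                            g = xi_w * a * pw
                            acc_r += g * math.cos(arg)
                            acc_t += g * math.sin(arg)
                ri = r[i] if r[i] > r_floor else r_floor
                dr_c[i] = acc_r
                dth_c[i] = acc_t / ri
        elif scheme == 1:
            for i in range(n):
                acc_r = 0.0
                acc_t = 0.0
                for j in range(n):
                    if mask[i, j]:
                        a = math.sqrt(wre[i, j] ** 2 + wim[i, j] ** 2)
                        if a > 0.0:
                            phi = math.atan2(wim[i, j], wre[i, j])
                            arg = theta[j] + phi - theta[i]
                            acc_r += xi_w * a * r[j] * math.cos(arg)
                            acc_t += xi_w * a * r[j] * math.sin(arg)
                ri = r[i] if r[i] > r_floor else r_floor
                dr_c[i] = acc_r
                dth_c[i] = acc_t / ri
        else:
            for i in range(n):
                xi_ = r[i] * math.cos(theta[i])
                c = 0.0
                for j in range(n):
                    if mask[i, j]:
                        a = math.sqrt(wre[i, j] ** 2 + wim[i, j] ** 2)
                        xj = r[j] * math.cos(theta[j])
                        c += xi_w * a * (xj - xi_)
                ri = r[i] if r[i] > r_floor else r_floor
                dr_c[i] = c * math.cos(theta[i])
                dth_c[i] = -c * math.sin(theta[i]) / ri
        f = eps * e
        for i in range(n):
            ri = r[i] if r[i] > r_floor else r_floor
            dr = (mu + beta * r[i] * r[i]) * r[i] + dr_c[i] + f * math.cos(theta[i])
            dth = omega[i] + dth_c[i] - f * math.sin(theta[i]) / ri
            r[i] = r[i] + dt * dr
            if r[i] < 0.0:
                r[i] = 0.0
            theta[i] = theta[i] + dt * dth
        for i in range(n):
            w_new = omega[i] - eta_w * e * math.sin(theta[i])
            if w_new < omega_min:
                w_new = omega_min
            elif w_new > omega_hi:
                w_new = omega_hi
            omega[i] = w_new
            alpha[i] = alpha[i] + eta_a * e * math.cos(theta[i])
        if hebb:
            decay = dt / tau_w
            for i in range(n):
                for j in range(n):
                    if mask[i, j]:
                        rho = omega[i] / omega[j]
                        mag = r[i] * (r[j] ** rho) if r[j] > 0.0 else 0.0
                        ang = theta[i] - rho * theta[j]
                        tre = mag * math.cos(ang)
                        tim = mag * math.sin(ang)
                        wre[i, j] += decay * (tre - wre[i, j])
                        wim[i, j] += decay * (tim - wim[i, j])
        sq += e * e
        if record:
            s_out[k] = s
            e_out[k] = e
    return sq


def _epoch_numpy(D, dt, mu, beta, eps, eta_w, eta_a, omega, r, theta, alpha,
                 wre, wim, mask, xi_w, tau_w, scheme, hebb,
                 omega_min, omega_hi, s_out, e_out, record):
    n_t = D.shape[0]
    sq = 0.0
    any_mask = mask.any()
    for k in range(n_t):
        cos_th = np.cos(theta)
        s = float(alpha @ cos_th)
        e = D[k] - s
        r_safe = np.maximum(r, R_FLOOR)
        if any_mask:
            a = np.sqrt(wre**2 + wim**2)
            gain = np.where(mask, xi_w * a, 0.0)
            phi = np.where(mask & (a > 0), np.arctan2(wim, wre), 0.0)
            if scheme == 0:
                w_i = omega[:, None]
                w_j = omega[None, :]
                rho = w_i / w_j
                r_j = r[None, :]
                with np.errstate(divide="ignore"):
                    logr = np.log(np.where(r_j > 0, r_j, 1.0))
                pw = np.where(r_j > 0, np.exp(rho * logr), 0.0)
                arg = w_i * (theta[None, :] / w_j - theta[:, None] / w_i) + phi / w_j
                cdr = np.sum(gain * pw * np.cos(arg), axis=1)
                cdth = np.sum(gain * pw * np.sin(arg), axis=1) / r_safe
            elif scheme == 1:
                arg = theta[None, :] + phi - theta[:, None]
                cdr = np.sum(gain * r[None, :] * np.cos(arg), axis=1)
                cdth = np.sum(gain * r[None, :] * np.sin(arg), axis=1) / r_safe
            else:
                x = r * cos_th
                c = np.sum(gain * (x[None, :] - x[:, None]), axis=1)
                cdr = c * cos_th
                cdth = -c * np.sin(theta) / r_safe
        else:
            cdr = cdth = 0.0
        f = eps * e
        dr = (mu + beta * r * r) * r + cdr + f * cos_th
        dth = omega + cdth - f * np.sin(theta) / r_safe
        r[:] = np.maximum(r + dt * dr, 0.0)
        theta[:] = theta + dt * dth
        omega[:] = np.clip(omega - eta_w * e * np.sin(theta), omega_min, omega_hi)
        alpha[:] = alpha + eta_a * e * np.cos(theta)
        if hebb:
            rho = omega[:, None] / omega[None, :]
            r_j = r[None, :]
            with np.errstate(divide="ignore"):
                logr = np.log(np.where(r_j > 0, r_j, 1.0))
            mag = r[:, None] * np.where(r_j > 0, np.exp(rho * logr), 0.0)
            ang = theta[:, None] - rho * theta[None, :]
            decay = dt / tau_w
            upd_re = decay * (mag * np.cos(ang) - wre)
            upd_im = decay * (mag * np.sin(ang) - wim)
            wre[mask] += upd_re[mask]
            wim[mask] += upd_im[mask]
        sq += e * e
        if record:
            s_out[k] = s
            e_out[k] = e
    return sq


stage1_epoch = _epoch_jit if HAVE_NUMBA else _epoch_numpy
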