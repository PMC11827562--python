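"""Numba log-posterior and gradient for the hierarchical planning model.

The unconstrained parameter vector ``q`` is laid out as

    [ mu (n_mu) | global C_info raw (0 or 1) | cut_raw (4) | theta_raw (n_sub * n_sp) ]

Positive parameters are sampled on the log scale (theta = exp(theta_raw),
with the log-Jacobian added), matching a lower-bound-at-zero constraint.
Cut points use the ordered transform kappa_0 = c_0, kappa_k = kappa_{k-1} +
exp(c_k).  Priors: theta_jk ~ Normal(mu_k, 1) truncated to (0, inf) for the
hyper-meaned parameters, scale parameters ~ Normal(1, 1) truncated, mu_k ~
Normal(0, 5), kappa_k ~ Normal(0, 10), global C_info ~ Normal(0, 5)
truncated.  The likelihood is y ~ OrderedLogistic(VOI, kappa).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

N_CUT = 4


@njit(cache=True, fastmath=False)
def _log_ndtr(x: float) -> float:
    """log of the standard normal CDF, stable for very negative x."""
    if x > -20.0:
        return math.log(0.5 * math.erfc(-x / SQRT2))
    x2 = x * x
    return -0.5 * x2 - LOG_SQRT_2PI - math.log(-x) + math.log1p(-1.0 / x2)


@njit(cache=True, fastmath=False)
def _inv_mills(x: float) -> float:
    """phi(x) / Phi(x)."""
    return math.exp(-0.5 * x * x - LOG_SQRT_2PI - _log_ndtr(x))


@njit(cache=True, fastmath=False)
def _log1pexp(x: float) -> float:
    if x > 33.0:
        return x
    if x < -33.0:
        return math.exp(x)
    return math.log1p(math.exp(x))


@njit(cache=True, fastmath=False)
def _log_sigmoid(x: float) -> float:
    return -_log1pexp(-x)


@njit(cache=True, fastmath=False)
def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True, fastmath=False)
def logp_grad(
    q,
    subj,
    p,
    cost,
    is_gain,
    y,
    n_sub,
    n_sp,
    n_mu,
    use_global_cinfo,
    i_uo,
    i_cp,
    i_ci,
    i_ul,
    i_sg,
    i_sl,
    hyper_idx,
):
    """Joint log density (up to a constant) and its gradient wrt ``q``."""
    grad = np.zeros_like(q)
    mu = q[:n_mu]
    off = n_mu
    g_cinfo = 0.0
    g_cinfo_raw = 0.0
    if use_global_cinfo:
        g_cinfo_raw = q[off]
        g_cinfo = math.exp(g_cinfo_raw)
        off += 1
    cut_raw = q[off : off + N_CUT]
    theta_off = off + N_CUT

    kappa = np.empty(N_CUT)
    kappa[0] = cut_raw[0]
    for k in range(1, N_CUT):
        kappa[k] = kappa[k - 1] + math.exp(cut_raw[k])

    theta = np.empty((n_sub, n_sp))
    for j in range(n_sub):
        for k in range(n_sp):
            theta[j, k] = math.exp(q[theta_off + j * n_sp + k])

    lp = 0.0
    gtheta = np.zeros((n_sub, n_sp))
    gkappa = np.zeros(N_CUT)
    gmu = np.zeros(n_mu)
    g_global = 0.0

    # ---- likelihood -------------------------------------------------------
    n_trials = subj.shape[0]
    for t in range(n_trials):
        j = subj[t]
        pt = p[t]
        ct = cost[t]
        uo = theta[j, i_uo]
        cp = theta[j, i_cp]
        ul = theta[j, i_ul]
        if use_global_cinfo:
            ci = g_cinfo
        else:
            ci = theta[j, i_ci]
        if i_sg >= 0:
            if is_gain[t] == 1:
                s = theta[j, i_sg]
            else:
                s = theta[j, i_sl]
        else:
            s = 1.0
        u_plan = pt * s * uo - cp
        plan = u_plan >= ul
        u_info = pt * (s * uo - cp) - ci * ct
        if plan:
            voi = u_info - u_plan
        else:
            voi = u_info - ul

        yt = y[t]
        # ordered logistic log pmf and d log pmf / d voi
        if yt == 1:
            a = kappa[0] - voi
            lp += _log_sigmoid(a)
            dda = _sigmoid(-a)
            gkappa[0] += dda
            dv = -dda
        elif yt == 5:
            b = kappa[3] - voi
            lp += _log_sigmoid(-b)
            ddb = -_sigmoid(b)
            gkappa[3] += ddb
            dv = -ddb
        else:
            a = kappa[yt - 1] - voi
            b = kappa[yt - 2] - voi
            lsa = _log_sigmoid(a)
            lsb = _log_sigmoid(b)
            lsna = _log_sigmoid(-a)
            lsnb = _log_sigmoid(-b)
            d = b - a  # strictly negative
            if d < -1e-12:
                l1me = math.log1p(-math.exp(d))
            else:
                l1me = math.log(max(-d, 1e-300))
            lp += lsa + lsnb + l1me
            dda = math.exp(lsna - lsnb - l1me)
            ddb = -math.exp(lsb - lsa - l1me)
            gkappa[yt - 1] += dda
            gkappa[yt - 2] += ddb
            dv = -(dda + ddb)

        # back-propagate dv through VOI
        if plan:
            gtheta[j, i_cp] += dv * (1.0 - pt)
        else:
            gtheta[j, i_uo] += dv * pt * s
            gtheta[j, i_cp] += -dv * pt
            gtheta[j, i_ul] += -dv
            if i_sg >= 0:
                if is_gain[t] == 1:
                    gtheta[j, i_sg] += dv * pt * uo
                else:
                    gtheta[j, i_sl] += dv * pt * uo
        if use_global_cinfo:
            g_global += -dv * ct
        else:
            gtheta[j, i_ci] += -dv * ct

    # ---- priors -----------------------------------------------------------
    for j in range(n_sub):
        for k in range(n_sp):
            th = theta[j, k]
            h = hyper_idx[k]
            if h >= 0:
                m = mu[h]
                lp += -0.5 * (th - m) * (th - m) - _log_ndtr(m)
                gtheta[j, k] += -(th - m)
                gmu[h] += (th - m) - _inv_mills(m)
            else:
                lp += -0.5 * (th - 1.0) * (th - 1.0)
                gtheta[j, k] += -(th - 1.0)

    for h in range(n_mu):
        lp += -0.5 * mu[h] * mu[h] / 25.0
        gmu[h] += -mu[h] / 25.0

    if use_global_cinfo:
        lp += -0.5 * g_cinfo * g_cinfo / 25.0
        g_global += -g_cinfo / 25.0

    for k in range(N_CUT):
        lp += -0.5 * kappa[k] * kappa[k] / 100.0
        gkappa[k] += -kappa[k] / 100.0

    # ---- transforms: Jacobians and chain rule -----------------------------
    for h in range(n_mu):
        grad[h] = gmu[h]
    off = n_mu
    if use_global_cinfo:
        lp += g_cinfo_raw
        grad[off] = g_global * g_cinfo + 1.0
        off += 1
    # cut points: kappa_m depends on cut_raw_k for all m >= k
    csum = 0.0
    for m in range(N_CUT - 1, -1, -1):
        csum += gkappa[m]
        if m == 0:
            grad[off] = csum
        else:
            lp += cut_raw[m]
            grad[off + m] = csum * math.exp(cut_raw[m]) + 1.0
    for j in range(n_sub):
        for k in range(n_sp):
            idx = theta_off + j * n_sp + k
            lp += q[idx]
            grad[idx] = gtheta[j, k] * theta[j, k] + 1.0

    return lp, grad
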