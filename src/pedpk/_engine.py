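"""Compiled likelihood engine.

Numba implementation of the per-subject predictions, the conditional
objective, the inner Gauss-Newton search for the random-effect modes and
the Laplace marginal.  Mirrors :mod:`pedpk.likelihood` exactly (a parity
test keeps the two in lockstep); exists because population fits, power
replicates and parameter-recovery studies need the likelihood thousands of
times.

Parameter vector layout (natural scale)::

    0 cl, 1 vc, 2 q, 3 vp, 4 ka, 5 mtt_tablet, 6 nn, 7 beta_susp,
    8 gamma, 9 pmage50, 10 theta_mdr, 11 mdr_target_code,
    12 omega_cl, 13 pi_ka, 14 pi_mtt, 15 pi_f,
    16 sigma_prop, 17 sigma_add, 18 lloq, 19 ref_weight, 20 alpha_cl,
    21 alpha_v, 22 f

``mdr_target_code``: 0 none, 1 cl, 2 f, 3 mtt, 4 ka.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .likelihood import PackedData, effect_layout
from .random_effects import RandomEffectsSpec

__all__ = ["FlatData", "params_to_vector", "engine_neg2ll",
           "engine_predict", "max_effect_dim"]

LOG2PI = math.log(2.0 * math.pi)

_GL_X, _GL_W = np.polynomial.legendre.leggauss(24)
_GL_X.setflags(write=False)
_GL_W.setflags(write=False)


# ---------------------------------------------------------------------------
# special functions
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gammp(a, x, lga):
    """Regularised lower incomplete gamma P(a, x), x >= 0."""
    if x <= 0.0:
        return 0.0
    if x < a + 1.0:
        # series representation
        ap = a
        s = 1.0 / a
        term = s
        for _ in range(500):
            ap += 1.0
            term *= x / ap
            s += term
            if abs(term) < abs(s) * 1e-15:
                break
        return s * math.exp(-x + a * math.log(x) - lga)
    # continued fraction for Q(a, x), modified Lentz
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1e300
    d = 1.0 / b
    h = d
    for i in range(1, 500):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-15:
            break
    q = math.exp(-x + a * math.log(x) - lga) * h
    return 1.0 - q


@njit(cache=True)
def _conv(a, lga, ktr, lktr, lam, tau):
    """int_0^tau Gamma(a, ktr).pdf(s) exp(-lam (tau - s)) ds (scalar).

    ``lga`` and ``lktr`` are precomputed log-gamma(a) and log(ktr).
    """
    if tau <= 0.0:
        return 0.0
    d = ktr - lam
    z = d * tau
    if z >= 8.0:
        if z > a + 12.0 * math.sqrt(a) + 40.0:
            return math.exp(-lam * tau + a * (lktr - math.log(d)))
        p = _gammp(a, z, lga)
        if p <= 0.0:
            return 0.0
        return math.exp(-lam * tau + a * (lktr - math.log(d)) + math.log(p))
    if z > -8.0:
        s_acc = 0.0
        term = 1.0
        for k in range(40):
            s_acc += term / (a + k)
            term *= -z / (k + 1.0)
        lp = -lam * tau + a * (lktr + math.log(tau)) - lga
        return math.exp(lp) * s_acc
    # z <= -8: mass sits at the upper endpoint; Gauss-Legendre there
    u = lam - ktr
    vmax = tau if tau < 60.0 / u else 60.0 / u
    half = 0.5 * vmax
    acc = 0.0
    for i in range(_GL_X.shape[0]):
        v = half * (_GL_X[i] + 1.0)
        base = tau - v
        if base < 1e-300:
            base = 1e-300
        acc += half * _GL_W[i] * math.exp((a - 1.0) * math.log(base) - u * v)
    if acc <= 0.0:
        return 0.0
    return math.exp(a * lktr - lga - ktr * tau + math.log(acc))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pred_subject(out, obs_t, dose_t, dose_amt, f_d, mtt_d, ka_d,
                  cl, vc, q, vp, nn):
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc2 = s * s - 4.0 * k10 * k21
    disc = math.sqrt(disc2) if disc2 > 0.0 else 0.0
    if disc < 1e-9 * s:  # repeated eigenvalue: split the pair slightly
        disc = 1e-9 * s
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    a = nn + 1.0
    lga = math.lgamma(a)
    for i in range(out.shape[0]):
        out[i] = 0.0
    for m in range(dose_t.shape[0]):
        ka = ka_d[m]
        if abs(ka - lam1) < 1e-8 * max(ka, lam1):
            ka = ka * (1.0 + 1e-6) + 1e-12
        if abs(ka - lam2) < 1e-8 * max(ka, lam2):
            ka = ka * (1.0 + 1e-6) + 1e-12
        c1 = (k21 - lam1) / ((ka - lam1) * (lam2 - lam1))
        c2 = (k21 - lam2) / ((ka - lam2) * (lam1 - lam2))
        c3 = (k21 - ka) / ((lam1 - ka) * (lam2 - ka))
        ktr = a / mtt_d[m]
        lktr = math.log(ktr)
        scale = dose_amt[m] * f_d[m] * ka / vc
        for i in range(obs_t.shape[0]):
            tau = obs_t[i] - dose_t[m]
            if tau <= 0.0:
                continue
            val = (c1 * _conv(a, lga, ktr, lktr, lam1, tau)
                   + c2 * _conv(a, lga, ktr, lktr, lam2, tau)
                   + c3 * _conv(a, lga, ktr, lktr, ka, tau))
            out[i] += scale * val
    for i in range(out.shape[0]):
        if out[i] < 0.0:
            out[i] = 0.0


@njit(cache=True)
def _conv_d(a, lga, ktr, lktr, lam, tau):
    """As :func:`_conv` but also returns (dI/dlam, dI/dktr).

    The derivatives follow each branch analytically: incomplete-gamma
    closed form via dP/dz = z^(a-1) e^(-z) / Gamma(a), the power series via
    S'(z) = -S_{a+1}(z), and the endpoint quadrature by differentiating
    under the integral sign.
    """
    if tau <= 0.0:
        return 0.0, 0.0, 0.0
    d = ktr - lam
    z = d * tau
    if z >= 8.0:
        if z > a + 12.0 * math.sqrt(a) + 40.0:
            I = math.exp(-lam * tau + a * (lktr - math.log(d)))
            return I, I * (-tau + a / d), I * a * (1.0 / ktr - 1.0 / d)
        p = _gammp(a, z, lga)
        if p <= 0.0:
            return 0.0, 0.0, 0.0
        era = math.exp(-lam * tau + a * (lktr - math.log(d)))
        I = era * p
        pz = math.exp((a - 1.0) * math.log(z) - z - lga)
        dIl = I * (-tau + a / d) - era * pz * tau
        dIk = I * a * (1.0 / ktr - 1.0 / d) + era * pz * tau
        return I, dIl, dIk
    if z > -8.0:
        s_acc = 0.0
        s2_acc = 0.0
        term = 1.0
        for kk in range(40):
            s_acc += term / (a + kk)
            s2_acc += term / (a + 1.0 + kk)
            term *= -z / (kk + 1.0)
        C = math.exp(-lam * tau + a * (lktr + math.log(tau)) - lga)
        I = C * s_acc
        dIl = -tau * (I - C * s2_acc)
        dIk = (a / ktr) * I - tau * C * s2_acc
        return I, dIl, dIk
    u = lam - ktr
    vmax = tau if tau < 60.0 / u else 60.0 / u
    half = 0.5 * vmax
    accq = 0.0
    accqv = 0.0
    for i in range(_GL_X.shape[0]):
        v = half * (_GL_X[i] + 1.0)
        base = tau - v
        if base < 1e-300:
            base = 1e-300
        w = half * _GL_W[i] * math.exp((a - 1.0) * math.log(base) - u * v)
        accq += w
        accqv += w * v
    if accq <= 0.0:
        return 0.0, 0.0, 0.0
    I = math.exp(a * lktr - lga - ktr * tau + math.log(accq))
    rv = accqv / accq
    return I, -I * rv, I * (a / ktr - tau + rv)


@njit(cache=True)
def _pred_jac(pred, J, kinds, slots, obs_t, dose_t, dose_amt, dose_slot,
              f_d, mtt_d, ka_d, cl, vc, q, vp, nn):
    """Predictions plus the analytic Jacobian wrt the log-scale effects.

    ``f_d``, ``mtt_d``, ``ka_d`` and ``cl`` are the individual values with
    the effects already applied; the chain rule through
    ``parameter = base * exp(b)`` multiplies each partial by the parameter
    itself, which is done here so that J columns are d(pred)/d(b_k).
    """
    nobs = obs_t.shape[0]
    k = kinds.shape[0]
    for i in range(nobs):
        pred[i] = 0.0
        for kk in range(k):
            J[i, kk] = 0.0
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc2 = s * s - 4.0 * k10 * k21
    disc = math.sqrt(disc2) if disc2 > 0.0 else 0.0
    if disc < 1e-9 * s:
        disc = 1e-9 * s
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    # eigenvalue sensitivities to the log-clearance effect
    ddisc = (s * k10 - 2.0 * k10 * k21) / disc
    dl1 = 0.5 * (k10 + ddisc)
    dl2 = 0.5 * (k10 - ddisc)
    icl = -1
    col_ka = np.full(8, -1, dtype=np.int64)
    col_mtt = np.full(8, -1, dtype=np.int64)
    col_f = np.full(8, -1, dtype=np.int64)
    for kk in range(k):
        kind = kinds[kk]
        if kind == 0:
            icl = kk
        elif kind == 1:
            col_ka[slots[kk]] = kk
        elif kind == 2:
            col_mtt[slots[kk]] = kk
        else:
            col_f[slots[kk]] = kk
    a = nn + 1.0
    lga = math.lgamma(a)
    for m in range(dose_t.shape[0]):
        ka = ka_d[m]
        if abs(ka - lam1) < 1e-8 * max(ka, lam1):
            ka = ka * (1.0 + 1e-6) + 1e-12
        if abs(ka - lam2) < 1e-8 * max(ka, lam2):
            ka = ka * (1.0 + 1e-6) + 1e-12
        d1a = ka - lam1
        d2a = ka - lam2
        d21 = lam2 - lam1
        d12 = -d21
        c1 = (k21 - lam1) / (d1a * d21)
        c2 = (k21 - lam2) / (d2a * d12)
        c3 = (k21 - ka) / ((lam1 - ka) * (lam2 - ka))
        slot = dose_slot[m]
        jka = col_ka[slot]
        jmtt = col_mtt[slot]
        jf = col_f[slot]
        dc1dl1 = dc1dl2 = dc2dl1 = dc2dl2 = dc3dl1 = dc3dl2 = 0.0
        dc1dka = dc2dka = dc3dka = 0.0
        if icl >= 0:
            den1 = d1a * d21
            den2 = d2a * d12
            dc1dl1 = -1.0 / den1 + (k21 - lam1) * (d21 + d1a) / (den1 * den1)
            dc1dl2 = -c1 / d21
            dc2dl2 = -1.0 / den2 + (k21 - lam2) * (d12 + d2a) / (den2 * den2)
            dc2dl1 = -c2 / d12
            dc3dl1 = -c3 / (lam1 - ka)
            dc3dl2 = -c3 / (lam2 - ka)
        if jka >= 0:
            dc1dka = -c1 / d1a
            dc2dka = -c2 / d2a
            dc3dka = c3 * (1.0 / (ka - k21) + 1.0 / (lam1 - ka)
                           + 1.0 / (lam2 - ka))
        ktr = a / mtt_d[m]
        lktr = math.log(ktr)
        scale = dose_amt[m] * f_d[m] * ka / vc
        for i in range(nobs):
            tau = obs_t[i] - dose_t[m]
            if tau <= 0.0:
                continue
            I1, dI1l, dI1k = _conv_d(a, lga, ktr, lktr, lam1, tau)
            I2, dI2l, dI2k = _conv_d(a, lga, ktr, lktr, lam2, tau)
            I3, dI3l, dI3k = _conv_d(a, lga, ktr, lktr, ka, tau)
            val = c1 * I1 + c2 * I2 + c3 * I3
            pred[i] += scale * val
            if jf >= 0:
                J[i, jf] += scale * val
            if jmtt >= 0:
                J[i, jmtt] += scale * (c1 * dI1k + c2 * dI2k
                                       + c3 * dI3k) * (-ktr)
            if jka >= 0:
                J[i, jka] += scale * val + ka * scale * (
                    dc1dka * I1 + dc2dka * I2 + dc3dka * I3 + c3 * dI3l)
            if icl >= 0:
                J[i, icl] += scale * (
                    (dc1dl1 * dl1 + dc1dl2 * dl2) * I1 + c1 * dI1l * dl1
                    + (dc2dl1 * dl1 + dc2dl2 * dl2) * I2 + c2 * dI2l * dl2
                    + (dc3dl1 * dl1 + dc3dl2 * dl2) * I3)
    for i in range(nobs):
        if pred[i] < 0.0:
            pred[i] = 0.0


@njit(cache=True)
def _apply_effects(b, kinds, slots, dose_slot, mtt_b, ka_b, f_b,
                   mtt_d, ka_d, f_d):
    nd = dose_slot.shape[0]
    for m in range(nd):
        mtt_d[m] = mtt_b[m]
        ka_d[m] = ka_b[m]
        f_d[m] = f_b[m]
    cl_fac = 1.0
    for k in range(kinds.shape[0]):
        kind = kinds[k]
        e = math.exp(b[k])
        if kind == 0:
            cl_fac *= e
        else:
            slot = slots[k]
            for m in range(nd):
                if dose_slot[m] == slot:
                    if kind == 1:
                        ka_d[m] *= e
                    elif kind == 2:
                        mtt_d[m] *= e
                    else:
                        f_d[m] *= e
    return cl_fac


@njit(cache=True)
def _subj_obj(b, kinds, slots, sds, obs_t, obs_y, obs_blq, dose_t, dose_amt,
              dose_slot, mtt_b, ka_b, f_b, cl_i, vc, q, vp, nn,
              sig_prop, sig_add, lloq, pred, mtt_d, ka_d, f_d):
    cl_fac = _apply_effects(b, kinds, slots, dose_slot, mtt_b, ka_b, f_b,
                            mtt_d, ka_d, f_d)
    _pred_subject(pred, obs_t, dose_t, dose_amt, f_d, mtt_d, ka_d,
                  cl_i * cl_fac, vc, q, vp, nn)
    val = 0.0
    for i in range(obs_t.shape[0]):
        add = sig_add + 0.5 * lloq if obs_blq[i] else sig_add
        var = pred[i] * pred[i] * sig_prop * sig_prop + add * add
        r = obs_y[i] - pred[i]
        val += math.log(2.0 * math.pi * var) + r * r / var
    for k in range(sds.shape[0]):
        val += b[k] * b[k] / (sds[k] * sds[k]) \
            + math.log(2.0 * math.pi * sds[k] * sds[k])
    return val


@njit(cache=True)
def _chol_solve(H, g, step):
    """Solve H step = g via Cholesky; returns False if H not PD."""
    k = H.shape[0]
    L = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1):
            acc = H[i, j]
            for m in range(j):
                acc -= L[i, m] * L[j, m]
            if i == j:
                if acc <= 0.0:
                    return False
                L[i, i] = math.sqrt(acc)
            else:
                L[i, j] = acc / L[j, j]
    # forward then backward substitution
    y = np.zeros(k)
    for i in range(k):
        acc = g[i]
        for m in range(i):
            acc -= L[i, m] * y[m]
        y[i] = acc / L[i, i]
    for i in range(k - 1, -1, -1):
        acc = y[i]
        for m in range(i + 1, k):
            acc -= L[m, i] * step[m]
        step[i] = acc / L[i, i]
    return True


@njit(cache=True)
def _grad_from_jac(b, sds, obs_y, obs_blq, pred0, J, sig_prop, sig_add,
                   lloq, grad):
    k = sds.shape[0]
    for kk in range(k):
        grad[kk] = 2.0 * b[kk] / (sds[kk] * sds[kk])
    for i in range(obs_y.shape[0]):
        add = sig_add + 0.5 * lloq if obs_blq[i] else sig_add
        var = pred0[i] * pred0[i] * sig_prop * sig_prop + add * add
        dvar = 2.0 * pred0[i] * sig_prop * sig_prop
        r = obs_y[i] - pred0[i]
        dl_df = dvar / var - 2.0 * r / var - r * r * dvar / (var * var)
        for kk in range(k):
            grad[kk] += dl_df * J[i, kk]


@njit(cache=True)
def _inner_newton(b, kinds, slots, sds, obs_t, obs_y, obs_blq, dose_t,
                  dose_amt, dose_slot, mtt_b, ka_b, f_b, cl_i, vc, q, vp,
                  nn, sig_prop, sig_add, lloq, pred, mtt_d, ka_d, f_d,
                  pred0, J, grad, H, step, btry):
    """Gauss-Newton search for the conditional mode (analytic Jacobian).

    Returns (objective, last Newton decrement); a small decrement marks
    convergence independent of the gradient scale.
    """
    nobs = obs_t.shape[0]
    k = sds.shape[0]
    f_cur = _subj_obj(b, kinds, slots, sds, obs_t, obs_y, obs_blq, dose_t,
                      dose_amt, dose_slot, mtt_b, ka_b, f_b, cl_i, vc, q,
                      vp, nn, sig_prop, sig_add, lloq, pred, mtt_d, ka_d,
                      f_d)
    if not np.isfinite(f_cur):
        for i in range(k):
            b[i] = 0.0
        f_cur = _subj_obj(b, kinds, slots, sds, obs_t, obs_y, obs_blq,
                          dose_t, dose_amt, dose_slot, mtt_b, ka_b, f_b,
                          cl_i, vc, q, vp, nn, sig_prop, sig_add, lloq,
                          pred, mtt_d, ka_d, f_d)
    decr = np.inf
    for _it in range(40):
        cl_fac = _apply_effects(b, kinds, slots, dose_slot, mtt_b, ka_b, f_b,
                                mtt_d, ka_d, f_d)
        _pred_jac(pred0, J, kinds, slots, obs_t, dose_t, dose_amt, dose_slot,
                  f_d, mtt_d, ka_d, cl_i * cl_fac, vc, q, vp, nn)
        _grad_from_jac(b, sds, obs_y, obs_blq, pred0, J, sig_prop, sig_add,
                       lloq, grad)
        # Gauss-Newton Hessian
        for kk in range(k):
            for ll in range(k):
                H[kk, ll] = 0.0
            H[kk, kk] = 2.0 / (sds[kk] * sds[kk])
        for i in range(nobs):
            add = sig_add + 0.5 * lloq if obs_blq[i] else sig_add
            var = pred0[i] * pred0[i] * sig_prop * sig_prop + add * add
            dvar = 2.0 * pred0[i] * sig_prop * sig_prop
            w = 2.0 / var + dvar * dvar / (var * var)
            for kk in range(k):
                for ll in range(k):
                    H[kk, ll] += w * J[i, kk] * J[i, ll]
        improved = False
        converged = False
        ridge = 0.0
        decr = np.inf
        for _try in range(6):
            if ridge > 0.0:
                Hr = H.copy()
                for kk in range(k):
                    Hr[kk, kk] += ridge
            else:
                Hr = H
            if _chol_solve(Hr, grad, step):
                if ridge == 0.0:
                    # Newton decrement: expected objective decrease; a
                    # scale-free convergence measure
                    decr = 0.0
                    for kk in range(k):
                        decr += grad[kk] * step[kk]
                    if decr < 1e-12:
                        converged = True
                        break
                t = 1.0
                for _ls in range(25):
                    bad = False
                    for kk in range(k):
                        btry[kk] = b[kk] - t * step[kk]
                        if abs(btry[kk]) > 6.0 * sds[kk]:
                            bad = True
                    if not bad:
                        f_try = _subj_obj(btry, kinds, slots, sds, obs_t,
                                          obs_y, obs_blq, dose_t, dose_amt,
                                          dose_slot, mtt_b, ka_b, f_b, cl_i,
                                          vc, q, vp, nn, sig_prop, sig_add,
                                          lloq, pred, mtt_d, ka_d, f_d)
                        if np.isfinite(f_try) and f_try < f_cur - 1e-14:
                            for kk in range(k):
                                b[kk] = btry[kk]
                            f_cur = f_try
                            improved = True
                            break
                    t *= 0.5
            if improved:
                break
            ridge = 1.0 if ridge == 0.0 else ridge * 10.0
        if converged or not improved:
            break
        smax = 0.0
        for kk in range(k):
            if abs(t * step[kk]) > smax:
                smax = abs(t * step[kk])
        if smax < 1e-11:
            break
    return f_cur, decr


@njit(cache=True)
def _subject_marginal(b, b_ref, kinds, slots, sds, obs_t, obs_y, obs_blq,
                      dose_t, dose_amt, dose_slot, mtt_b, ka_b, f_b, cl_i,
                      vc, q, vp, nn, sig_prop, sig_add, lloq, exact_hess):
    """Laplace -2 log marginal for one subject; b (in/out) holds the mode."""
    nobs = obs_t.shape[0]
    nd = dose_t.shape[0]
    k = sds.shape[0]
    pred = np.empty(nobs)
    mtt_d = np.empty(nd)
    ka_d = np.empty(nd)
    f_d = np.empty(nd)

    if k == 0:
        return _subj_obj(b, kinds, slots, sds, obs_t, obs_y, obs_blq, dose_t,
                         dose_amt, dose_slot, mtt_b, ka_b, f_b, cl_i, vc, q,
                         vp, nn, sig_prop, sig_add, lloq, pred, mtt_d, ka_d,
                         f_d)

    pred0 = np.empty(nobs)
    J = np.empty((nobs, k))
    grad = np.empty(k)
    H = np.empty((k, k))
    step = np.empty(k)
    btry = np.empty(k)

    # the mode search starts from the fixed per-evaluation reference (the
    # origin when none is supplied): a deterministic start makes the
    # marginal an exact function of the parameters, whereas warm starts
    # carried over from other parameter vectors can strand the search in
    # poor local modes of the absorption parameters
    for kk in range(k):
        val = b_ref[kk]
        if not np.isfinite(val) or abs(val) > 6.0 * sds[kk]:
            val = 0.0
        b[kk] = val
    f_cur, decr = _inner_newton(b, kinds, slots, sds, obs_t, obs_y, obs_blq,
                                dose_t, dose_amt, dose_slot, mtt_b, ka_b,
                                f_b, cl_i, vc, q, vp, nn, sig_prop, sig_add,
                                lloq, pred, mtt_d, ka_d, f_d, pred0, J, grad,
                                H, step, btry)
    if not np.isfinite(f_cur):
        return np.inf

    # Hessian for the log-determinant term
    if exact_hess:
        # central finite differences of the analytic gradient
        hh = 1e-5
        gp = np.empty(k)
        gm = np.empty(k)
        He = np.empty((k, k))
        for i1 in range(k):
            for kk in range(k):
                btry[kk] = b[kk]
            btry[i1] += hh
            cf = _apply_effects(btry, kinds, slots, dose_slot, mtt_b, ka_b,
                                f_b, mtt_d, ka_d, f_d)
            _pred_jac(pred0, J, kinds, slots, obs_t, dose_t, dose_amt,
                      dose_slot, f_d, mtt_d, ka_d, cl_i * cf, vc, q, vp, nn)
            _grad_from_jac(btry, sds, obs_y, obs_blq, pred0, J, sig_prop,
                           sig_add, lloq, gp)
            btry[i1] -= 2.0 * hh
            cf = _apply_effects(btry, kinds, slots, dose_slot, mtt_b, ka_b,
                                f_b, mtt_d, ka_d, f_d)
            _pred_jac(pred0, J, kinds, slots, obs_t, dose_t, dose_amt,
                      dose_slot, f_d, mtt_d, ka_d, cl_i * cf, vc, q, vp, nn)
            _grad_from_jac(btry, sds, obs_y, obs_blq, pred0, J, sig_prop,
                           sig_add, lloq, gm)
            for j1 in range(k):
                He[i1, j1] = (gp[j1] - gm[j1]) / (2.0 * hh)
        for i1 in range(k):
            for j1 in range(k):
                H[i1, j1] = 0.5 * (He[i1, j1] + He[j1, i1])
    else:
        # GN Hessian at the mode from the analytic Jacobian
        cl_fac = _apply_effects(b, kinds, slots, dose_slot, mtt_b, ka_b, f_b,
                                mtt_d, ka_d, f_d)
        _pred_jac(pred0, J, kinds, slots, obs_t, dose_t, dose_amt, dose_slot,
                  f_d, mtt_d, ka_d, cl_i * cl_fac, vc, q, vp, nn)
        for kk in range(k):
            for ll in range(k):
                H[kk, ll] = 0.0
            H[kk, kk] = 2.0 / (sds[kk] * sds[kk])
        for i in range(nobs):
            add = sig_add + 0.5 * lloq if obs_blq[i] else sig_add
            var = pred0[i] * pred0[i] * sig_prop * sig_prop + add * add
            dvar = 2.0 * pred0[i] * sig_prop * sig_prop
            w = 2.0 / var + dvar * dvar / (var * var)
            for kk in range(k):
                for ll in range(k):
                    H[kk, ll] += w * J[i, kk] * J[i, ll]

    # log det(H/2) via the eigenvalues, floored at a small fraction of the
    # prior curvature: the exact conditional Hessian can approach
    # singularity in weakly informed directions, where an unbounded
    # log-determinant would let the optimizer chase -infinity; the floor
    # keeps the marginal bounded without affecting well-behaved subjects
    floor = 2.0 / (sds[0] * sds[0])
    for kk in range(1, k):
        c_k = 2.0 / (sds[kk] * sds[kk])
        if c_k < floor:
            floor = c_k
    floor *= 0.02
    w = np.linalg.eigvalsh(H)
    logdet = 0.0
    for i1 in range(k):
        wi = w[i1]
        if not np.isfinite(wi):
            return np.inf
        if wi < floor:
            wi = floor
        logdet += math.log(0.5 * wi)
    return f_cur - k * LOG2PI + logdet


@njit(cache=True)
def _marginal_all(pvec, obs_ptr, obs_t, obs_y, obs_blq, obs_slot,
                  dose_ptr, dose_t, dose_amt, dose_susp, dose_slot,
                  subj_wt, subj_pmage, subj_mdr, subj_nslots,
                  iiv_on, iov_kinds, b_all, b_ref_all, exact_hess):
    (cl, vc, q, vp, ka, mtt_tab, nn, beta_susp, gamma, pmage50, theta,
     target, omega, pi_ka, pi_mtt, pi_f, sig_prop, sig_add, lloq, ref_wt,
     alpha_cl, alpha_v) = (pvec[0], pvec[1], pvec[2], pvec[3], pvec[4],
                           pvec[5], pvec[6], pvec[7], pvec[8], pvec[9],
                           pvec[10], pvec[11], pvec[12], pvec[13], pvec[14],
                           pvec[15], pvec[16], pvec[17], pvec[18], pvec[19],
                           pvec[20], pvec[21])
    n_iov = iov_kinds.shape[0]
    iov_sds = np.empty(n_iov)
    for j in range(n_iov):
        kindj = iov_kinds[j]
        if kindj == 1:
            iov_sds[j] = pi_ka
        elif kindj == 2:
            iov_sds[j] = pi_mtt
        else:
            iov_sds[j] = pi_f
    total = 0.0
    n_subj = obs_ptr.shape[0] - 1
    for s in range(n_subj):
        o0, o1 = obs_ptr[s], obs_ptr[s + 1]
        d0, d1 = dose_ptr[s], dose_ptr[s + 1]
        nslots = subj_nslots[s]
        k = (1 if iiv_on else 0) + nslots * n_iov
        kinds = np.empty(k, dtype=np.int64)
        slots = np.empty(k, dtype=np.int64)
        sds = np.empty(k)
        pos = 0
        if iiv_on:
            kinds[0] = 0
            slots[0] = 0
            sds[0] = omega
            pos = 1
        for slot in range(nslots):
            for j in range(n_iov):
                kinds[pos] = iov_kinds[j]
                slots[pos] = slot
                sds[pos] = iov_sds[j]
                pos += 1
        # covariate-adjusted typicals
        wfac_cl = (subj_wt[s] / ref_wt) ** alpha_cl
        wfac_v = (subj_wt[s] / ref_wt) ** alpha_v
        pm = subj_pmage[s]
        mat = math.exp(gamma * (math.log(pm) - math.log(pmage50)))
        mat = mat / (1.0 + mat)
        cl_i = cl * wfac_cl * mat
        q_i = q * wfac_cl
        vc_i = vc * wfac_v
        vp_i = vp * wfac_v
        nd = d1 - d0
        mtt_b = np.empty(nd)
        ka_b = np.empty(nd)
        f_b = np.empty(nd)
        for m in range(nd):
            mtt_b[m] = mtt_tab * (1.0 + beta_susp) if dose_susp[d0 + m] \
                else mtt_tab
            ka_b[m] = ka
            f_b[m] = pvec[22]
        if target > 0.5 and subj_mdr[s]:
            fac = 1.0 + theta
            if target < 1.5:
                cl_i *= fac
            elif target < 2.5:
                for m in range(nd):
                    f_b[m] *= fac
            elif target < 3.5:
                for m in range(nd):
                    mtt_b[m] *= fac
            else:
                for m in range(nd):
                    ka_b[m] *= fac
        b = b_all[s, :k]
        val = _subject_marginal(
            b, b_ref_all[s, :k], kinds, slots, sds, obs_t[o0:o1],
            obs_y[o0:o1], obs_blq[o0:o1],
            dose_t[d0:d1], dose_amt[d0:d1], dose_slot[d0:d1], mtt_b, ka_b,
            f_b, cl_i, vc_i, q_i, vp_i, nn, sig_prop, sig_add, lloq,
            exact_hess)
        if not np.isfinite(val):
            return np.inf
        total += val
    return total


@njit(cache=True)
def _predict_all(pvec, obs_ptr, obs_t, obs_slot, dose_ptr, dose_t, dose_amt,
                 dose_susp, dose_slot, subj_wt, subj_pmage, subj_mdr,
                 subj_nslots, iiv_on, iov_kinds, b_all, out):
    """Predictions at the observation times given per-subject effects."""
    (cl, vc, q, vp, ka, mtt_tab, nn, beta_susp, gamma, pmage50, theta,
     target, ref_wt, alpha_cl, alpha_v) = (
        pvec[0], pvec[1], pvec[2], pvec[3], pvec[4], pvec[5], pvec[6],
        pvec[7], pvec[8], pvec[9], pvec[10], pvec[11], pvec[19], pvec[20],
        pvec[21])
    n_iov = iov_kinds.shape[0]
    n_subj = obs_ptr.shape[0] - 1
    for s in range(n_subj):
        o0, o1 = obs_ptr[s], obs_ptr[s + 1]
        d0, d1 = dose_ptr[s], dose_ptr[s + 1]
        nslots = subj_nslots[s]
        k = (1 if iiv_on else 0) + nslots * n_iov
        kinds = np.empty(k, dtype=np.int64)
        slots = np.empty(k, dtype=np.int64)
        pos = 0
        if iiv_on:
            kinds[0] = 0
            slots[0] = 0
            pos = 1
        for slot in range(nslots):
            for j in range(n_iov):
                kinds[pos] = iov_kinds[j]
                slots[pos] = slot
                pos += 1
        wfac_cl = (subj_wt[s] / ref_wt) ** alpha_cl
        wfac_v = (subj_wt[s] / ref_wt) ** alpha_v
        pm = subj_pmage[s]
        mat = math.exp(gamma * (math.log(pm) - math.log(pmage50)))
        mat = mat / (1.0 + mat)
        cl_i = cl * wfac_cl * mat
        q_i = q * wfac_cl
        vc_i = vc * wfac_v
        vp_i = vp * wfac_v
        nd = d1 - d0
        mtt_b = np.empty(nd)
        ka_b = np.empty(nd)
        f_b = np.empty(nd)
        for m in range(nd):
            mtt_b[m] = mtt_tab * (1.0 + beta_susp) if dose_susp[d0 + m] \
                else mtt_tab
            ka_b[m] = ka
            f_b[m] = pvec[22]
        if target > 0.5 and subj_mdr[s]:
            fac = 1.0 + theta
            if target < 1.5:
                cl_i *= fac
            elif target < 2.5:
                for m in range(nd):
                    f_b[m] *= fac
            elif target < 3.5:
                for m in range(nd):
                    mtt_b[m] *= fac
            else:
                for m in range(nd):
                    ka_b[m] *= fac
        mtt_d = np.empty(nd)
        ka_d = np.empty(nd)
        f_d = np.empty(nd)
        cl_fac = _apply_effects(b_all[s, :k], kinds, slots,
                                dose_slot[d0:d1], mtt_b, ka_b, f_b,
                                mtt_d, ka_d, f_d)
        _pred_subject(out[o0:o1], obs_t[o0:o1], dose_t[d0:d1],
                      dose_amt[d0:d1], f_d, mtt_d, ka_d, cl_i * cl_fac,
                      vc_i, q_i, vp_i, nn)


# ---------------------------------------------------------------------------
# python-side wrapper
# ---------------------------------------------------------------------------

class FlatData:
    """Flat-array view of a :class:`~pedpk.likelihood.PackedData`."""

    def __init__(self, packed: PackedData):
        subs = packed.subjects
        self.subject_ids = [s.subject_id for s in subs]
        self.obs_ptr = np.cumsum([0] + [len(s.obs_y) for s in subs]).astype(np.int64)
        self.dose_ptr = np.cumsum([0] + [len(s.dose_t) for s in subs]).astype(np.int64)
        self.obs_t = np.concatenate([s.obs_t for s in subs])
        self.obs_y = np.concatenate([s.obs_y for s in subs])
        self.obs_blq = np.concatenate([s.obs_blq for s in subs]).astype(np.bool_)
        self.obs_slot = np.concatenate([s.obs_slot for s in subs]).astype(np.int64)
        self.dose_t = np.concatenate([s.dose_t for s in subs])
        self.dose_amt = np.concatenate([s.dose_amt for s in subs])
        self.dose_susp = np.concatenate([s.dose_susp for s in subs]).astype(np.bool_)
        self.dose_slot = np.concatenate([s.dose_slot for s in subs]).astype(np.int64)
        self.subj_wt = np.array([s.weight for s in subs])
        self.subj_pmage = np.array([s.pmage for s in subs])
        self.subj_mdr = np.array([s.mdr for s in subs], dtype=np.bool_)
        self.subj_nslots = np.array([s.n_slots for s in subs], dtype=np.int64)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


_TARGET_CODE = {None: 0.0, "cl": 1.0, "f": 2.0, "mtt": 3.0, "ka": 4.0}


def params_to_vector(structural, random_effects, error) -> np.ndarray:
    p = structural
    return np.array([
        p.cl, p.vc, p.q, p.vp, p.ka, p.mtt_tablet, p.nn, p.beta_susp,
        p.gamma, p.pmage50, p.theta_mdr, _TARGET_CODE[p.mdr_target],
        random_effects.omega_cl, random_effects.pi_ka,
        random_effects.pi_mtt, random_effects.pi_f,
        error.sigma_prop, error.sigma_add, error.lloq,
        p.ref_weight, p.alpha_cl, p.alpha_v, p.f,
    ])


def _iov_config(spec: RandomEffectsSpec):
    iov_kinds = [k for k, sd in ((1, spec.pi_ka), (2, spec.pi_mtt),
                                 (3, spec.pi_f)) if sd > 0]
    return bool(spec.omega_cl > 0), np.array(iov_kinds, dtype=np.int64)


def max_effect_dim(spec: RandomEffectsSpec) -> int:
    iiv, iov = _iov_config(spec)
    return int(iiv) + 2 * len(iov)


def engine_neg2ll(flat: FlatData, structural, random_effects, error,
                  b_all: np.ndarray, hessian: str = "gn",
                  b_ref: np.ndarray | None = None) -> float:
    """Laplace marginal -2LL via the compiled engine; updates ``b_all``.

    ``b_ref`` supplies fixed per-subject starting modes for the inner
    search (default: the origin); the result is deterministic in
    (parameters, data, ``b_ref``).
    """
    pvec = params_to_vector(structural, random_effects, error)
    iiv_on, iov_kinds = _iov_config(random_effects)
    if b_ref is None:
        b_ref = np.zeros_like(b_all)
    return float(_marginal_all(
        pvec, flat.obs_ptr, flat.obs_t, flat.obs_y, flat.obs_blq,
        flat.obs_slot, flat.dose_ptr, flat.dose_t, flat.dose_amt,
        flat.dose_susp, flat.dose_slot, flat.subj_wt, flat.subj_pmage,
        flat.subj_mdr, flat.subj_nslots, iiv_on, iov_kinds, b_all, b_ref,
        hessian == "exact"))


def engine_predict(flat: FlatData, structural, random_effects, error,
                   b_all: np.ndarray) -> np.ndarray:
    """Predicted concentrations at all observation rows given effects."""
    pvec = params_to_vector(structural, random_effects, error)
    iiv_on, iov_kinds = _iov_config(random_effects)
    out = np.empty(len(flat.obs_t))
    _predict_all(pvec, flat.obs_ptr, flat.obs_t, flat.obs_slot,
                 flat.dose_ptr, flat.dose_t, flat.dose_amt, flat.dose_susp,
                 flat.dose_slot, flat.subj_wt, flat.subj_pmage,
                 flat.subj_mdr, flat.subj_nslots, iiv_on, iov_kinds, b_all,
                 out)
    return out
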