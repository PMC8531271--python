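"""Structural pharmacokinetic model.

Transit-compartment absorption (continuous number of transit compartments
``NN``, mean transit time ``MTT``) feeding a first-order depot (``ka``) and
a two-compartment disposition system with first-order elimination, all
parameterised as apparent oral quantities (CL/F, Vc/F, Q/F, Vp/F).

Size differences are handled by allometric scaling to a reference weight
(exponent 0.75 for clearances, 1.0 for volumes) and clearance maturation by
a sigmoidal Hill function of postmenstrual age,

    MAT(PMAGE) = PMAGE^gamma / (PMAGE50^gamma + PMAGE^gamma),

the fraction of the mature (adult) clearance reached at postmenstrual age
PMAGE (postnatal + gestational age, months).

Because the system is linear in the administered amounts, multiple doses are
handled by superposition.  Each dose contributes, at time ``tau`` after the
dose, the convolution of the gamma-density transit input with the
tri-exponential unit impulse response of the depot + two-compartment chain;
the convolution is evaluated in closed form through the regularised lower
incomplete gamma function, with series/quadrature fallbacks where that
expression is numerically unusable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import special

from .datasets import SubjectCovariates

__all__ = [
    "StructuralParams",
    "DoseEvent",
    "maturation_fraction",
    "allometric_factor",
    "individual_structural_params",
    "transit_input_rate",
    "predict_concentrations",
    "steady_state_history",
    "disposition_eigenvalues",
]


@dataclass(frozen=True)
class StructuralParams:
    """Typical-value (fixed-effect) parameters of the structural model.

    Clearances in L/h, volumes in L, times in h; all apparent oral values
    referenced to a child of ``ref_weight`` kg with fully matured clearance.
    ``beta_susp`` is the proportional effect of the suspension formulation on
    MTT; ``theta_mdr`` a proportional effect of MDR-TB co-treatment on the
    parameter named by ``mdr_target`` (``None`` disables it).
    """

    cl: float
    vc: float
    q: float
    vp: float
    ka: float
    mtt_tablet: float
    nn: float
    f: float = 1.0
    beta_susp: float = 0.0
    gamma: float = 1.0
    pmage50: float = 10.0
    theta_mdr: float = 0.0
    mdr_target: str | None = None  # "cl" | "f" | "mtt" | "ka" | None
    ref_weight: float = 15.0
    alpha_cl: float = 0.75
    alpha_v: float = 1.0

    def __post_init__(self):
        for name in ("cl", "vc", "q", "vp", "ka", "mtt_tablet",
                     "pmage50", "gamma", "f", "ref_weight"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.nn >= 0:
            raise ValueError("nn must be >= 0")
        if not 1.0 + self.beta_susp > 0:
            raise ValueError("1 + beta_susp must be positive")
        if self.mdr_target not in (None, "cl", "f", "mtt", "ka"):
            raise ValueError(f"unknown mdr_target {self.mdr_target!r}")
        if self.mdr_target is not None and not 1.0 + self.theta_mdr > 0:
            raise ValueError("1 + theta_mdr must be positive")

    def mtt_for(self, formulation: str) -> float:
        """Mean transit time for a formulation (crushed pooled with tablet)."""
        if formulation == "suspension":
            return self.mtt_tablet * (1.0 + self.beta_susp)
        return self.mtt_tablet


@dataclass(frozen=True)
class DoseEvent:
    time: float  # h
    amount: float  # mg
    formulation: str = "tablet"

    def __post_init__(self):
        if not self.amount > 0:
            raise ValueError("dose amount must be positive")


def maturation_fraction(pmage, pmage50, gamma):
    """Fraction of mature clearance at postmenstrual age ``pmage`` (months)."""
    pmage = np.asarray(pmage, dtype=float)
    if np.any(pmage <= 0) or pmage50 <= 0 or gamma <= 0:
        raise ValueError("pmage, pmage50 and gamma must be strictly positive")
    # evaluate on the log scale for numerical symmetry at extreme ages
    r = np.exp(gamma * (np.log(pmage) - math.log(pmage50)))
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def allometric_factor(weight, ref_weight, exponent):
    """Power-law body-size scaling factor (weight / ref_weight) ** exponent."""
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0) or ref_weight <= 0:
        raise ValueError("weights must be strictly positive")
    out = (weight / ref_weight) ** exponent
    return float(out) if out.ndim == 0 else out


def individual_structural_params(typ: StructuralParams,
                                 cov: SubjectCovariates) -> StructuralParams:
    """Covariate-adjusted parameters for one subject.

    Applies allometry (CL, Q ~ weight^0.75; Vc, Vp ~ weight^1), clearance
    maturation, the formulation effect on MTT (the returned ``mtt_tablet``
    is the subject's effective MTT and ``beta_susp`` is cleared), and the
    MDR-TB covariate effect if active.  Random effects are applied on top of
    these values by the population model.
    """
    fa_cl = allometric_factor(cov.weight, typ.ref_weight, typ.alpha_cl)
    fa_v = allometric_factor(cov.weight, typ.ref_weight, typ.alpha_v)
    mat = maturation_fraction(cov.pmage, typ.pmage50, typ.gamma)
    cl = typ.cl * fa_cl * mat
    q = typ.q * fa_cl
    vc = typ.vc * fa_v
    vp = typ.vp * fa_v
    mtt = typ.mtt_for(cov.dose_formulation)
    ka = typ.ka
    f = typ.f
    if typ.mdr_target is not None and cov.mdr_tb:
        fac = 1.0 + typ.theta_mdr
        if typ.mdr_target == "cl":
            cl *= fac
        elif typ.mdr_target == "f":
            f *= fac
        elif typ.mdr_target == "mtt":
            mtt *= fac
        elif typ.mdr_target == "ka":
            ka *= fac
    return replace(typ, cl=cl, vc=vc, q=q, vp=vp, ka=ka, f=f,
                   mtt_tablet=mtt, beta_susp=0.0)


def transit_input_rate(t, dose: DoseEvent, f: float, mtt: float, nn: float):
    """Drug input rate (mg/h) of the transit chain at time ``t``.

    The cumulative input is the gamma CDF with shape ``nn + 1`` and rate
    ``ktr = (nn + 1) / mtt`` scaled by ``f * amount``; the rate is the
    corresponding gamma density, evaluated through the log-gamma function.
    """
    if mtt <= 0 or nn < 0:
        raise ValueError("mtt must be positive and nn >= 0")
    t = np.asarray(t, dtype=float)
    tau = t - dose.time
    a = nn + 1.0
    ktr = a / mtt
    with np.errstate(divide="ignore", invalid="ignore"):
        logpdf = (a * math.log(ktr) + (a - 1.0) * np.log(tau)
                  - ktr * tau - math.lgamma(a))
        rate = f * dose.amount * np.exp(logpdf)
    rate = np.where(tau > 0, rate, 0.0)
    if nn == 0:
        rate = np.where(tau == 0, f * dose.amount * ktr, rate)
    return float(rate) if rate.ndim == 0 else rate


# ---------------------------------------------------------------------------
# gamma-density x exponential convolution
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)
_SERIES_CUT = 8.0
_SERIES_TERMS = 40


def gamma_exp_conv(a, ktr, lam, tau):
    """``int_0^tau Gamma(a, ktr).pdf(s) * exp(-lam * (tau - s)) ds``.

    Three regimes, split on z = (ktr - lam) * tau:
    z >= 8: incomplete-gamma closed form; |z| < 8: power series (all-positive
    for z <= 0, mildly alternating otherwise); z <= -8: Gauss-Legendre
    quadrature concentrated at the upper endpoint where the mass sits.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out if out.shape else float(out)
    t = tau[pos]
    d = ktr - lam
    z = d * t
    res = np.empty_like(t)

    m_gam = z >= _SERIES_CUT
    m_ser = np.abs(z) < _SERIES_CUT
    m_qad = z <= -_SERIES_CUT

    if m_gam.any():
        tg = t[m_gam]
        with np.errstate(divide="ignore"):
            logp = np.log(special.gammainc(a, d * tg))
        res[m_gam] = np.exp(-lam * tg + a * (math.log(ktr) - math.log(d))
                            + logp)
    if m_ser.any():
        ts = t[m_ser]
        zs = d * ts
        # S = sum_k (-z)^k / (k! (a + k)); |z| < 8 so the terms are tame
        s_acc = np.zeros_like(ts)
        term = np.ones_like(ts)
        for k in range(_SERIES_TERMS):
            s_acc += term / (a + k)
            term *= -zs / (k + 1.0)
        log_pref = (-lam * ts + a * (math.log(ktr) + np.log(ts))
                    - math.lgamma(a))
        res[m_ser] = np.exp(log_pref) * s_acc
    if m_qad.any():
        tq = t[m_qad]
        u = lam - ktr  # > 0 here
        vmax = np.minimum(tq, 60.0 / u)
        # nodes on [0, vmax], integrand (tau - v)^(a-1) exp(-u v)
        half = 0.5 * vmax
        v = half[:, None] * (_GL_NODES[None, :] + 1.0)
        w = half[:, None] * _GL_WEIGHTS[None, :]
        base = np.clip(tq[:, None] - v, 1e-300, None)
        integ = np.sum(w * np.exp((a - 1.0) * np.log(base) - u * v), axis=1)
        with np.errstate(divide="ignore"):
            res[m_qad] = np.exp(a * math.log(ktr) - math.lgamma(a)
                                - ktr * tq + np.log(np.maximum(integ, 0.0)
                                                    + 1e-300))
    out[pos] = res
    return out


def _disposition(cl, vc, q, vp):
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    return k21, lam1, lam2


def disposition_eigenvalues(params: StructuralParams):
    """(fast, slow) eigenvalues of the two-compartment disposition matrix."""
    _, lam1, lam2 = _disposition(params.cl, params.vc, params.q, params.vp)
    return lam1, lam2


def conc_profile(times, dose_times, dose_amts, dose_f, dose_mtt, dose_ka,
                 cl, vc, q, vp, nn):
    """Concentration (mg/L) at ``times`` for per-dose absorption parameters.

    Low-level superposition engine used by both the public prediction API and
    the simulation machinery; all dose-level arrays are aligned.
    """
    times = np.asarray(times, dtype=float)
    k21, lam1, lam2 = _disposition(cl, vc, q, vp)
    a = nn + 1.0
    conc = np.zeros_like(times)
    for td, amt, f_d, mtt_d, ka_d in zip(dose_times, dose_amts, dose_f,
                                         dose_mtt, dose_ka):
        ka_eff = ka_d
        # guard against coincident absorption/disposition rate constants
        for lam in (lam1, lam2):
            if abs(ka_eff - lam) < 1e-8 * max(ka_eff, lam):
                ka_eff = ka_eff * (1.0 + 1e-6) + 1e-12
        c1 = (k21 - lam1) / ((ka_eff - lam1) * (lam2 - lam1))
        c2 = (k21 - lam2) / ((ka_eff - lam2) * (lam1 - lam2))
        c3 = (k21 - ka_eff) / ((lam1 - ka_eff) * (lam2 - ka_eff))
        ktr = a / mtt_d
        tau = times - td
        contrib = np.zeros_like(times)
        for coef, lam in ((c1, lam1), (c2, lam2), (c3, ka_eff)):
            contrib += coef * gamma_exp_conv(a, ktr, lam, tau)
        conc += amt * f_d * ka_eff / vc * contrib
    return np.clip(conc, 0.0, None)


def predict_concentrations(params: StructuralParams, doses, times):
    """Predicted concentrations (mg/L) at ``times`` after ``doses``.

    ``params`` should be individualised (covariate-adjusted) values; each
    dose uses the MTT of its own formulation.  Times need not be sorted but
    doses are superposed linearly, so order is irrelevant.
    """
    dose_times = np.array([d.time for d in doses], dtype=float)
    dose_amts = np.array([d.amount for d in doses], dtype=float)
    dose_f = np.full(len(doses), params.f)
    dose_mtt = np.array([params.mtt_for(d.formulation) for d in doses])
    dose_ka = np.full(len(doses), params.ka)
    return conc_profile(times, dose_times, dose_amts, dose_f, dose_mtt,
                        dose_ka, params.cl, params.vc, params.q, params.vp,
                        params.nn)


def steady_state_history(interval: float, n_doses: int,
                         dose: DoseEvent) -> list[DoseEvent]:
    """Doses preceding the observed dose at the nominal interval.

    Returns ``n_doses`` doses at ``dose.time - k * interval`` for
    k = n_doses .. 1 (ascending in time), used to generate and fit the
    pre-dose (trough) concentrations of a child at steady state.
    """
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    return [replace(dose, time=dose.time - k * interval)
            for k in range(n_doses, 0, -1)]
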