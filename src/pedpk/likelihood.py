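"""Marginal likelihood of the population model.

The subject-level random effects (one clearance effect per subject, one
absorption/bioavailability triple per occasion) are integrated out of the
joint likelihood with the Laplace approximation around the per-subject joint
mode.  Two Hessian flavours are available for the log-determinant term:

``exact``
    central finite-difference Hessian of the full conditional objective
    (classic Laplace approximation);
``gn``
    Gauss-Newton/expected-information Hessian built from the prediction
    Jacobian (the FOCE-like variant; much cheaper and adequate for the rich
    6-sample profiles this package targets).

Observations imputed at LLOQ/2 enter as Gaussian densities with the
additive error inflated by LLOQ/2; excluded trailing below-LLOQ records
contribute nothing.  A small adaptive Gauss-Hermite quadrature
(:func:`marginal_neg2ll_gh`) serves as an independent accuracy check for
models with one or two random effects per subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datasets import PKDataset, assign_occasions
from .modelspec import ModelSpec
from .random_effects import ErrorModel, RandomEffectsSpec
from .structural import StructuralParams, conc_profile, maturation_fraction

__all__ = ["PackedData", "pack_dataset", "marginal_neg2ll",
           "marginal_neg2ll_gh", "subject_conditional_neg2ll"]

LOG2PI = math.log(2.0 * math.pi)

# random-effect kinds, in per-subject layout order
KIND_ETA_CL, KIND_KA, KIND_MTT, KIND_F = 0, 1, 2, 3


@dataclass
class SubjectData:
    subject_id: str
    obs_t: np.ndarray
    obs_y: np.ndarray
    obs_blq: np.ndarray       # True where imputed below-LLOQ
    obs_slot: np.ndarray      # occasion slot per observation (0-based)
    dose_t: np.ndarray
    dose_amt: np.ndarray
    dose_susp: np.ndarray     # bool, suspension formulation
    dose_slot: np.ndarray
    n_slots: int
    weight: float
    pmage: float
    mdr: bool
    n_excluded: int = 0


@dataclass
class PackedData:
    subjects: list[SubjectData]

    @property
    def n_obs(self) -> int:
        return sum(len(s.obs_y) for s in self.subjects)


def pack_dataset(dataset: PKDataset,
                 include_excluded: bool = False) -> PackedData:
    """Flatten a preprocessed dataset into per-subject arrays.

    Occasions are assigned if missing.  Raw (unprocessed) below-LLOQ flags
    are rejected: apply :func:`pedpk.datasets.preprocess_blq` first.
    Excluded (trailing below-LLOQ) observations are dropped from the
    likelihood here but counted for bookkeeping;
    ``include_excluded=True`` keeps them (simulation/diagnostic use).
    """
    df = dataset.records
    if (df["BLQ"] > 0).any() and not dataset.blq_processed:
        raise ValueError("dataset contains raw below-LLOQ flags; "
                         "run preprocess_blq first")
    if df.loc[df["EVID"] == 0, "OCC"].isna().any():
        dataset = assign_occasions(dataset)
        df = dataset.records
    subjects = []
    for sid in dataset.subjects:
        sub = df[df["ID"] == sid]
        keep = (sub["EVID"] == 0) if include_excluded \
            else ((sub["EVID"] == 0) & (sub["BLQ"] != 2))
        obs = sub[keep]
        n_excl = int(((sub["EVID"] == 0) & (sub["BLQ"] == 2)).sum())
        doses = sub[sub["EVID"] == 1]
        occs = sorted(obs["OCC"].dropna().unique())
        slot_of = {occ: i for i, occ in enumerate(occs)}
        cov = dataset.covariates[sid]
        dose_occ = doses["OCC"].to_numpy(dtype=float)
        dose_slot = np.array([slot_of.get(o, 0) for o in dose_occ], dtype=np.int64)
        subjects.append(SubjectData(
            subject_id=sid,
            obs_t=obs["TIME"].to_numpy(dtype=float),
            obs_y=obs["DV"].to_numpy(dtype=float),
            obs_blq=(obs["BLQ"].to_numpy(dtype=int) == 1),
            obs_slot=np.array([slot_of[o] for o in obs["OCC"]],
                              dtype=np.int64),
            dose_t=doses["TIME"].to_numpy(dtype=float),
            dose_amt=doses["AMT"].to_numpy(dtype=float),
            dose_susp=(sub.loc[sub["EVID"] == 1, "FORM"]
                       .map(lambda f: f == "suspension").to_numpy()),
            dose_slot=dose_slot,
            n_slots=max(len(occs), 1),
            weight=cov.weight, pmage=cov.pmage, mdr=cov.mdr_tb,
            n_excluded=n_excl,
        ))
    return PackedData(subjects)


def effect_layout(spec: RandomEffectsSpec, n_slots: int):
    """(kinds, slots, sds) of the active random effects for a subject."""
    kinds, slots, sds = [], [], []
    if spec.omega_cl > 0:
        kinds.append(KIND_ETA_CL); slots.append(0); sds.append(spec.omega_cl)
    for s in range(n_slots):
        for kind, sd in ((KIND_KA, spec.pi_ka), (KIND_MTT, spec.pi_mtt),
                         (KIND_F, spec.pi_f)):
            if sd > 0:
                kinds.append(kind); slots.append(s); sds.append(sd)
    return (np.array(kinds, dtype=np.int64), np.array(slots, dtype=np.int64),
            np.array(sds, dtype=float))


def _subject_typicals(sub: SubjectData, p: StructuralParams):
    """Covariate-adjusted typical values and per-dose absorption arrays."""
    fa_cl = (sub.weight / p.ref_weight) ** p.alpha_cl
    fa_v = (sub.weight / p.ref_weight) ** p.alpha_v
    cl = p.cl * fa_cl * maturation_fraction(sub.pmage, p.pmage50, p.gamma)
    q = p.q * fa_cl
    vc = p.vc * fa_v
    vp = p.vp * fa_v
    mtt_d = np.where(sub.dose_susp, p.mtt_tablet * (1.0 + p.beta_susp),
                     p.mtt_tablet)
    ka_d = np.full(len(sub.dose_t), p.ka)
    f_d = np.full(len(sub.dose_t), p.f)
    if p.mdr_target is not None and sub.mdr:
        fac = 1.0 + p.theta_mdr
        if p.mdr_target == "cl":
            cl *= fac
        elif p.mdr_target == "f":
            f_d = f_d * fac
        elif p.mdr_target == "mtt":
            mtt_d = mtt_d * fac
        elif p.mdr_target == "ka":
            ka_d = ka_d * fac
    return cl, vc, q, vp, ka_d, mtt_d, f_d


def _subject_pred(sub: SubjectData, p: StructuralParams, kinds, slots, b):
    cl, vc, q, vp, ka_d, mtt_d, f_d = _subject_typicals(sub, p)
    for k, (kind, slot) in enumerate(zip(kinds, slots)):
        e = math.exp(b[k])
        if kind == KIND_ETA_CL:
            cl *= e
        else:
            on = sub.dose_slot == slot
            if kind == KIND_KA:
                ka_d = np.where(on, ka_d * e, ka_d)
            elif kind == KIND_MTT:
                mtt_d = np.where(on, mtt_d * e, mtt_d)
            else:
                f_d = np.where(on, f_d * e, f_d)
    return conc_profile(sub.obs_t, sub.dose_t, sub.dose_amt, f_d, mtt_d,
                        ka_d, cl, vc, q, vp, p.nn)


def _obs_neg2ll(sub: SubjectData, err: ErrorModel, pred):
    add = np.where(sub.obs_blq, err.sigma_add + err.lloq / 2.0, err.sigma_add)
    var = pred ** 2 * err.sigma_prop ** 2 + add ** 2
    r = sub.obs_y - pred
    return float(np.sum(np.log(2.0 * math.pi * var) + r * r / var))


def subject_conditional_neg2ll(sub: SubjectData, p: StructuralParams,
                               err: ErrorModel, kinds, slots, sds, b):
    """-2 log of the joint density of (observations, random effects)."""
    pred = _subject_pred(sub, p, kinds, slots, b)
    val = _obs_neg2ll(sub, err, pred)
    if len(sds):
        val += float(np.sum(b * b / sds ** 2 + np.log(2.0 * math.pi * sds ** 2)))
    return val


def _subject_laplace(sub, p, err, kinds, slots, sds, b0, hessian="exact"):
    k = len(sds)
    if k == 0:
        return _obs_neg2ll(sub, err, _subject_pred(sub, p, kinds, slots,
                                                   np.zeros(0))), np.zeros(0)
    obj = lambda b: subject_conditional_neg2ll(sub, p, err, kinds, slots,
                                               sds, b)
    res = optimize.minimize(obj, b0, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 200})
    bhat = res.x
    if hessian == "gn":
        H = _gn_hessian(sub, p, err, kinds, slots, sds, bhat)
    else:
        H = _fd_hessian(obj, bhat)
    sign, logdet = np.linalg.slogdet(H / 2.0)
    if sign <= 0:  # fall back to the always-PD expected information
        H = _gn_hessian(sub, p, err, kinds, slots, sds, bhat)
        sign, logdet = np.linalg.slogdet(H / 2.0)
    return obj(bhat) - k * LOG2PI + logdet, bhat


def _fd_hessian(obj, x, h=1e-4):
    k = len(x)
    H = np.empty((k, k))
    f0 = obj(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (obj(xpp) - obj(xpm) - obj(xmp) + obj(xmm)) \
                / (4.0 * h * h)
    # symmetrise tiny asymmetries from roundoff
    return 0.5 * (H + H.T) if k else H


def _pred_jacobian(sub, p, kinds, slots, b, h=1e-5):
    f0 = _subject_pred(sub, p, kinds, slots, b)
    J = np.empty((len(f0), len(b)))
    for k in range(len(b)):
        bp = b.copy()
        bp[k] += h
        J[:, k] = (_subject_pred(sub, p, kinds, slots, bp) - f0) / h
    return f0, J

def _gn_hessian(sub, p, err, kinds, slots, sds, b):
    """Expected-information Hessian from the prediction Jacobian."""
    pred, J = _pred_jacobian(sub, p, kinds, slots, b)
    add = np.where(sub.obs_blq, err.sigma_add + err.lloq / 2.0, err.sigma_add)
    var = pred ** 2 * err.sigma_prop ** 2 + add ** 2
    dvar = 2.0 * pred * err.sigma_prop ** 2
    # d2/df2 of log var + r^2/var at r = 0 plus the curvature of log var
    w = 2.0 / var + dvar ** 2 / var ** 2
    H = (J * w[:, None]).T @ J
    H += np.diag(2.0 / sds ** 2)
    return H


def marginal_neg2ll(packed: PackedData, structural: StructuralParams,
                    random_effects: RandomEffectsSpec, error: ErrorModel,
                    hessian: str = "exact", warm: dict | None = None):
    """Laplace-approximated -2 log marginal likelihood of the dataset.

    Returns ``(value, ebes)`` where ``ebes`` maps subject id to the modal
    random-effect vector (the empirical Bayes estimates).  ``warm`` may
    carry starting modes from a previous evaluation.
    """
    total = 0.0
    ebes: dict[str, np.ndarray] = {}
    for sub in packed.subjects:
        kinds, slots, sds = effect_layout(random_effects, sub.n_slots)
        b0 = (warm or {}).get(sub.subject_id)
        if b0 is None or len(b0) != len(sds):
            b0 = np.zeros(len(sds))
        val, bhat = _subject_laplace(sub, structural, error, kinds, slots,
                                     sds, b0, hessian=hessian)
        if not np.isfinite(val):
            raise FloatingPointError(
                f"inner optimisation failed for subject {sub.subject_id}")
        total += val
        ebes[sub.subject_id] = bhat
    return total, ebes


def marginal_neg2ll_gh(packed: PackedData, structural: StructuralParams,
                       random_effects: RandomEffectsSpec, error: ErrorModel,
                       n_nodes: int = 64) -> float:
    """Adaptive Gauss-Hermite oracle for models with <= 2 effects/subject.

    Centred at the per-subject mode with the exact finite-difference
    Hessian; intended as an independent accuracy check of the Laplace
    approximation on small problems.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for sub in packed.subjects:
        kinds, slots, sds = effect_layout(random_effects, sub.n_slots)
        k = len(sds)
        if k > 2:
            raise ValueError("quadrature oracle supports at most 2 effects")
        obj = lambda b: subject_conditional_neg2ll(sub, structural, error,
                                                   kinds, slots, sds, b)
        if k == 0:
            total += obj(np.zeros(0))
            continue
        res = optimize.minimize(obj, np.zeros(k), method="BFGS",
                                options={"gtol": 1e-8})
        bhat = res.x
        H = _fd_hessian(obj, bhat)
        C = np.linalg.inv(H / 2.0)  # covariance scale of exp(-l/2)
        L = np.linalg.cholesky(C)
        if k == 1:
            zs = nodes[:, None]
            ws = weights
        else:
            g1, g2 = np.meshgrid(nodes, nodes, indexing="ij")
            zs = np.column_stack([g1.ravel(), g2.ravel()])
            ws = np.outer(weights, weights).ravel()
        log_terms = np.empty(len(zs))
        for i, z in enumerate(zs):
            b = bhat + math.sqrt(2.0) * (L @ z)
            log_terms[i] = -0.5 * obj(b) + np.sum(z * z)
        m = log_terms.max()
        integral = math.sqrt(2.0) ** k * abs(np.linalg.det(L)) \
            * np.exp(m) * np.sum(ws * np.exp(log_terms - m))
        total += -2.0 * (math.log(integral))
    return total
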