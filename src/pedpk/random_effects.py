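"""Random-effects structure and residual-error model.

Between-subject variability (BSV/IIV) acts on clearance; between-occasion
variability (BOV/IOV) acts on the absorption rate constant, the mean transit
time and relative bioavailability.  All random effects are lognormal: an
individual parameter is the covariate-adjusted typical value multiplied by
``exp(eta)`` with ``eta ~ N(0, sd^2)`` on the log scale, so the reported
percent variabilities are the log-scale standard deviations x 100.

Residual unexplained variability is a combined additive + proportional
Gaussian model.  For below-LLOQ observations imputed at LLOQ/2 the additive
SD is inflated by LLOQ/2 to reflect the imputation uncertainty, and the
additive SD is bounded below by 20% of the assay LLOQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structural import StructuralParams

__all__ = ["RandomEffectsSpec", "ErrorModel", "draw_random_effects",
           "individualize", "residual_sd"]

IOV_NAMES = ("ka", "mtt", "f")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Log-scale standard deviations of the random effects.

    ``omega_cl`` is the BSV SD on clearance; ``pi_ka``, ``pi_mtt`` and
    ``pi_f`` are BOV SDs.  ``correlations`` is the correlation matrix of
    (eta_cl, kappa_ka, kappa_mtt, kappa_f); the final models carry none, so
    it defaults to identity.
    """

    omega_cl: float = 0.0
    pi_ka: float = 0.0
    pi_mtt: float = 0.0
    pi_f: float = 0.0
    correlations: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        for name in ("omega_cl", "pi_ka", "pi_mtt", "pi_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        corr = np.asarray(self.correlations, dtype=float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise ValueError("correlations must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        object.__setattr__(self, "correlations", corr)

    @property
    def iov_sds(self) -> np.ndarray:
        return np.array([self.pi_ka, self.pi_mtt, self.pi_f])


@dataclass(frozen=True)
class ErrorModel:
    """Combined additive (mg/L) + proportional residual error."""

    sigma_prop: float = 0.0
    sigma_add: float = 0.0048
    lloq: float = 0.024

    def __post_init__(self):
        if self.sigma_prop < 0:
            raise ValueError("sigma_prop must be >= 0")
        if not self.lloq > 0:
            raise ValueError("lloq must be positive")
        if self.sigma_add < 0.2 * self.lloq - 1e-12:
            raise ValueError(
                f"sigma_add must be at least 20% of the LLOQ "
                f"({0.2 * self.lloq:.4g} mg/L), got {self.sigma_add}")


def residual_sd(error: ErrorModel, pred, blq_imputed=False):
    """Residual SD (mg/L) at prediction ``pred``.

    Combined model: ``sqrt(pred^2 sigma_prop^2 + sigma_add_eff^2)`` with the
    additive component inflated by LLOQ/2 for imputed below-LLOQ records.
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be non-negative")
    add = np.where(blq_imputed, error.sigma_add + error.lloq / 2.0,
                   error.sigma_add)
    out = np.sqrt(pred ** 2 * error.sigma_prop ** 2 + add ** 2)
    return float(out) if out.ndim == 0 else out


def draw_random_effects(spec: RandomEffectsSpec, n_subjects: int,
                        occasions_per_subject, seed) -> pd.DataFrame:
    """Sample one eta_cl per subject plus one BOV triple per occasion.

    ``occasions_per_subject`` is a list of occasion counts (1 or 2).
    Returns a tidy frame with one row per subject-occasion; ``eta_cl`` is
    repeated across a subject's occasions.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    occasions_per_subject = list(occasions_per_subject)
    if len(occasions_per_subject) != n_subjects:
        raise ValueError("one occasion count per subject required")
    sds = np.array([spec.omega_cl, spec.pi_ka, spec.pi_mtt, spec.pi_f])
    cov = spec.correlations * np.outer(sds, sds)
    # draw via Cholesky of the (possibly singular) covariance
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rows = []
    for i, n_occ in enumerate(occasions_per_subject):
        z = rng.standard_normal(4)
        eta_cl = (root @ z)[0]
        for occ in range(1, n_occ + 1):
            if occ == 1:
                kap = (root @ z)[1:]
            else:
                kap = (root @ rng.standard_normal(4))[1:]
            rows.append({"subject": i, "occasion": occ, "eta_cl": eta_cl,
                         "kappa_ka": kap[0], "kappa_mtt": kap[1],
                         "kappa_f": kap[2]})
    return pd.DataFrame(rows)


def individualize(params: StructuralParams, eta_cl: float = 0.0,
                  kappa_ka: float = 0.0, kappa_mtt: float = 0.0,
                  kappa_f: float = 0.0) -> StructuralParams:
    """Apply lognormal random effects to covariate-adjusted parameters.

    ``params`` should already be individualised for covariates (see
    :func:`pedpk.structural.individual_structural_params`); the returned
    values are the occasion-specific individual parameters.
    """
    return replace(params,
                   cl=params.cl * np.exp(eta_cl),
                   ka=params.ka * np.exp(kappa_ka),
                   mtt_tablet=params.mtt_tablet * np.exp(kappa_mtt),
                   f=params.f * np.exp(kappa_f))
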