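"""Parameter uncertainty by sampling importance resampling (SIR).

Proposal vectors are drawn from a multivariate normal centred at the
estimate on the estimation (log) scale, with covariance from the outer
Hessian inflated by a safety factor; each draw is weighted by the ratio of
the model likelihood to the proposal density and ``n`` vectors are
resampled without replacement.  Percentiles of the resample give the
parameter intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SIRResult", "sir", "sir_uncertainty"]


@dataclass
class SIRResult:
    names: tuple[str, ...]
    resampled: np.ndarray      # n x p, natural scale
    intervals: dict            # name -> (lo, hi), natural scale
    medians: dict
    ess: float
    m_samples: int
    n_resamples: int

    def frame(self) -> pd.DataFrame:
        rows = [{"parameter": n, "median": self.medians[n],
                 "ci2.5": self.intervals[n][0],
                 "ci97.5": self.intervals[n][1]} for n in self.names]
        return pd.DataFrame(rows)


def sir(neg2ll_fn, x_mode: np.ndarray, cov: np.ndarray, m_samples: int,
        n_resamples: int, seed: int, inflate: float = 1.5,
        min_ess: float = 10.0):
    """Core SIR on an arbitrary -2 log-likelihood surface.

    Returns ``(resampled_x, weights, ess)`` with ``resampled_x`` the
    ``n_resamples`` parameter vectors drawn without replacement from the
    weighted proposal sample.  Raises if the effective sample size of the
    weights falls below ``min_ess`` (advice: inflate the proposal).
    """
    if n_resamples > m_samples:
        raise ValueError("cannot resample more vectors than proposed")
    rng = np.random.default_rng(seed)
    p = len(x_mode)
    cov_prop = inflate ** 2 * cov
    L = np.linalg.cholesky(cov_prop + 1e-12 * np.eye(p))
    z = rng.standard_normal((m_samples, p))
    draws = x_mode + z @ L.T
    f0 = neg2ll_fn(x_mode)
    logw = np.empty(m_samples)
    for i in range(m_samples):
        # log target - log proposal (up to constants)
        quad = 0.5 * z[i] @ z[i]
        logw[i] = -0.5 * (neg2ll_fn(draws[i]) - f0) + quad
    logw -= logw.max()
    w = np.exp(logw)
    w_sum = w.sum()
    ess = w_sum ** 2 / np.sum(w ** 2)
    if ess < min_ess:
        raise RuntimeError(
            f"degenerate SIR weights (effective sample size {ess:.1f}); "
            "increase the proposal inflation factor")
    probs = w / w_sum
    idx = rng.choice(m_samples, size=n_resamples, replace=False, p=probs)
    return draws[idx], w, float(ess)


def sir_uncertainty(results, m_samples: int = 1000, n_resamples: int = 200,
                    seed: int | None = None, inflate: float = 1.5) -> SIRResult:
    """SIR intervals for a fitted population model.

    ``results`` is a :class:`~pedpk.model.PopPKResults`; the proposal
    covariance comes from its outer Hessian.  Intervals are reported on the
    natural parameter scale.
    """
    if seed is None:
        raise ValueError("a seed is required for SIR")
    if not results.converged:
        raise ValueError("SIR requires a converged fit")
    from ._engine import engine_neg2ll, max_effect_dim
    from .model import _LOG1P

    model = results.model
    b_all = np.zeros((model.flat.n_subjects,
                      max_effect_dim(results.spec.random_effects)))

    def obj(x):
        spec = results.space.to_spec(x)
        try:
            val = engine_neg2ll(model.flat, spec.structural,
                                spec.random_effects, spec.error, b_all,
                                hessian="gn")
        except Exception:  # noqa: BLE001
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return val + model._prior_penalty(spec, results.priors)

    cov = results.cov_matrix()
    draws, w, ess = sir(obj, results.x, cov, m_samples, n_resamples, seed,
                        inflate=inflate)
    natural = np.empty_like(draws)
    for j, name in enumerate(results.free):
        natural[:, j] = np.expm1(draws[:, j]) if name in _LOG1P \
            else np.exp(draws[:, j])
    intervals = {}
    medians = {}
    for j, name in enumerate(results.free):
        lo, mid, hi = np.percentile(natural[:, j], [2.5, 50.0, 97.5])
        intervals[name] = (float(lo), float(hi))
        medians[name] = float(mid)
    return SIRResult(names=tuple(results.free), resampled=natural,
                     intervals=intervals, medians=medians, ess=ess,
                     m_samples=m_samples, n_resamples=n_resamples)
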