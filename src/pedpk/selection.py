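"""Likelihood-ratio testing and stepwise covariate selection.

Covariate effects are parameterised multiplicatively, ``P -> P (1 + theta)``
in the covariate group.  Selection follows the conventional stepwise
procedure: forward inclusion at p < 0.05 on the drop in -2LL, backward
elimination at p < 0.01 (one extra parameter: a drop larger than the
chi-square(1) 99% quantile, 6.63, is significant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy import stats

from .model import PopPKModel
from .modelspec import ModelSpec

__all__ = ["LRTResult", "lrt", "CovariateSearchResult", "covariate_search"]


@dataclass(frozen=True)
class LRTResult:
    delta: float      # neg2ll_reduced - neg2ll_full
    df: int
    alpha: float
    threshold: float
    pvalue: float
    significant: bool


def lrt(neg2ll_full: float, neg2ll_reduced: float, df: int = 1,
        alpha: float = 0.01) -> LRTResult:
    """Likelihood-ratio test between nested fits.

    The test statistic is the drop in -2LL from the reduced to the full
    model, referred to the chi-square distribution with ``df`` degrees of
    freedom.  A negative drop (full fit worse than reduced) triggers a
    warning and is never significant.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = neg2ll_reduced - neg2ll_full
    if delta < -1e-6:
        warnings.warn(f"full model fits worse than reduced (delta = "
                      f"{delta:.4g}); check convergence", stacklevel=2)
    threshold = float(stats.chi2.ppf(1.0 - alpha, df))
    pvalue = float(stats.chi2.sf(max(delta, 0.0), df))
    return LRTResult(delta=float(delta), df=df, alpha=alpha,
                     threshold=threshold, pvalue=pvalue,
                     significant=bool(delta > threshold))


@dataclass
class CovariateSearchResult:
    spec: ModelSpec               # selected model specification
    selected: list[tuple[str, str]]
    log: list[dict] = field(default_factory=list)

    def __repr__(self):
        sel = ", ".join(f"{c} on {p}" for c, p in self.selected) or "none"
        return f"<CovariateSearchResult selected: {sel}, {len(self.log)} steps>"


def covariate_search(dataset, base_spec: ModelSpec, candidates,
                     forward_alpha: float = 0.05,
                     backward_alpha: float = 0.01,
                     method: str = "foce", fixed=(), priors=None,
                     **fit_kwargs) -> CovariateSearchResult:
    """Stepwise forward/backward search over candidate covariate effects.

    ``candidates`` is a list of ``(covariate, parameter)`` pairs; the MDR-TB
    group flag tested on clearance, bioavailability, mean transit time or
    the absorption rate constant (``("mdr_tb", "cl")`` etc.).  The model
    carries at most one active group effect, so the forward pass includes
    the single most significant candidate; the backward pass then re-tests
    it at the stricter level.  Candidates whose fit fails are skipped and
    logged.  Returns the selected specification plus the full decision log.
    """
    for cov, par in candidates:
        if cov != "mdr_tb":
            raise ValueError(f"unsupported covariate {cov!r}")
        if par not in ("cl", "f", "mtt", "ka"):
            raise ValueError(f"unsupported parameter {par!r}")
    log: list[dict] = []
    base_model = PopPKModel(dataset, base_spec.without_mdr_effect(),
                            priors=priors)
    base_fit = base_model.fit(method=method, fixed=fixed, **fit_kwargs)
    best = None
    for cov, par in candidates:
        spec_c = base_spec.with_mdr_effect(par, 0.0)
        try:
            fit_c = PopPKModel(dataset, spec_c, priors=priors).fit(
                method=method, fixed=fixed, **fit_kwargs)
            test = lrt(fit_c.neg2ll, base_fit.neg2ll, df=1,
                       alpha=forward_alpha)
        except Exception as exc:  # noqa: BLE001 - skip failing candidates
            log.append({"step": "forward", "covariate": cov,
                        "parameter": par, "error": str(exc)})
            continue
        log.append({"step": "forward", "covariate": cov, "parameter": par,
                    "delta_neg2ll": test.delta, "threshold": test.threshold,
                    "significant": test.significant,
                    "theta": fit_c.spec.structural.theta_mdr})
        if test.significant and (best is None
                                 or test.delta > best[2].delta):
            best = ((cov, par), fit_c, test)
    if best is None:
        return CovariateSearchResult(spec=base_fit.spec, selected=[],
                                     log=log)
    (cov, par), fit_c, _ = best
    back = lrt(fit_c.neg2ll, base_fit.neg2ll, df=1, alpha=backward_alpha)
    log.append({"step": "backward", "covariate": cov, "parameter": par,
                "delta_neg2ll": back.delta, "threshold": back.threshold,
                "significant": back.significant})
    if not back.significant:
        return CovariateSearchResult(spec=base_fit.spec, selected=[],
                                     log=log)
    return CovariateSearchResult(spec=fit_c.spec, selected=[(cov, par)],
                                 log=log)
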