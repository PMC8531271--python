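"""Marginal likelihood: closed-form degenerate case, quadrature oracle,
compiled-engine parity, additivity, censored-record handling."""

import math
from dataclasses import replace

import numpy as np
import pytest

from pedpk._engine import (FlatData, engine_neg2ll, engine_predict,
                           max_effect_dim)
from pedpk.datasets import preprocess_blq
from pedpk.likelihood import (PackedData, marginal_neg2ll,
                              marginal_neg2ll_gh, pack_dataset)


@pytest.fixture(scope="module")
def packed(small_dataset):
    return pack_dataset(preprocess_blq(small_dataset))


@pytest.fixture(scope="module")
def packed4(packed):
    """First four subjects: keeps the quadrature oracle affordable."""
    return PackedData(packed.subjects[:4])


def test_raw_blq_flags_rejected(small_cohort, lam_model):
    from pedpk.cohort import simulate_observations
    spec = replace(lam_model, error=replace(lam_model.error, lloq=0.3,
                                            sigma_add=0.06))
    raw = simulate_observations(small_cohort, spec, seed=5)
    assert (raw.records["BLQ"] > 0).any()
    with pytest.raises(ValueError, match="preprocess"):
        pack_dataset(raw)


def test_no_random_effects_is_closed_form_gaussian(packed, lam_model):
    """With all SDs at zero the Laplace approximation must be exact."""
    re0 = replace(lam_model.random_effects, omega_cl=0.0, pi_ka=0.0,
                  pi_mtt=0.0, pi_f=0.0)
    got, _ = marginal_neg2ll(packed, lam_model.structural, re0,
                             lam_model.error)
    # direct sum of Gaussian -2 log densities at the typical prediction
    from pedpk.likelihood import _subject_pred
    expected = 0.0
    err = lam_model.error
    for sub in packed.subjects:
        pred = _subject_pred(sub, lam_model.structural,
                             np.empty(0, dtype=np.int64),
                             np.empty(0, dtype=np.int64), np.empty(0))
        add = np.where(sub.obs_blq, err.sigma_add + err.lloq / 2,
                       err.sigma_add)
        var = pred ** 2 * err.sigma_prop ** 2 + add ** 2
        expected += float(np.sum(np.log(2 * math.pi * var)
                                 + (sub.obs_y - pred) ** 2 / var))
    assert got == pytest.approx(expected, abs=1e-8)


@pytest.mark.parametrize("hessian,tol", [("exact", 0.1), ("gn", 1.2)])
def test_laplace_matches_quadrature_one_effect(packed4, lam_model, hessian,
                                               tol):
    """Single clearance effect: 64-node adaptive quadrature oracle.

    The observed-information (exact-Hessian) Laplace approximation tracks
    the integral closely; the expected-information flavour trades a known,
    bounded extra error (~0.1-0.3 per subject here) for robustness
    and speed.
    """
    re1 = replace(lam_model.random_effects, pi_ka=0.0, pi_mtt=0.0, pi_f=0.0)
    lap, _ = marginal_neg2ll(packed4, lam_model.structural, re1,
                             lam_model.error, hessian=hessian)
    gh = marginal_neg2ll_gh(packed4, lam_model.structural, re1,
                            lam_model.error)
    assert abs(lap - gh) < tol


def test_laplace_matches_quadrature_two_effects(packed, lam_model):
    """Clearance + bioavailability effects, product-grid oracle."""
    re2 = replace(lam_model.random_effects, pi_ka=0.0, pi_mtt=0.0)
    # restrict to single-occasion layout: use subjects with 1 slot only,
    # otherwise kappa_f appears twice
    subs = [s for s in packed.subjects if s.n_slots == 1]
    if not subs:  # all subjects have pre-dose samples: collapse to one slot
        subs = packed.subjects[:2]
        for s in subs:
            s.n_slots = 1
            s.obs_slot = np.zeros_like(s.obs_slot)
            s.dose_slot = np.zeros_like(s.dose_slot)
    p2 = PackedData(subs[:2])
    lap, _ = marginal_neg2ll(p2, lam_model.structural, re2, lam_model.error,
                             hessian="exact")
    gh = marginal_neg2ll_gh(p2, lam_model.structural, re2, lam_model.error)
    assert abs(lap - gh) < 0.1


def test_additivity_over_subjects(packed4, lam_model):
    m = lam_model
    whole, _ = marginal_neg2ll(packed4, m.structural, m.random_effects,
                               m.error, hessian="gn")
    parts = 0.0
    for sub in packed4.subjects:
        v, _ = marginal_neg2ll(PackedData([sub]), m.structural,
                               m.random_effects, m.error, hessian="gn")
        parts += v
    assert whole == pytest.approx(parts, abs=1e-6)


def test_duplicate_subject_adds_its_contribution(packed4, lam_model):
    m = lam_model
    base, _ = marginal_neg2ll(packed4, m.structural, m.random_effects,
                              m.error, hessian="gn")
    one, _ = marginal_neg2ll(PackedData([packed4.subjects[0]]), m.structural,
                             m.random_effects, m.error, hessian="gn")
    dup = PackedData(packed4.subjects + [packed4.subjects[0]])
    both, _ = marginal_neg2ll(dup, m.structural, m.random_effects, m.error,
                              hessian="gn")
    assert both == pytest.approx(base + one, abs=1e-6)


@pytest.mark.parametrize("hessian", ["gn", "exact"])
def test_engine_matches_reference(packed4, lam_model, hessian):
    """Compiled engine and pure-python reference agree."""
    m = lam_model
    ref, _ = marginal_neg2ll(packed4, m.structural, m.random_effects,
                             m.error, hessian=hessian)
    flat = FlatData(packed4)
    b = np.zeros((flat.n_subjects, max_effect_dim(m.random_effects)))
    got = engine_neg2ll(flat, m.structural, m.random_effects, m.error, b,
                        hessian=hessian)
    # the two inner optimisers differ slightly in their final modes
    assert got == pytest.approx(ref, abs=0.05)


def test_engine_deterministic(packed, lam_model):
    m = lam_model
    flat = FlatData(packed)
    b = np.zeros((flat.n_subjects, max_effect_dim(m.random_effects)))
    v1 = engine_neg2ll(flat, m.structural, m.random_effects, m.error, b)
    far = replace(m.structural, cl=25.0, mtt_tablet=1.8)
    engine_neg2ll(flat, far, m.random_effects, m.error, b)
    v2 = engine_neg2ll(flat, m.structural, m.random_effects, m.error, b)
    assert v1 == v2


def test_excluded_records_contribute_nothing(small_cohort, lam_model):
    """Trailing below-LLOQ observations are dropped from the likelihood."""
    from pedpk.cohort import simulate_observations
    spec = replace(lam_model, error=replace(lam_model.error, lloq=0.3,
                                            sigma_add=0.06))
    ds = preprocess_blq(simulate_observations(small_cohort, spec, seed=5))
    packed_all = pack_dataset(ds, include_excluded=True)
    packed_lik = pack_dataset(ds)
    n_all = sum(len(s.obs_y) for s in packed_all.subjects)
    n_lik = sum(len(s.obs_y) for s in packed_lik.subjects)
    n_excl = sum(s.n_excluded for s in packed_lik.subjects)
    assert n_excl > 0 and n_all == n_lik + n_excl


def test_blq_inflation_raises_likelihood_spread(packed, lam_model):
    """Imputed records carry a larger residual SD than ordinary ones."""
    m = lam_model
    sub = packed.subjects[0]
    mod = replace(sub)
    base, _ = marginal_neg2ll(PackedData([sub]), m.structural,
                              m.random_effects, m.error, hessian="gn")
    flagged = replace(sub, obs_blq=np.ones_like(sub.obs_blq))
    infl, _ = marginal_neg2ll(PackedData([flagged]), m.structural,
                              m.random_effects, m.error, hessian="gn")
    assert infl != pytest.approx(base, abs=1e-3)


def test_engine_predict_matches_reference_predictions(packed, lam_model):
    from pedpk.likelihood import _subject_pred, effect_layout
    m = lam_model
    flat = FlatData(packed)
    kmax = max_effect_dim(m.random_effects)
    rng = np.random.default_rng(4)
    b = np.zeros((flat.n_subjects, kmax))
    for i, sub in enumerate(packed.subjects):
        kinds, slots, sds = effect_layout(m.random_effects, sub.n_slots)
        b[i, :len(sds)] = rng.normal(0, 1, len(sds)) * sds
    got = engine_predict(flat, m.structural, m.random_effects, m.error, b)
    pos = 0
    for i, sub in enumerate(packed.subjects):
        kinds, slots, sds = effect_layout(m.random_effects, sub.n_slots)
        ref = _subject_pred(sub, m.structural, kinds, slots, b[i, :len(sds)])
        assert np.allclose(got[pos:pos + len(ref)], ref, rtol=1e-10)
        pos += len(ref)
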