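"""Synthetic cohort generation and trial simulation."""

from dataclasses import replace

import math

import numpy as np
import pytest

from pedpk.cohort import (CohortSpec, GroupStats, generate_cohort,
                          load_cohort_spec, scenario_suite,
                          simulate_observations)
from pedpk.modelspec import load_model


def test_bundled_specs_match_study_arms():
    lam = load_cohort_spec("study_lamivudine")
    aba = load_cohort_spec("study_abacavir")
    assert (lam.n_mdr, lam.n_control) == (27, 27)
    assert (aba.n_mdr, aba.n_control) == (25, 25)
    assert lam.dose_mg_per_kg == 4.0 and aba.dose_mg_per_kg == 8.0
    assert lam.weight_mdr.median == 13.4


def test_seed_reproducibility(lam_cohort_spec):
    a = generate_cohort(lam_cohort_spec, seed=42)
    b = generate_cohort(lam_cohort_spec, seed=42)
    for da, db in zip(a.designs, b.designs):
        assert np.array_equal(da.dose_times, db.dose_times)
        assert np.array_equal(da.sample_times, db.sample_times)
    assert a.covariates == b.covariates
    c = generate_cohort(lam_cohort_spec, seed=43)
    assert a.covariates != c.covariates


def test_seed_required(lam_cohort_spec):
    with pytest.raises(ValueError, match="seed"):
        generate_cohort(lam_cohort_spec)


def test_dose_amounts_exactly_weight_based(full_cohort):
    spec = full_cohort.spec
    for d in full_cohort.designs:
        wt = full_cohort.covariates[d.subject_id].weight
        per_kg = spec.qd_dose_mg_per_kg if d.qd else spec.dose_mg_per_kg
        assert np.allclose(d.dose_amounts, per_kg * wt)


def test_demographics_match_target_quartiles(lam_cohort_spec):
    """At large n the generated medians/IQRs approach the design values."""
    big = replace(lam_cohort_spec, n_mdr=10_000, n_control=0,
                  n_qd_control=0)
    coh = generate_cohort(big, seed=8)
    wts = np.array([c.weight for c in coh.covariates.values()])
    ages = np.array([c.postnatal_age / 12.0 for c in coh.covariates.values()])
    assert np.median(wts) == pytest.approx(13.4, rel=0.03)
    assert np.median(ages) == pytest.approx(4.2, rel=0.03)
    # a lognormal cannot reproduce an asymmetric IQR exactly; it matches
    # the median and the quartile RATIO, so compare against those values
    sigma = math.log(21.4 / 9.1) / (2 * 0.6745)
    assert np.percentile(wts, 25) == pytest.approx(
        13.4 * math.exp(-0.6745 * sigma), rel=0.03)
    assert np.percentile(wts, 75) == pytest.approx(
        13.4 * math.exp(0.6745 * sigma), rel=0.03)
    assert 9.1 < np.median(wts) < 21.4
    # rank coupling: heavier children are older (boundary clipping ties
    # keep the Pearson correlation a touch below 1)
    assert np.corrcoef(wts, ages)[0, 1] > 0.85
    # all postmenstrual ages positive
    assert all(c.pmage > 0 for c in coh.covariates.values())


def test_suspension_fraction_extremes(lam_cohort_spec):
    allsusp = replace(lam_cohort_spec, n_mdr=20, n_control=0,
                      n_qd_control=0,
                      suspension_fraction={"mdr": 1.0, "control": 0.0})
    coh = generate_cohort(allsusp, seed=2)
    assert all(c.formulation == "suspension"
               for c in coh.covariates.values())


def test_protocol_schedule_and_alternating_final_sample(full_cohort):
    bid = [d for d in full_cohort.designs if not d.qd]
    finals = set()
    for d in bid:
        rel = d.sample_times - d.dose_times[-1]
        assert set(np.round(rel, 6)) >= {-1.0, 0.0, 1.0, 3.0, 7.0}
        extra = set(np.round(rel, 6)) - {-1.0, 0.0, 1.0, 3.0, 7.0}
        assert extra <= {5.0, 10.0}
        finals |= extra
    assert finals == {5.0, 10.0}  # the final sample alternates
    qd = [d for d in full_cohort.designs if d.qd]
    assert len(qd) == 2
    for d in qd:
        rel = d.sample_times - d.dose_times[-1]
        assert list(np.round(rel, 6)) == [10.0, 11.0, 13.0, 15.0, 17.0]


def test_missed_dose_removes_evening_dose(lam_cohort_spec):
    spec = replace(lam_cohort_spec, n_mdr=40, n_control=0, n_qd_control=0,
                   missed_dose_fraction=1.0)
    coh = generate_cohort(spec, seed=6)
    for d in coh.designs:
        t_obs = d.dose_times[-1]
        assert t_obs - spec.interval not in d.dose_times


def test_simulation_matches_deterministic_prediction_when_quiet(
        small_cohort, lam_model):
    from pedpk.structural import conc_profile, individual_structural_params
    from pedpk.random_effects import ErrorModel
    quiet = replace(
        lam_model,
        random_effects=replace(lam_model.random_effects, omega_cl=0.0,
                               pi_ka=0.0, pi_mtt=0.0, pi_f=0.0),
        error=ErrorModel(sigma_prop=1e-12, sigma_add=2e-9, lloq=1e-8))
    ds = simulate_observations(small_cohort, quiet, seed=1)
    d0 = small_cohort.designs[0]
    cov = small_cohort.covariates[d0.subject_id]
    p = individual_structural_params(quiet.structural, cov)
    nd = len(d0.dose_times)
    expected = conc_profile(d0.sample_times, d0.dose_times, d0.dose_amounts,
                            np.ones(nd), np.full(nd, p.mtt_tablet),
                            np.full(nd, p.ka), p.cl, p.vc, p.q, p.vp, p.nn)
    got = ds.records[(ds.records["ID"] == d0.subject_id)
                     & (ds.records["EVID"] == 0)]["DV"].to_numpy()
    assert np.allclose(got, expected, rtol=1e-4)


def test_mean_concentration_converges_over_subjects(lam_cohort_spec,
                                                    lam_model):
    """Law of large numbers: mean log-trough stabilises as n grows."""
    means = []
    for n, seed in ((250, 1), (250, 2)):
        spec = replace(lam_cohort_spec, n_mdr=n, n_control=0,
                       n_qd_control=0, blq_censoring=False,
                       missed_dose_fraction=0.0)
        coh = generate_cohort(spec, seed=seed)
        ds = simulate_observations(coh, lam_model, seed=seed + 10)
        obs = ds.observations
        rel = obs["TIME"] - 120.0
        trough = obs[np.isclose(rel, 0.0)]["DV"]
        means.append(np.log(trough.clip(lower=1e-6)).mean())
    assert means[0] == pytest.approx(means[1], abs=0.2)


def test_scenario_suite_contract():
    sc = scenario_suite()
    assert set(sc) == {"lam_base", "aba_base", "lam_mdr_effect_1.2",
                       "aba_mdr_effect_1.25", "missed_dose", "qd_subset"}
    lam_coh, lam_spec = sc["lam_base"]
    assert lam_coh.n_subjects == 54
    n_samples = sum(len(d.sample_times) for d in lam_coh.designs)
    assert n_samples == 52 * 6 + 2 * 5  # 322, the study's sample count
    eff_coh, eff_spec = sc["lam_mdr_effect_1.2"]
    assert eff_spec.structural.theta_mdr == pytest.approx(0.2)
    assert eff_spec.structural.mdr_target == "cl"
    qd_coh, _ = sc["qd_subset"]
    assert all(d.qd for d in qd_coh.designs)
    # regenerating from the recorded seeds is bit-identical
    sc2 = scenario_suite()
    a = simulate_observations(lam_coh, lam_spec, seed=1)
    b = simulate_observations(sc2["lam_base"][0], sc2["lam_base"][1], seed=1)
    assert a.records.equals(b.records)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        CohortSpec(n_mdr=-1)
    with pytest.raises(ValueError):
        CohortSpec(weight_mdr=GroupStats(10.0, 12.0, 9.0))
    with pytest.raises(ValueError):
        CohortSpec(n_control=1, n_qd_control=2)
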