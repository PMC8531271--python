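"""Structural model: maturation, allometry, transit absorption, disposition.

The closed-form concentration is checked against an explicit-chain ODE
oracle (integer number of transit compartments solved compartment by
compartment with a stiff integrator) and against direct numerical
quadrature of the transit-input convolution.
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from pedpk.datasets import SubjectCovariates
from pedpk.structural import (DoseEvent, StructuralParams,
                              allometric_factor, conc_profile,
                              disposition_eigenvalues, gamma_exp_conv,
                              individual_structural_params,
                              maturation_fraction, predict_concentrations,
                              steady_state_history, transit_input_rate)

LAM = dict(cl=10.8, vc=26.5, q=2.25, vp=69.8, ka=1.07, mtt_tablet=0.643,
           nn=6.38, beta_susp=-0.463, gamma=3.32, pmage50=10.6)
ABA = dict(cl=16.3, vc=21.7, q=1.42, vp=12.0, ka=1.77, mtt_tablet=0.458,
           nn=3.70, beta_susp=-0.816, gamma=3.94, pmage50=11.9)


# -- maturation and allometry ----------------------------------------------

def test_maturation_half_at_pmage50():
    assert maturation_fraction(10.6, 10.6, 3.32) == pytest.approx(0.5)


def test_maturation_table_value():
    # 2-year-old (24 months postnatal + 9 gestational) on the lamivudine
    # curve is essentially mature
    assert maturation_fraction(33.0, 10.6, 3.32) == pytest.approx(0.9772,
                                                                  abs=5e-4)


def test_maturation_asymptote_and_monotonicity():
    assert maturation_fraction(1e6, 10.6, 3.32) == pytest.approx(1.0,
                                                                 abs=1e-6)
    ages = np.linspace(0.5, 120, 200)
    m = maturation_fraction(ages, 10.6, 3.32)
    assert np.all(np.diff(m) > 0) and np.all((m > 0) & (m < 1))


def test_maturation_domain_errors():
    with pytest.raises(ValueError):
        maturation_fraction(-1.0, 10.6, 3.32)
    with pytest.raises(ValueError):
        maturation_fraction(10.0, 10.6, 0.0)


@pytest.mark.parametrize("wt,ref,expo,expected", [
    (15.0, 15.0, 0.75, 1.0),
    (30.0, 15.0, 0.75, 2 ** 0.75),
    (7.5, 15.0, 1.0, 0.5),
])
def test_allometric_factor(wt, ref, expo, expected):
    assert allometric_factor(wt, ref, expo) == pytest.approx(expected)


def test_allometric_rejects_nonpositive_weight():
    with pytest.raises(ValueError):
        allometric_factor(0.0, 15.0, 0.75)


# -- covariate individualisation -------------------------------------------

def test_suspension_shortens_mtt_as_reported():
    lam = StructuralParams(**LAM)
    aba = StructuralParams(**ABA)
    cov_susp = SubjectCovariates(weight=15.0, postnatal_age=600.0,
                                 formulation="suspension")
    cov_tab = SubjectCovariates(weight=15.0, postnatal_age=600.0,
                                formulation="tablet")
    # lamivudine: 21 vs 39 minutes; abacavir: 5 vs 27 minutes
    assert round(individual_structural_params(lam, cov_susp).mtt_tablet
                 * 60) == 21
    assert round(individual_structural_params(lam, cov_tab).mtt_tablet
                 * 60) == 39
    assert round(individual_structural_params(aba, cov_susp).mtt_tablet
                 * 60) == 5
    assert round(individual_structural_params(aba, cov_tab).mtt_tablet
                 * 60) == 27


def test_reference_child_keeps_typical_values():
    lam = StructuralParams(**LAM)
    cov = SubjectCovariates(weight=15.0, postnatal_age=600.0,
                            formulation="tablet")
    ind = individual_structural_params(lam, cov)
    assert ind.cl == pytest.approx(10.8, rel=1e-3)  # maturation ~ 1
    assert ind.vc == pytest.approx(26.5)
    assert ind.q == pytest.approx(2.25, rel=1e-9)


def test_mdr_effect_applies_to_target_group_only():
    lam = StructuralParams(**LAM, theta_mdr=0.2, mdr_target="cl")
    base = SubjectCovariates(weight=15.0, postnatal_age=600.0,
                             formulation="tablet")
    mdr = SubjectCovariates(weight=15.0, postnatal_age=600.0,
                            formulation="tablet", mdr_tb=True)
    r = individual_structural_params(lam, mdr).cl \
        / individual_structural_params(lam, base).cl
    assert r == pytest.approx(1.2)


# -- transit input ----------------------------------------------------------

def test_transit_rate_zero_at_dose_time_and_before():
    dose = DoseEvent(0.0, 60.0)
    assert transit_input_rate(0.0, dose, 1.0, 0.643, 6.38) == 0.0
    assert transit_input_rate(-1.0, dose, 1.0, 0.643, 6.38) == 0.0


def test_transit_rate_integrates_to_dose():
    dose = DoseEvent(0.0, 60.0)
    total, _ = integrate.quad(
        lambda t: transit_input_rate(t, dose, 0.9, 0.643, 6.38), 0, 50)
    assert total == pytest.approx(0.9 * 60.0, rel=1e-8)


def test_transit_rate_peaks_at_mode_of_gamma_density():
    nn, mtt = 6.38, 0.643
    ktr = (nn + 1) / mtt
    t_peak = nn / ktr  # mode of the gamma(nn+1, ktr) density
    dose = DoseEvent(0.0, 60.0)
    ts = np.linspace(0.01, 3.0, 2000)
    rates = transit_input_rate(ts, dose, 1.0, mtt, nn)
    assert ts[np.argmax(rates)] == pytest.approx(t_peak, abs=2e-3)


# -- convolution kernel ------------------------------------------------------

@pytest.mark.parametrize("a,ktr,lam,tau", [
    (7.38, 11.5, 0.45, 3.0),     # typical absorption vs disposition
    (7.38, 11.5, 0.026, 24.0),   # slow terminal phase
    (4.7, 1.2, 1.77, 10.0),      # inflated transit time, ka faster (z<0)
    (2.0, 0.3, 2.0, 30.0),       # deep negative-z quadrature branch
    (1.0, 5.0, 5.0, 2.0),        # rate collision (z = 0)
])
def test_gamma_exp_conv_matches_quadrature(a, ktr, lam, tau):
    ref, _ = integrate.quad(
        lambda s: stats.gamma.pdf(s, a, scale=1.0 / ktr)
        * math.exp(-lam * (tau - s)), 0.0, tau, limit=300)
    got = gamma_exp_conv(a, ktr, lam, np.array([tau]))[0]
    assert got == pytest.approx(ref, rel=1e-7, abs=1e-250)


# -- concentration predictions ----------------------------------------------

def _ode_oracle(times, nn_int, mtt, ka, cl, vc, q, vp, dose):
    """Explicit transit chain (gamma shape nn+1) + depot + 2 compartments."""
    nchain = nn_int + 1
    ktr = (nn_int + 1) / mtt

    def rhs(t, y):
        dy = np.zeros(nchain + 3)
        dy[0] = -ktr * y[0]
        for i in range(1, nchain):
            dy[i] = ktr * (y[i - 1] - y[i])
        dy[nchain] = ktr * y[nchain - 1] - ka * y[nchain]
        dy[nchain + 1] = (ka * y[nchain]
                          - (cl / vc + q / vc) * y[nchain + 1]
                          + (q / vp) * y[nchain + 2])
        dy[nchain + 2] = (q / vc) * y[nchain + 1] - (q / vp) * y[nchain + 2]
        return dy

    y0 = np.zeros(nchain + 3)
    y0[0] = dose
    sol = integrate.solve_ivp(rhs, (0.0, times[-1]), y0, t_eval=times,
                              rtol=1e-10, atol=1e-13, method="LSODA")
    return sol.y[nchain + 1] / vc, sol.y


def test_profile_matches_explicit_chain_oracle():
    times = np.array([0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 12.0, 24.0])
    ode_c, _ = _ode_oracle(times, 6, 0.643, 1.07, 10.8, 26.5, 2.25, 69.8,
                           60.0)
    ana_c = conc_profile(times, [0.0], [60.0], [1.0], [0.643], [1.07],
                         10.8, 26.5, 2.25, 69.8, 6.0)
    assert np.max(np.abs(ana_c - ode_c) / ode_c) < 5e-3


def test_mass_balance_of_explicit_chain():
    times = np.linspace(0.0, 48.0, 4000)
    _, y = _ode_oracle(times, 6, 0.643, 1.07, 10.8, 26.5, 2.25, 69.8, 60.0)
    in_system = y.sum(axis=0)  # transit chain + depot + central + peripheral
    elim_integral = integrate.cumulative_trapezoid(
        10.8 / 26.5 * y[-2], times, initial=0.0)
    # amount in system + amount eliminated equals the dose throughout
    assert np.max(np.abs(in_system + elim_integral - 60.0)) < 60.0 * 1e-4


def test_zero_concentration_at_dose_time_and_linearity():
    p = StructuralParams(**LAM)
    doses = [DoseEvent(0.0, 60.0)]
    assert predict_concentrations(p, doses, [0.0])[0] == 0.0
    ts = [0.5, 1.0, 3.0, 7.0, 12.0]
    c1 = predict_concentrations(p, doses, ts)
    c2 = predict_concentrations(p, [DoseEvent(0.0, 120.0)], ts)
    assert np.max(np.abs(c2 - 2.0 * c1) / c1) < 1e-10


def test_dose_splitting_invariance():
    p = StructuralParams(**LAM)
    ts = [1.0, 3.0, 7.0]
    whole = predict_concentrations(p, [DoseEvent(0.0, 60.0)], ts)
    halves = predict_concentrations(p, [DoseEvent(0.0, 30.0),
                                        DoseEvent(0.0, 30.0)], ts)
    assert np.allclose(whole, halves, rtol=1e-12)


def test_terminal_slope_is_slow_eigenvalue():
    p = StructuralParams(**ABA)
    _, lam2 = disposition_eigenvalues(p)
    ts = np.array([60.0, 72.0])
    c = predict_concentrations(p, [DoseEvent(0.0, 120.0)], ts)
    slope = -(math.log(c[1]) - math.log(c[0])) / (ts[1] - ts[0])
    assert slope == pytest.approx(lam2, rel=1e-3)


def test_auc_equals_dose_over_clearance():
    p = StructuralParams(**LAM)
    f_dose = 1.0 * 60.0
    ts = np.linspace(0.0, 400.0, 8000)
    c = predict_concentrations(p, [DoseEvent(0.0, 60.0)], ts)
    auc = np.trapezoid(c, ts)
    assert auc == pytest.approx(f_dose / p.cl, rel=5e-3)


def test_steady_state_history_and_missed_dose():
    obs_dose = DoseEvent(120.0, 120.0)
    hist = steady_state_history(12.0, 10, obs_dose)
    assert [d.time for d in hist] == [120.0 - 12.0 * k
                                      for k in range(10, 0, -1)]
    p = StructuralParams(**ABA)

    def trough(doses):
        return predict_concentrations(p, doses, [120.0])[0]

    full = trough(hist)
    more = trough(steady_state_history(12.0, 12, obs_dose))
    assert abs(more - full) / full < 1e-3  # abacavir reaches steady state
    missed = [d for d in hist if d.time != 108.0]
    assert trough(missed) < 0.55 * full  # missed evening dose drops trough


def test_single_prior_dose_is_single_dose_profile():
    obs_dose = DoseEvent(24.0, 60.0)
    hist = steady_state_history(12.0, 1, obs_dose)
    assert len(hist) == 1 and hist[0].time == 12.0
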