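"""Shared fixtures: bundled model specs and small synthetic datasets.

Session-scoped where generation or fitting is expensive; all randomness is
seeded so the suite is fully reproducible.
"""

from dataclasses import replace

import pytest

from pedpk import (PopPKModel, generate_cohort, load_cohort_spec,
                   load_model, maturation_priors, simulate_observations)


@pytest.fixture(scope="session")
def lam_model():
    return load_model("lamivudine")


@pytest.fixture(scope="session")
def aba_model():
    return load_model("abacavir")


@pytest.fixture(scope="session")
def lam_cohort_spec():
    return load_cohort_spec("study_lamivudine")


@pytest.fixture(scope="session")
def small_cohort(lam_cohort_spec):
    """12 children (6 MDR-TB, 6 control), no once-daily subset."""
    spec = replace(lam_cohort_spec, n_mdr=6, n_control=6, n_qd_control=0,
                   missed_dose_fraction=0.0)
    return generate_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, lam_model):
    return simulate_observations(small_cohort, lam_model, seed=21)


@pytest.fixture(scope="session")
def full_cohort(lam_cohort_spec):
    """The full 54-child lamivudine design."""
    return generate_cohort(lam_cohort_spec, seed=101)



@pytest.fixture(scope="session")
def small_fit(small_dataset, lam_model):
    """One converged fit on the 12-child dataset, reused across tests."""
    model = PopPKModel(small_dataset, lam_model,
                       priors=maturation_priors(lam_model))
    return model.fit(method="foce")
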