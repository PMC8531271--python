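"""Dataset model: CSV round-trip, validation, occasions, below-LLOQ rules."""

import io

import numpy as np
import pandas as pd
import pytest

from pedpk.datasets import (AssaySpec, PKDataset, PKRecord,
                            SubjectCovariates, FormatError, ValidationError,
                            assign_occasions, preprocess_blq, read_dataset,
                            write_dataset)
from pedpk.datasets import validate

COV = {"A": SubjectCovariates(weight=15.0, postnatal_age=48.0)}


def _toy(records):
    return PKDataset.from_records(records, COV)


def toy_dataset():
    recs = [PKRecord("A", 0.0, "dose", amount=60.0)]
    recs += [PKRecord("A", t, "observation", concentration=c)
             for t, c in [(1.0, 1.2), (3.0, 0.9), (5.0, 0.6), (7.0, 0.4),
                          (12.0, 0.15)]]
    return _toy(recs)


def test_toy_round_trip_is_lossless():
    ds = toy_dataset()
    assert len(ds.subjects) == 1 and len(ds.records) == 6
    buf = io.StringIO()
    write_dataset(ds, buf)
    buf.seek(0)
    ds2 = read_dataset(buf, assay=ds.assay)
    pd.testing.assert_frame_equal(ds.records, ds2.records,
                                  check_dtype=False)
    assert ds2.covariates["A"] == ds.covariates["A"]


def test_simulated_dataset_round_trips(small_dataset, tmp_path):
    path = tmp_path / "cohort.csv"
    write_dataset(small_dataset, path)
    ds2 = read_dataset(path, assay=small_dataset.assay)
    pd.testing.assert_frame_equal(small_dataset.records, ds2.records,
                                  check_dtype=False)


def test_concentration_on_dose_row_rejected():
    df = toy_dataset().records.copy()
    df.loc[df["EVID"] == 1, "DV"] = 1.0
    with pytest.raises(ValidationError, match="row"):
        validate(PKDataset(df, COV))


def test_missing_column_is_format_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("ID,TIME,AMT\nA,0,60\n")
    with pytest.raises(FormatError, match="missing"):
        read_dataset(p)


def test_negative_time_names_row():
    df = toy_dataset().records.copy()
    df.loc[1, "TIME"] = -5.0
    with pytest.raises(ValidationError, match="TIME"):
        validate(PKDataset(df, COV))


def test_covariate_invariants():
    with pytest.raises(ValidationError):
        SubjectCovariates(weight=0.5, postnatal_age=12.0)
    cov = SubjectCovariates(weight=15.0, postnatal_age=24.0)
    assert cov.pmage == pytest.approx(33.0)
    assert SubjectCovariates(15.0, 24.0, formulation="crushed") \
        .dose_formulation == "tablet"


# -- occasions --------------------------------------------------------------

def occasion_dataset(times_pre, times_post, dose_time=120.0):
    recs = [PKRecord("A", dose_time - 12.0 * k, "dose", amount=60.0)
            for k in range(3, 0, -1)]
    recs.append(PKRecord("A", dose_time, "dose", amount=60.0))
    recs += [PKRecord("A", dose_time + t, "observation", concentration=0.1)
             for t in times_pre]
    recs += [PKRecord("A", dose_time + t, "observation", concentration=0.5)
             for t in times_post]
    return _toy(recs)


def test_predose_samples_are_occasion_one():
    ds = assign_occasions(occasion_dataset([-1.0, 0.0], [1.0, 3.0, 7.0,
                                                         10.0]))
    obs = ds.observations.sort_values("TIME")
    rel = obs["TIME"].to_numpy() - 120.0
    occ = obs["OCC"].to_numpy(dtype=float)
    assert list(occ[rel <= 0]) == [1, 1]
    assert list(occ[rel > 0]) == [2, 2, 2, 2]
    # the observed dose carries occasion 2, history doses occasion 1
    doses = ds.doses.sort_values("TIME")
    assert doses["OCC"].tolist() == [1, 1, 1, 2]


def test_post_dose_only_subject_single_occasion():
    ds = assign_occasions(occasion_dataset([], [10.0, 11.0, 13.0, 15.0,
                                               17.0]))
    assert set(ds.observations["OCC"]) == {2}
    assert set(ds.doses["OCC"]) == {2}


def test_occasions_invariant_to_record_order(small_dataset):
    ds1 = assign_occasions(small_dataset)
    shuffled = small_dataset.copy()
    shuffled.records = shuffled.records.sample(frac=1.0, random_state=3)
    ds2 = assign_occasions(shuffled)
    key = ["ID", "TIME", "EVID"]
    merged = ds1.records.merge(ds2.records[key + ["OCC"]], on=key,
                               suffixes=("", "_perm"))
    assert (merged["OCC"].astype(float)
            == merged["OCC_perm"].astype(float)).all()


# -- below-LLOQ handling ----------------------------------------------------

def blq_dataset(concs, blqs, assay=AssaySpec(lloq=0.024)):
    recs = [PKRecord("A", 0.0, "dose", amount=60.0)]
    recs += [PKRecord("A", 1.0 + i, "observation",
                      concentration=(np.nan if b else c), blq=int(b))
             for i, (c, b) in enumerate(zip(concs, blqs))]
    ds = PKDataset.from_records(recs, COV, assay=assay)
    return ds


def test_trailing_run_first_imputed_rest_excluded():
    ds = preprocess_blq(blq_dataset([0.50, None, None, None],
                                    [0, 1, 1, 1]))
    obs = ds.observations.sort_values("TIME")
    assert obs["DV"].tolist() == pytest.approx([0.50, 0.012, 0.012, 0.012])
    assert obs["BLQ"].tolist() == [0, 1, 2, 2]


def test_isolated_censored_sample_imputed_not_excluded():
    ds = preprocess_blq(blq_dataset([None, 0.5, 0.3], [1, 0, 0]))
    obs = ds.observations.sort_values("TIME")
    assert obs["BLQ"].tolist() == [1, 0, 0]
    assert obs["DV"].iloc[0] == pytest.approx(0.012)


def test_no_censoring_is_identity():
    ds = blq_dataset([0.5, 0.3, 0.2], [0, 0, 0])
    out = preprocess_blq(ds)
    pd.testing.assert_frame_equal(ds.records, out.records,
                                  check_dtype=False)


def test_counts_conserved_and_noncensored_untouched(small_cohort, lam_model):
    from pedpk.cohort import simulate_observations
    from dataclasses import replace
    # crank the LLOQ up so censoring actually occurs
    spec = replace(lam_model, error=replace(lam_model.error, lloq=0.2,
                                            sigma_add=0.04))
    ds = simulate_observations(small_cohort, spec, seed=5)
    n_censored = int((ds.observations["BLQ"] > 0).sum())
    assert n_censored > 0
    out = preprocess_blq(ds)
    n_imp = int((out.observations["BLQ"] == 1).sum())
    n_exc = int((out.observations["BLQ"] == 2).sum())
    assert n_imp + n_exc == n_censored
    untouched = ds.observations["BLQ"] == 0
    assert np.allclose(out.observations.loc[untouched.index[untouched], "DV"],
                       ds.observations.loc[untouched.index[untouched], "DV"])


def test_zero_lloq_rejected():
    with pytest.raises(ValidationError):
        AssaySpec(lloq=0.0)
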