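"""Longitudinal pharmacokinetic datasets in NONMEM-style long format.

A dataset is a long-format event table (dose and observation records) plus
one set of covariates per subject and an assay specification.  The CSV
dialect uses the conventional columns

    ID, TIME, AMT, DV, EVID, BLQ, OCC, WT, PNA, GA, FORM, MDRTB, ART, ROUTE, DRUG

with ``EVID`` 0 = observation, 1 = dose; ``AMT`` in mg (doses only); ``DV``
the measured concentration in mg/L (observations only); ``TIME`` in hours
from the first event of the subject record; ``WT`` in kg; ``PNA`` and ``GA``
postnatal and gestational age in months.

``BLQ`` holds the censoring state: 0 = quantifiable, 1 = below the lower
limit of quantification (after :func:`preprocess_blq`: imputed at LLOQ/2),
2 = trailing below-limit value excluded from the likelihood but retained
for diagnostics.  Raw input files use only 0/1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AssaySpec",
    "SubjectCovariates",
    "PKRecord",
    "PKDataset",
    "FormatError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "assign_occasions",
    "preprocess_blq",
]

REQUIRED_COLUMNS = [
    "ID", "TIME", "AMT", "DV", "EVID", "BLQ", "OCC",
    "WT", "PNA", "GA", "FORM", "MDRTB", "ART", "ROUTE", "DRUG",
]

FORMULATIONS = ("suspension", "tablet", "crushed")
DRUGS = ("lamivudine", "abacavir")
ART_REGIMENS = ("lopinavir_ritonavir", "efavirenz")
ROUTES = ("oral", "nasogastric")


class FormatError(ValueError):
    """The file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Record-level invariants are violated; the message names the rows."""


@dataclass(frozen=True)
class AssaySpec:
    """Bioanalytical assay description; only the LLOQ matters here."""

    lloq: float = 0.024  # mg/L

    def __post_init__(self):
        if not self.lloq > 0:
            raise ValidationError(f"lloq must be positive, got {self.lloq}")


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject covariates; ages in months, weight in kg."""

    weight: float
    postnatal_age: float
    gestational_age: float = 9.0
    formulation: str = "suspension"
    mdr_tb: bool = False
    art_regimen: str = "lopinavir_ritonavir"
    admin_route: str = "oral"

    def __post_init__(self):
        if not (1.0 < self.weight < 100.0):
            raise ValidationError(f"weight {self.weight} kg outside (1, 100)")
        if self.postnatal_age < 0:
            raise ValidationError("postnatal_age must be >= 0")
        if self.pmage <= 0:
            raise ValidationError("postmenstrual age must be positive")
        if self.formulation not in FORMULATIONS:
            raise ValidationError(f"unknown formulation {self.formulation!r}")
        if self.art_regimen not in ART_REGIMENS:
            raise ValidationError(f"unknown ART regimen {self.art_regimen!r}")
        if self.admin_route not in ROUTES:
            raise ValidationError(f"unknown route {self.admin_route!r}")

    @property
    def pmage(self) -> float:
        """Postmenstrual age in months (postnatal plus gestational)."""
        return self.postnatal_age + self.gestational_age

    @property
    def dose_formulation(self) -> str:
        """Formulation pooled for covariate modelling (crushed -> tablet)."""
        return "tablet" if self.formulation == "crushed" else self.formulation


@dataclass(frozen=True)
class PKRecord:
    """One event row; convenience for building small datasets by hand."""

    subject_id: str
    time: float
    event: str  # "dose" | "observation"
    amount: float = np.nan       # mg, doses only
    concentration: float = np.nan  # mg/L, observations only
    blq: int = 0
    occasion: int | None = None
    drug: str = "lamivudine"


@dataclass
class PKDataset:
    """Event table + per-subject covariates + assay specification."""

    records: pd.DataFrame
    covariates: dict[str, SubjectCovariates]
    assay: AssaySpec = field(default_factory=AssaySpec)
    blq_processed: bool = False

    def __post_init__(self):
        self.records = _canonicalize(self.records)

    # -- convenience views ------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.records["ID"]))

    @property
    def observations(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 1]

    @property
    def drug(self) -> str:
        return str(self.records["DRUG"].iloc[0])

    def copy(self) -> "PKDataset":
        return PKDataset(self.records.copy(), dict(self.covariates),
                         self.assay, self.blq_processed)

    @classmethod
    def from_records(cls, records: list[PKRecord],
                     covariates: dict[str, SubjectCovariates],
                     assay: AssaySpec | None = None) -> "PKDataset":
        rows = []
        for r in records:
            cov = covariates[r.subject_id]
            rows.append({
                "ID": r.subject_id, "TIME": r.time,
                "AMT": r.amount if r.event == "dose" else np.nan,
                "DV": r.concentration if r.event == "observation" else np.nan,
                "EVID": 1 if r.event == "dose" else 0,
                "BLQ": r.blq, "OCC": r.occasion,
                "WT": cov.weight, "PNA": cov.postnatal_age,
                "GA": cov.gestational_age, "FORM": cov.formulation,
                "MDRTB": int(cov.mdr_tb), "ART": cov.art_regimen,
                "ROUTE": cov.admin_route, "DRUG": r.drug,
            })
        df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
        ds = cls(df, covariates, assay or AssaySpec())
        validate(ds)
        return ds


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["ID"] = df["ID"].astype(str)
    for col in ("TIME", "AMT", "DV", "WT", "PNA", "GA"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["EVID"] = pd.to_numeric(df["EVID"], errors="coerce").astype("Int64")
    df["BLQ"] = pd.to_numeric(df["BLQ"], errors="coerce").fillna(0).astype("Int64")
    df["OCC"] = pd.to_numeric(df["OCC"], errors="coerce").astype("Int64")
    df["MDRTB"] = pd.to_numeric(df["MDRTB"], errors="coerce").fillna(0).astype("Int64")
    # stable sort: by subject (order of first appearance), time, obs-before-dose
    order = {sid: i for i, sid in enumerate(dict.fromkeys(df["ID"]))}
    df["_subj"] = df["ID"].map(order)
    df = df.sort_values(["_subj", "TIME", "EVID"], kind="stable")
    df = df.drop(columns="_subj").reset_index(drop=True)
    return df


def validate(dataset: PKDataset) -> None:
    """Check record-level invariants; raise ValidationError naming bad rows."""
    df = dataset.records
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    problems = []
    for i, row in df.iterrows():
        if pd.isna(row["TIME"]) or row["TIME"] < 0:
            problems.append(f"row {i}: TIME must be a non-negative number")
        if row["EVID"] not in (0, 1):
            problems.append(f"row {i}: EVID must be 0 or 1")
        elif row["EVID"] == 1:
            if not (row["AMT"] > 0):
                problems.append(f"row {i}: dose record needs AMT > 0")
            if not pd.isna(row["DV"]):
                problems.append(f"row {i}: dose record must not carry DV")
            if row["BLQ"] not in (0, pd.NA) and row["BLQ"] != 0:
                problems.append(f"row {i}: BLQ flag only allowed on observations")
        else:
            if not pd.isna(row["AMT"]):
                problems.append(f"row {i}: observation must not carry AMT")
            if pd.isna(row["DV"]) and row["BLQ"] == 0:
                problems.append(f"row {i}: observation needs DV or BLQ flag")
            if not pd.isna(row["DV"]) and row["DV"] < 0:
                problems.append(f"row {i}: negative concentration")
        if row["DRUG"] not in DRUGS:
            problems.append(f"row {i}: unknown drug {row['DRUG']!r}")
    for sid in dataset.subjects:
        if sid not in dataset.covariates:
            problems.append(f"subject {sid}: no covariates")
        sub = df[df["ID"] == sid]
        if not (sub["EVID"] == 1).any():
            problems.append(f"subject {sid}: no dose record")
    if problems:
        raise ValidationError("; ".join(problems))


def read_dataset(path, assay: AssaySpec | None = None) -> PKDataset:
    """Read a NONMEM-style CSV into a validated :class:`PKDataset`."""
    if isinstance(path, (str,)) or hasattr(path, "read"):
        try:
            df = pd.read_csv(path, dtype={"ID": str})
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise FormatError(f"cannot parse CSV: {exc}") from exc
    else:
        df = pd.read_csv(str(path), dtype={"ID": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    covariates: dict[str, SubjectCovariates] = {}
    for sid, sub in df.groupby("ID", sort=False):
        first = sub.iloc[0]
        covariates[str(sid)] = SubjectCovariates(
            weight=float(first["WT"]),
            postnatal_age=float(first["PNA"]),
            gestational_age=float(first["GA"]) if pd.notna(first["GA"]) else 9.0,
            formulation=str(first["FORM"]),
            mdr_tb=bool(int(first["MDRTB"])),
            art_regimen=str(first["ART"]),
            admin_route=str(first["ROUTE"]),
        )
    processed = bool((pd.to_numeric(df["BLQ"], errors="coerce") == 2).any())
    ds = PKDataset(df, covariates, assay or AssaySpec(), blq_processed=processed)
    validate(ds)
    return ds


def write_dataset(dataset: PKDataset, path) -> None:
    """Write the dataset back to the CSV dialect (lossless round-trip)."""
    df = dataset.records[REQUIRED_COLUMNS]
    if hasattr(path, "write"):
        df.to_csv(path, index=False)
    else:
        df.to_csv(str(path), index=False)


def to_csv_string(dataset: PKDataset) -> str:
    buf = io.StringIO()
    write_dataset(dataset, buf)
    return buf.getvalue()


def assign_occasions(dataset: PKDataset) -> PKDataset:
    """Label occasions: pre-dose samples are occasion 1, the observed-dose
    profile occasion 2.

    The observed dose is the last dose record of the subject.  Observations
    at or before that time (the two pre-dose troughs, including the one drawn
    immediately before dosing) form occasion 1; later observations occasion 2.
    Subjects with only post-dose samples get the single occasion 2.  Dose
    records are labelled with the occasion whose absorption they inform:
    the observed dose 2, earlier (steady-state history) doses 1 when the
    subject has pre-dose observations, else 2.
    """
    ds = dataset.copy()
    df = ds.records
    for sid in ds.subjects:
        mask = df["ID"] == sid
        sub = df[mask]
        dose_times = sub.loc[sub["EVID"] == 1, "TIME"]
        if dose_times.empty:
            raise ValidationError(f"subject {sid}: no dose record")
        t_obs_dose = dose_times.max()
        obs = sub["EVID"] == 0
        pre = sub.index[obs & (sub["TIME"] <= t_obs_dose)]
        post = sub.index[obs & (sub["TIME"] > t_obs_dose)]
        has_pre = len(pre) > 0
        df.loc[pre, "OCC"] = 1
        df.loc[post, "OCC"] = 2
        is_dose = sub["EVID"] == 1
        last = sub.index[is_dose & (sub["TIME"] == t_obs_dose)]
        earlier = sub.index[is_dose & (sub["TIME"] < t_obs_dose)]
        df.loc[last, "OCC"] = 2
        df.loc[earlier, "OCC"] = 1 if has_pre else 2
    return ds


def preprocess_blq(dataset: PKDataset) -> PKDataset:
    """Apply the M6 rule to raw censored observations.

    Every observation flagged below the LLOQ is imputed at LLOQ/2; within the
    trailing run of consecutive censored observations at the end of a
    subject's profile, only the first is imputed and the remainder are marked
    excluded (kept for diagnostics, dropped from the likelihood).
    """
    lloq = dataset.assay.lloq
    if not lloq > 0:
        raise ValidationError("LLOQ must be positive")
    ds = dataset.copy()
    df = ds.records
    for sid in ds.subjects:
        idx = df.index[(df["ID"] == sid) & (df["EVID"] == 0)]
        if len(idx) == 0:
            continue
        blq = df.loc[idx, "BLQ"].to_numpy(dtype=int) > 0
        if not blq.any():
            continue
        df.loc[idx[blq], "DV"] = lloq / 2.0
        df.loc[idx[blq], "BLQ"] = 1
        # trailing maximal run of censored observations: first imputed,
        # remainder excluded
        run_len = 0
        for flag in blq[::-1]:
            if flag:
                run_len += 1
            else:
                break
        if run_len >= 2:
            tail = idx[len(idx) - run_len + 1:]
            df.loc[tail, "BLQ"] = 2
    ds.blq_processed = True
    return ds
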