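"""Synthetic cohort generation and trial simulation.

Generates virtual cohorts with the design of the source study: two groups
(children on MDR-TB treatment and controls), weights and ages drawn from
lognormal distributions matched to the reported group medians and
interquartile ranges, twice-daily weight-based dosing with an observed dose
after a run of steady-state doses, sparse sampling at the protocol times
(-1, 0, 1, 3, 7 and alternating 5 or 10 h around the observed dose), an
optional once-daily-dosed subset sampled at 10-17 h after an unobserved
evening dose, below-LLOQ censoring and occasional missed evening doses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import AssaySpec, PKDataset, SubjectCovariates, REQUIRED_COLUMNS
from .modelspec import ModelSpec, load_model
from .random_effects import draw_random_effects, residual_sd
from .structural import conc_profile, individual_structural_params

__all__ = ["CohortSpec", "Cohort", "load_cohort_spec", "generate_cohort",
           "simulate_observations", "scenario_suite"]

# sampling schedule relative to the observed dose (h); the final sample
# alternates between +5 and +10 by subject index
PROTOCOL_TIMES = (-1.0, 0.0, 1.0, 3.0, 7.0)
ALT_FINAL = (5.0, 10.0)
QD_TIMES = (10.0, 11.0, 13.0, 15.0, 17.0)

# clipping bounds for covariate draws (kg, years): keep the lognormal
# tails inside the plausible paediatric range of the study (0 to <15 years)
WEIGHT_BOUNDS = (2.5, 70.0)
AGE_BOUNDS = (0.25, 14.9)


@dataclass(frozen=True)
class GroupStats:
    median: float
    q1: float
    q3: float

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        # quartile-matched lognormal SD: ln(q3/q1) spans 2 x 0.6745 sigma
        return math.log(self.q3 / self.q1) / (2.0 * 0.674489750196082)


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic trial arm (one drug)."""

    drug: str = "lamivudine"
    n_mdr: int = 27
    n_control: int = 27
    weight_mdr: GroupStats = GroupStats(13.4, 9.1, 21.4)
    weight_control: GroupStats = GroupStats(15.6, 11.2, 23.1)
    age_mdr: GroupStats = GroupStats(4.2, 1.6, 9.6)
    age_control: GroupStats = GroupStats(5.7, 1.6, 9.5)
    suspension_fraction: dict = field(
        default_factory=lambda: {"mdr": 0.67, "control": 0.37})
    nasogastric_fraction: dict = field(
        default_factory=lambda: {"mdr": 0.44, "control": 0.30})
    lpv_fraction: dict = field(
        default_factory=lambda: {"mdr": 0.59, "control": 0.59})
    dose_mg_per_kg: float = 4.0
    interval: float = 12.0
    qd_dose_mg_per_kg: float = 8.0
    n_qd_control: int = 2
    n_prior_doses: int = 10
    blq_censoring: bool = True
    missed_dose_fraction: float = 0.074
    lloq: float = 0.024
    seed: int | None = None

    def __post_init__(self):
        if self.n_mdr < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        for stats in (self.weight_mdr, self.weight_control,
                      self.age_mdr, self.age_control):
            if not stats.q1 <= stats.median <= stats.q3:
                raise ValueError("IQR bounds must bracket the median")
        for frac in (*self.suspension_fraction.values(),
                     self.missed_dose_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_qd_control > self.n_control:
            raise ValueError("more QD subjects requested than controls")


def load_cohort_spec(name_or_path: str | Path) -> CohortSpec:
    """Load a cohort spec from a bundled name or YAML path."""
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
    else:
        ref = resources.files("pedpk.models") / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(f"no bundled cohort spec {name_or_path!r}")
        text = ref.read_text()
    d = yaml.safe_load(text)
    return CohortSpec(
        drug=d["drug"],
        n_mdr=int(d["n_mdr"]), n_control=int(d["n_control"]),
        weight_mdr=GroupStats(**d["weight_kg"]["mdr"]),
        weight_control=GroupStats(**d["weight_kg"]["control"]),
        age_mdr=GroupStats(**d["age_years"]["mdr"]),
        age_control=GroupStats(**d["age_years"]["control"]),
        suspension_fraction=d["suspension_fraction"],
        nasogastric_fraction=d.get("nasogastric_fraction",
                                   {"mdr": 0.0, "control": 0.0}),
        lpv_fraction=d.get("lpv_fraction", {"mdr": 0.5, "control": 0.5}),
        dose_mg_per_kg=float(d["dose_mg_per_kg"]),
        interval=float(d["interval_h"]),
        qd_dose_mg_per_kg=float(d.get("qd_dose_mg_per_kg",
                                      2 * d["dose_mg_per_kg"])),
        n_qd_control=int(d.get("n_qd_control", 0)),
        n_prior_doses=int(d.get("n_prior_doses", 10)),
        blq_censoring=bool(d.get("blq_censoring", True)),
        missed_dose_fraction=float(d.get("missed_dose_fraction", 0.0)),
        lloq=float(d.get("lloq", 0.024)),
    )


@dataclass
class SubjectDesign:
    subject_id: str
    dose_times: np.ndarray    # absolute h, ascending
    dose_amounts: np.ndarray  # mg
    sample_times: np.ndarray  # absolute h
    qd: bool = False


@dataclass
class Cohort:
    """Covariates plus the event skeleton (doses, sampling times)."""

    spec: CohortSpec
    covariates: dict[str, SubjectCovariates]
    designs: list[SubjectDesign]

    @property
    def n_subjects(self) -> int:
        return len(self.designs)

    def covariate_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.designs:
            c = self.covariates[d.subject_id]
            rows.append({"ID": d.subject_id, "WT": c.weight,
                         "PNA": c.postnatal_age, "GA": c.gestational_age,
                         "FORM": c.formulation, "MDRTB": int(c.mdr_tb),
                         "ART": c.art_regimen, "ROUTE": c.admin_route,
                         "QD": d.qd})
        return pd.DataFrame(rows)


def _draw_truncated(rng, stats: GroupStats, n: int, bounds) -> np.ndarray:
    # clip rather than resample: clipping keeps the median and quartiles of
    # the matched lognormal exactly (the bounds lie outside the IQR) while
    # keeping every draw inside the plausible paediatric range
    draw = np.exp(rng.normal(stats.mu, stats.sigma, size=n))
    return np.clip(draw, bounds[0], bounds[1])


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Draw covariates and build the event skeleton for one virtual trial.

    Weight and age are drawn from median/IQR-matched lognormals, truncated
    to a plausible paediatric range and coupled by rank within each group so
    that heavier children are also older.
    """
    if seed is None:
        seed = spec.seed
    if seed is None:
        raise ValueError("a seed is required to generate a cohort")
    rng = np.random.default_rng(seed)
    covariates: dict[str, SubjectCovariates] = {}
    designs: list[SubjectDesign] = []
    groups = [("mdr", spec.n_mdr, spec.weight_mdr, spec.age_mdr),
              ("control", spec.n_control, spec.weight_control,
               spec.age_control)]
    idx = 0
    for gname, n, wstats, astats in groups:
        if n == 0:
            continue
        weights = _draw_truncated(rng, wstats, n, WEIGHT_BOUNDS)
        ages = _draw_truncated(rng, astats, n, AGE_BOUNDS)
        # rank coupling: assign weights so their order follows the age order
        weights = np.sort(weights)[np.argsort(np.argsort(ages))]
        susp = rng.random(n) < spec.suspension_fraction[gname]
        ngt = rng.random(n) < spec.nasogastric_fraction[gname]
        lpv = rng.random(n) < spec.lpv_fraction[gname]
        missed = rng.random(n) < spec.missed_dose_fraction
        qd_flags = np.zeros(n, dtype=bool)
        if gname == "control" and spec.n_qd_control:
            qd_flags[-spec.n_qd_control:] = True
        for j in range(n):
            sid = f"S{idx + 1:03d}"
            covariates[sid] = SubjectCovariates(
                weight=float(weights[j]),
                postnatal_age=float(ages[j]) * 12.0,
                formulation="suspension" if susp[j] else "tablet",
                mdr_tb=(gname == "mdr"),
                art_regimen=("lopinavir_ritonavir" if lpv[j] else "efavirenz"),
                admin_route="nasogastric" if ngt[j] else "oral",
            )
            if qd_flags[j]:
                interval = 24.0
                amt = spec.qd_dose_mg_per_kg * weights[j]
                t_last = spec.n_prior_doses * interval
                dose_t = np.arange(spec.n_prior_doses + 1) * interval
                samples = t_last + np.asarray(QD_TIMES)
            else:
                interval = spec.interval
                amt = spec.dose_mg_per_kg * weights[j]
                t_last = spec.n_prior_doses * interval
                dose_t = np.arange(spec.n_prior_doses + 1) * interval
                if missed[j]:
                    dose_t = dose_t[dose_t != t_last - interval]
                final = ALT_FINAL[idx % 2]
                samples = t_last + np.sort(np.asarray(
                    PROTOCOL_TIMES + (final,)))
            designs.append(SubjectDesign(
                subject_id=sid, dose_times=dose_t.astype(float),
                dose_amounts=np.full(len(dose_t), float(amt)),
                sample_times=samples.astype(float), qd=bool(qd_flags[j])))
            idx += 1
    return Cohort(spec=spec, covariates=covariates, designs=designs)


def simulate_observations(cohort: Cohort, model: ModelSpec,
                          seed: int) -> PKDataset:
    """Simulate one trial: random effects, predictions, residual error, BLQ.

    Pre-dose concentrations arise from the explicit steady-state dose
    history in each subject's design.  Simulated concentrations are
    truncated at zero and, when censoring is on, values below the LLOQ are
    flagged raw-BLQ with the measured value removed.
    """
    spec = cohort.spec
    rng = np.random.default_rng(seed)
    occ_counts = [2 if (d.sample_times <= d.dose_times[-1]).any() else 1
                  for d in cohort.designs]
    effects = draw_random_effects(model.random_effects, cohort.n_subjects,
                                  occ_counts,
                                  seed=int(rng.integers(2 ** 31 - 1)))
    rows = []
    for i, design in enumerate(cohort.designs):
        cov = cohort.covariates[design.subject_id]
        base = individual_structural_params(model.structural, cov)
        eff = effects[effects["subject"] == i].set_index("occasion")
        eta_cl = float(eff["eta_cl"].iloc[0])
        n_occ = occ_counts[i]
        t_obs_dose = design.dose_times[-1]
        nd = len(design.dose_times)
        # per-dose occasion: the observed dose belongs to the last occasion,
        # history doses to the first
        dose_occ = np.where(design.dose_times == t_obs_dose, n_occ, 1)
        kap = {occ: (float(eff.loc[occ, "kappa_ka"]),
                     float(eff.loc[occ, "kappa_mtt"]),
                     float(eff.loc[occ, "kappa_f"])) for occ in range(1, n_occ + 1)}
        mtt_d = np.array([base.mtt_tablet * math.exp(kap[o][1])
                          for o in dose_occ])
        ka_d = np.array([base.ka * math.exp(kap[o][0]) for o in dose_occ])
        f_d = np.array([base.f * math.exp(kap[o][2]) for o in dose_occ])
        conc = conc_profile(design.sample_times, design.dose_times,
                            design.dose_amounts, f_d, mtt_d, ka_d,
                            base.cl * math.exp(eta_cl), base.vc, base.q,
                            base.vp, base.nn)
        sd = residual_sd(model.error, conc)
        y = np.maximum(conc + rng.normal(0.0, 1.0, len(conc)) * sd, 0.0)
        for td, amt in zip(design.dose_times, design.dose_amounts):
            occ = n_occ if td == t_obs_dose else 1
            rows.append(_row(design.subject_id, cov, spec.drug, td,
                             evid=1, amt=amt, occ=occ))
        for t, val in zip(design.sample_times, y):
            occ = 1 if (n_occ == 2 and t <= t_obs_dose) else n_occ
            blq = int(spec.blq_censoring and val < model.error.lloq)
            rows.append(_row(design.subject_id, cov, spec.drug, t, evid=0,
                             dv=(np.nan if blq else val), blq=blq, occ=occ))
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    return PKDataset(df, dict(cohort.covariates),
                     AssaySpec(lloq=model.error.lloq))


def _row(sid, cov, drug, time, evid, amt=np.nan, dv=np.nan, blq=0, occ=None):
    return {"ID": sid, "TIME": time, "AMT": amt, "DV": dv, "EVID": evid,
            "BLQ": blq, "OCC": occ, "WT": cov.weight,
            "PNA": cov.postnatal_age, "GA": cov.gestational_age,
            "FORM": cov.formulation, "MDRTB": int(cov.mdr_tb),
            "ART": cov.art_regimen, "ROUTE": cov.admin_route, "DRUG": drug}


def scenario_suite() -> dict[str, tuple[Cohort, ModelSpec]]:
    """Standard named fixtures (cohort, model) with recorded seeds."""
    lam_spec = load_cohort_spec("study_lamivudine")
    aba_spec = load_cohort_spec("study_abacavir")
    lam = load_model("lamivudine")
    aba = load_model("abacavir")
    qd_spec = replace(lam_spec, n_mdr=0, n_control=2, n_qd_control=2,
                      missed_dose_fraction=0.0)
    missed_spec = replace(lam_spec, missed_dose_fraction=0.2)
    return {
        "lam_base": (generate_cohort(lam_spec, seed=101), lam),
        "aba_base": (generate_cohort(aba_spec, seed=102), aba),
        "lam_mdr_effect_1.2": (generate_cohort(lam_spec, seed=103),
                               lam.with_mdr_effect("cl", 0.2)),
        "aba_mdr_effect_1.25": (generate_cohort(aba_spec, seed=104),
                                aba.with_mdr_effect("cl", 0.25)),
        "missed_dose": (generate_cohort(missed_spec, seed=105), lam),
        "qd_subset": (generate_cohort(qd_spec, seed=106), lam),
    }
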