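"""Virtual two-group rat studies with the statistical structure of the analysis.

The generator emulates the source experiment's design: two oral arms (vehicle
control vs. herb-pretreated, 5 rats each) receiving S-1 at 5 mg/kg tegafur
with sampling at predose, 0.25, 0.5, 1, 1.5, 2, 3, 4, 8, 12 and 24 h, an
optional auxiliary IV 5-FU arm at 10 mg/kg, log-normal between-subject
variability, a combined additive + proportional residual error per analyte,
and censoring at the assay quantification limits (50 / 10 / 50 ng/mL for
tegafur / 5-FU / gimeracil).

Gimeracil is not part of the structural model; a one-compartment oral
(Bateman) generator produces gimeracil profiles calibrated to the study's
published summary so the noncompartmental pipeline can be exercised on all
three analytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import reference
from .dataset import ANALYTE_TO_DVID, COLUMNS, ROUTE_TO_CODE, StudyDataset
from .model import (
    MG_PER_L_TO_NG_PER_ML,
    PARAM_NAMES,
    Analyte,
    DoseEvent,
    Route,
    StructuralParams,
    simulate,
)

__all__ = [
    "ResidualErrorModel",
    "PopulationModel",
    "StudyDesign",
    "GimeracilParams",
    "draw_subject",
    "simulate_study",
    "simulate_gimeracil",
    "bateman_profile",
]

#: default proportional residual SD (fraction of the prediction)
DEFAULT_PROPORTIONAL_SD = 0.15
_LOGIT_CLIP = 1e-9


@dataclass(frozen=True)
class ResidualErrorModel:
    """Combined residual error: SD(pred) = sqrt(additive^2 + (proportional*pred)^2)."""

    additive: float
    proportional: float

    def __post_init__(self) -> None:
        if self.additive < 0 or self.proportional < 0:
            raise ValueError("residual SDs must be >= 0")
        if self.additive == 0 and self.proportional == 0:
            raise ValueError("additive and proportional SD cannot both be 0")

    def sd(self, pred: np.ndarray | float) -> np.ndarray | float:
        return np.sqrt(self.additive**2 + (self.proportional * np.asarray(pred)) ** 2)


def _default_residuals() -> dict[str, ResidualErrorModel]:
    # additive SD = LLOQ/2 per analyte; typical bioanalytical noise levels
    return {
        a: ResidualErrorModel(additive=lloq / 2.0, proportional=DEFAULT_PROPORTIONAL_SD)
        for a, lloq in reference.LLOQ.items()
    }


@dataclass
class PopulationModel:
    """Population distribution: typical values, pretreatment effects, BSV, error.

    ``omega2`` holds the between-subject variability per parameter; by
    default it is interpreted as the variance of the log-parameter, with
    ``bsv_is_sd=True`` switching to a standard-deviation reading.
    """

    typical: StructuralParams
    group_ratios: Mapping[str, float] = field(default_factory=dict)
    omega2: Mapping[str, float] = field(default_factory=dict)
    residual: Mapping[str, ResidualErrorModel] = field(default_factory=_default_residuals)
    bsv_is_sd: bool = False

    def __post_init__(self) -> None:
        for name, value in self.omega2.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown BSV parameter {name!r}")
            if value < 0:
                raise ValueError(f"omega2[{name!r}] must be >= 0")
        for name, value in self.group_ratios.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown group-effect parameter {name!r}")
            if value <= 0:
                raise ValueError(f"group ratio for {name!r} must be > 0")

    def variance(self, name: str) -> float:
        value = float(self.omega2.get(name, 0.0))
        return value**2 if self.bsv_is_sd else value

    def typical_for_group(self, group: int) -> StructuralParams:
        values = {}
        for name in PARAM_NAMES:
            value = getattr(self.typical, name)
            if group == 1:
                value *= self.group_ratios.get(name, 1.0)
            values[name] = value
        return StructuralParams(**values)

    @classmethod
    def from_reference(cls, **overrides) -> "PopulationModel":
        """The published rat S-1 population model as generator defaults."""
        kwargs = dict(
            typical=reference.CONTROL_PARAMS,
            group_ratios=dict(reference.GROUP_RATIOS),
            omega2=dict(reference.BSV_OMEGA2),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class StudyDesign:
    """Sampling design of a virtual study (times in h, doses in mg/kg)."""

    n_per_group: int = 5
    dose: float = reference.TEGAFUR_DOSE
    sampling_times: tuple = reference.SAMPLING_TIMES
    lloq: Mapping[str, float] = field(default_factory=lambda: dict(reference.LLOQ))
    seed: int = 0
    n_iv: int = 0
    iv_dose: float = reference.IV_5FU_DOSE
    iv_sampling_times: tuple = reference.IV_SAMPLING_TIMES

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for times in (self.sampling_times, self.iv_sampling_times):
            t = np.asarray(times, dtype=float)
            if t.size == 0:
                raise ValueError("design must have at least one sampling time")
            if np.any(np.diff(t) <= 0) or np.any(t <= 0):
                raise ValueError("sampling times must be positive and strictly increasing")


def draw_subject(
    pop: PopulationModel, group: int, rng: np.random.Generator
) -> StructuralParams:
    """Draw one subject's parameters.

    Each parameter is typical x group ratio x exp(eta) with
    eta ~ N(0, omega^2), independent across parameters; ``f_met`` varies on
    the logit scale so draws stay inside (0, 1).
    """
    typical = pop.typical_for_group(group)
    values = {}
    for name in PARAM_NAMES:
        eta = rng.normal(0.0, np.sqrt(pop.variance(name)))
        base = getattr(typical, name)
        if name == "f_met":
            base = np.clip(base, _LOGIT_CLIP, 1.0 - _LOGIT_CLIP)
            values[name] = float(expit(logit(base) + eta))
        else:
            values[name] = float(base * np.exp(eta))
    return StructuralParams(**values)


def _observation_rows(
    subject: int,
    group: int,
    analyte: Analyte,
    times: np.ndarray,
    true_conc: np.ndarray,
    error: ResidualErrorModel,
    lloq: float,
    rng: np.random.Generator,
    predose: bool = True,
) -> list[dict]:
    noisy = true_conc + error.sd(true_conc) * rng.standard_normal(times.size)
    noisy = np.maximum(noisy, 0.0)
    rows = []
    if predose:
        rows.append(
            dict(ID=subject, TIME=0.0, EVID=0, AMT=np.nan, ROUTE="",
                 DVID=ANALYTE_TO_DVID[analyte], DV=0.0, BLQ=1, GROUP=group)
        )
    for t, dv in zip(times, noisy):
        rows.append(
            dict(ID=subject, TIME=float(t), EVID=0, AMT=np.nan, ROUTE="",
                 DVID=ANALYTE_TO_DVID[analyte], DV=float(dv),
                 BLQ=int(dv < lloq), GROUP=group)
        )
    return rows


def _dose_row(subject: int, group: int, amount: float, route: Route) -> dict:
    return dict(ID=subject, TIME=0.0, EVID=1, AMT=float(amount),
                ROUTE=ROUTE_TO_CODE[route], DVID=pd.NA, DV=np.nan, BLQ=0, GROUP=group)


def simulate_study(
    pop: PopulationModel,
    design: StudyDesign,
    include_gimeracil: bool = False,
    gimeracil_params: "GimeracilParams | None" = None,
) -> StudyDataset:
    """Simulate a complete virtual study; deterministic given (pop, design, seed).

    Subjects 1..n are controls, n+1..2n pretreated; an optional IV 5-FU arm
    (untreated animals, 5-FU observations only) follows with ids 2n+1 onward.
    """
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.sampling_times, dtype=float)
    rows: list[dict] = []
    subject = 0
    true_params: dict[int, StructuralParams] = {}
    for group in (0, 1):
        for _ in range(design.n_per_group):
            subject += 1
            params = draw_subject(pop, group, rng)
            true_params[subject] = params
            dose = DoseEvent(time=0.0, amount=design.dose, route=Route.ORAL_TEGAFUR)
            profile = simulate(params, [dose], times)
            rows.append(_dose_row(subject, group, design.dose, Route.ORAL_TEGAFUR))
            for analyte in (Analyte.TEGAFUR, Analyte.FU):
                rows.extend(
                    _observation_rows(
                        subject, group, analyte, times,
                        profile.concentration(analyte),
                        pop.residual[analyte.value],
                        design.lloq[analyte.value], rng,
                    )
                )
    iv_times = np.asarray(design.iv_sampling_times, dtype=float)
    for _ in range(design.n_iv):
        subject += 1
        params = draw_subject(pop, 0, rng)
        true_params[subject] = params
        dose = DoseEvent(time=0.0, amount=design.iv_dose, route=Route.IV_5FU)
        profile = simulate(params, [dose], iv_times)
        rows.append(_dose_row(subject, 0, design.iv_dose, Route.IV_5FU))
        rows.extend(
            _observation_rows(
                subject, 0, Analyte.FU, iv_times, profile.fu,
                pop.residual[Analyte.FU.value], design.lloq[Analyte.FU.value], rng,
            )
        )
    table = pd.DataFrame.from_records(rows, columns=list(COLUMNS))
    ds = StudyDataset(table, meta={"seed": design.seed, "true_params": true_params})
    if include_gimeracil:
        gim = simulate_gimeracil(design, params=gimeracil_params, rng=rng)
        ds = StudyDataset(
            pd.concat([ds.table, gim.table], ignore_index=True), ds.meta
        )
    return ds


# -- gimeracil (one-compartment oral, outside the structural model) ----------


@dataclass(frozen=True)
class GimeracilParams:
    """Apparent one-compartment oral parameters for gimeracil.

    Defaults are calibrated so the noise-free control profile reproduces the
    study's published control summary (Cmax ~348 ng/mL, terminal half-life
    ~0.7 h, AUCinf ~516 ng.h/mL at 1.45 mg/kg), and the pretreated arm's
    reduced absorption is emulated by a lower apparent bioavailability
    (f_ratio) and absorption rate (ka_ratio).
    """

    ka: float = 5.3  # 1/h
    cl: float = 2.81  # L/h/kg
    v: float = 2.84  # L/kg
    f_ratio: float = 0.47
    ka_ratio: float = 0.611
    omega2: float = 0.03  # log-variance shared by ka, cl, v

    @property
    def ke(self) -> float:
        return self.cl / self.v


def bateman_profile(
    times: np.ndarray, dose: float, ka: float, cl: float, v: float, f: float = 1.0
) -> np.ndarray:
    """One-compartment first-order absorption profile in ng/mL."""
    t = np.asarray(times, dtype=float)
    ke = cl / v
    if abs(ka - ke) < 1e-10:
        amt = f * dose * ka * t * np.exp(-ka * t)
    else:
        amt = f * dose * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    return np.maximum(amt, 0.0) / v * MG_PER_L_TO_NG_PER_ML


def simulate_gimeracil(
    design: StudyDesign,
    params: GimeracilParams | None = None,
    rng: np.random.Generator | None = None,
    dose: float = reference.GIMERACIL_DOSE,
    residual: ResidualErrorModel | None = None,
) -> StudyDataset:
    """Gimeracil observation records for both oral arms of a study.

    Subject ids match :func:`simulate_study` (1..n control, n+1..2n
    pretreated); only observation rows are produced, since gimeracil is
    co-administered within the S-1 dose already on file.
    """
    params = params or GimeracilParams()
    rng = rng if rng is not None else np.random.default_rng(design.seed + 1)
    residual = residual or _default_residuals()[Analyte.GIMERACIL.value]
    times = np.asarray(design.sampling_times, dtype=float)
    rows: list[dict] = []
    subject = 0
    for group in (0, 1):
        ka = params.ka * (params.ka_ratio if group == 1 else 1.0)
        f = params.f_ratio if group == 1 else 1.0
        for _ in range(design.n_per_group):
            subject += 1
            sd = np.sqrt(params.omega2)
            ka_i = ka * np.exp(rng.normal(0.0, sd))
            cl_i = params.cl * np.exp(rng.normal(0.0, sd))
            v_i = params.v * np.exp(rng.normal(0.0, sd))
            conc = bateman_profile(times, dose, ka_i, cl_i, v_i, f=f)
            rows.extend(
                _observation_rows(
                    subject, group, Analyte.GIMERACIL, times, conc,
                    residual, design.lloq[Analyte.GIMERACIL.value], rng,
                    predose=False,
                )
            )
    table = pd.DataFrame.from_records(rows, columns=list(COLUMNS))
    return StudyDataset(table, meta={"seed": design.seed})
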