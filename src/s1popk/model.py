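"""Structural parent-metabolite model for oral S-1 in the rat.

Tegafur is absorbed from the gut by a first-order process (``ka``) and, in
parallel, converted presystemically toward the 5-FU precursor
(5'-hydroxytegafur) with rate ``ka_met``.  Systemically, tegafur distributes
over a central and a peripheral compartment and is cleared by ``cl_teg``; a
fraction ``f_met`` of that clearance feeds the precursor pool, which turns
into 5-FU with rate ``k_conv``.  5-FU itself follows two-compartment
disposition with clearance ``cl_5fu``.  All six states are linear and
time-invariant, so profiles are propagated exactly with an eigendecomposition
of the rate matrix (matrix exponential as fallback for defective systems).

Internal units are mg/kg for amounts, L/kg for volumes and h for time;
concentrations cross the API boundary in ng/mL (1 mg/L = 1000 ng/mL).
All clearances and volumes are apparent (per bioavailable fraction F); no
molecular-weight correction is applied between tegafur and 5-FU amounts.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Analyte",
    "Route",
    "StructuralParams",
    "DoseEvent",
    "SimProfile",
    "simulate",
    "analytic_auc",
    "terminal_slope",
    "mass_balance_error",
    "total_5fu_formed",
    "MG_PER_L_TO_NG_PER_ML",
]

#: unit conversion at the I/O boundary: mg/kg divided by L/kg is mg/L = 1000 ng/mL
MG_PER_L_TO_NG_PER_ML = 1000.0

N_STATES = 6
IDX_GUT, IDX_TEG1, IDX_TEG2, IDX_PRE, IDX_FU1, IDX_FU2 = range(N_STATES)


class Analyte(str, enum.Enum):
    """Analytes observable in plasma."""

    TEGAFUR = "tegafur"
    FU = "5fu"
    GIMERACIL = "gimeracil"


class Route(str, enum.Enum):
    """Supported administration routes."""

    ORAL_TEGAFUR = "oral-tegafur"
    IV_5FU = "iv-5fu"


PARAM_NAMES = (
    "ka",
    "ka_met",
    "k_conv",
    "cl_teg",
    "cld_teg",
    "f_met",
    "cl_5fu",
    "cld_5fu",
    "v1_teg",
    "v2_teg",
    "v1_5fu",
    "v2_5fu",
)


@dataclass(frozen=True)
class StructuralParams:
    """Apparent (per-F) parameters of the six-state structural model.

    Rates in 1/h, clearances in L/h/kg, volumes in L/kg; ``f_met`` is the
    dimensionless fraction of central tegafur clearance routed to the 5-FU
    precursor.
    """

    ka: float
    ka_met: float
    k_conv: float
    cl_teg: float
    cld_teg: float
    f_met: float
    cl_5fu: float
    cld_5fu: float
    v1_teg: float
    v2_teg: float
    v1_5fu: float
    v2_5fu: float

    #: parameters allowed to be exactly zero (no gut-route formation /
    #: one-compartment disposition limits); all others are strictly positive
    _NONNEGATIVE = frozenset({"ka_met", "cld_teg", "cld_5fu"})

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
            if name == "f_met":
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"f_met must lie in [0, 1], got {value!r}")
            elif name in self._NONNEGATIVE:
                if value < 0.0:
                    raise ValueError(f"parameter {name!r} must be >= 0, got {value!r}")
            elif value <= 0.0:
                raise ValueError(f"parameter {name!r} must be positive, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "StructuralParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def replace(self, **kwargs: float) -> "StructuralParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class DoseEvent:
    """A dosing event: oral tegafur enters the gut, IV 5-FU the 5-FU central state."""

    time: float
    amount: float
    route: Route = Route.ORAL_TEGAFUR

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount!r}")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time!r}")
        object.__setattr__(self, "route", Route(self.route))


@dataclass(frozen=True)
class SimProfile:
    """Concentration-time profiles (ng/mL) for tegafur and 5-FU on a common grid."""

    times: np.ndarray
    tegafur: np.ndarray
    fu: np.ndarray

    def concentration(self, analyte: Analyte | str) -> np.ndarray:
        analyte = Analyte(analyte)
        if analyte is Analyte.TEGAFUR:
            return self.tegafur
        if analyte is Analyte.FU:
            return self.fu
        raise KeyError(f"analyte {analyte} not simulated by the structural model")


def rate_matrix(params: StructuralParams | np.ndarray) -> np.ndarray:
    """Rate matrix A of the six-state system, d(state)/dt = A @ state."""
    if isinstance(params, StructuralParams):
        p = params.as_array()
    else:
        p = np.asarray(params, dtype=float)
    ka, ka_met, k_conv, cl, cld, f_met, cl5, cld5, v1, v2, v15, v25 = p
    A = np.zeros((N_STATES, N_STATES))
    A[IDX_GUT, IDX_GUT] = -(ka + ka_met)
    A[IDX_TEG1, IDX_GUT] = ka
    A[IDX_TEG1, IDX_TEG1] = -(cl + cld) / v1
    A[IDX_TEG1, IDX_TEG2] = cld / v2
    A[IDX_TEG2, IDX_TEG1] = cld / v1
    A[IDX_TEG2, IDX_TEG2] = -cld / v2
    A[IDX_PRE, IDX_GUT] = ka_met
    A[IDX_PRE, IDX_TEG1] = cl * f_met / v1
    A[IDX_PRE, IDX_PRE] = -k_conv
    A[IDX_FU1, IDX_PRE] = k_conv
    A[IDX_FU1, IDX_FU1] = -(cl5 + cld5) / v15
    A[IDX_FU1, IDX_FU2] = cld5 / v25
    A[IDX_FU2, IDX_FU1] = cld5 / v15
    A[IDX_FU2, IDX_FU2] = -cld5 / v25
    return A


def _initial_state(dose: DoseEvent) -> np.ndarray:
    x0 = np.zeros(N_STATES)
    if dose.route is Route.ORAL_TEGAFUR:
        x0[IDX_GUT] = dose.amount
    else:
        x0[IDX_FU1] = dose.amount
    return x0


def _propagate(A: np.ndarray, x0: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """States at elapsed times ``dt`` (>= 0) from initial state ``x0``.

    Eigendecomposition path; falls back to stepwise matrix exponentials when
    the eigenvector basis is ill-conditioned (defective/near-defective A).
    Returns an array of shape (len(dt), n_states).
    """
    w, V = np.linalg.eig(A)
    ok = np.isfinite(V).all()
    if ok:
        try:
            c = np.linalg.solve(V, x0.astype(complex))
            cond_ok = np.linalg.cond(V) < 1e10
        except np.linalg.LinAlgError:
            cond_ok = False
        ok = cond_ok
    if ok:
        phases = np.exp(np.multiply.outer(dt, w))  # (nt, n)
        X = (phases * c) @ V.T
        return np.maximum(X.real, 0.0)
    # fallback: exact stepping through sorted elapsed times
    order = np.argsort(dt)
    X = np.empty((dt.size, x0.size))
    x = x0.copy()
    t_prev = 0.0
    for i in order:
        step = dt[i] - t_prev
        if step > 0:
            x = expm(A * step) @ x
            t_prev = dt[i]
        X[i] = x
    return np.maximum(X, 0.0)


def states(
    params: StructuralParams,
    doses: Iterable[DoseEvent],
    times: Sequence[float],
) -> np.ndarray:
    """Compartment amounts (mg/kg), shape (len(times), 6), by superposition over doses."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    A = rate_matrix(params)
    X = np.zeros((t.size, N_STATES))
    for dose in doses:
        if dose.amount == 0:
            continue
        after = t >= dose.time
        if not np.any(after):
            continue
        X[after] += _propagate(A, _initial_state(dose), t[after] - dose.time)
    return X


def simulate(
    params: StructuralParams,
    doses: Iterable[DoseEvent],
    times: Sequence[float],
) -> SimProfile:
    """Simulate plasma concentration-time profiles (ng/mL) for both analytes.

    The system is linear, so multiple doses superpose exactly.  Times before
    the first dose yield zero concentrations.
    """
    doses = list(doses)
    X = states(params, doses, times)
    t = np.asarray(times, dtype=float)
    c_teg = X[:, IDX_TEG1] / params.v1_teg * MG_PER_L_TO_NG_PER_ML
    c_fu = X[:, IDX_FU1] / params.v1_5fu * MG_PER_L_TO_NG_PER_ML
    return SimProfile(times=t, tegafur=c_teg, fu=c_fu)


def analytic_auc(params: StructuralParams, dose: float) -> tuple[float, float]:
    """Closed-form AUC(0-inf) in ng.h/mL for a single oral dose (mg/kg).

    For a linear system AUC = (amount reaching the analyte's central
    compartment) / clearance.  A fraction ka/(ka+ka_met) of the dose is
    absorbed as tegafur; 5-FU receives the gut-route fraction
    ka_met/(ka+ka_met) plus f_met of the absorbed tegafur.
    """
    k_exit = params.ka + params.ka_met
    if k_exit <= 0:
        raise ValueError("degenerate input: ka + ka_met must be > 0")
    frac_teg = params.ka / k_exit
    frac_fu = params.ka_met / k_exit + frac_teg * params.f_met
    auc_teg = frac_teg * dose / params.cl_teg * MG_PER_L_TO_NG_PER_ML
    auc_fu = frac_fu * dose / params.cl_5fu * MG_PER_L_TO_NG_PER_ML
    return auc_teg, auc_fu


def _two_compartment_eigenvalues(
    cl: float, cld: float, v1: float, v2: float
) -> np.ndarray:
    """Decay rates (positive, 1/h) of a two-compartment disposition block.

    In the one-compartment limit (cld -> 0) the peripheral compartment
    decouples; its zero eigenvalue carries no residue and is dropped.
    """
    a = np.array([[-(cl + cld) / v1, cld / v2], [cld / v1, -cld / v2]])
    lam = -np.linalg.eigvals(a).real
    return lam[lam > 1e-12]


def terminal_slope(
    params: StructuralParams,
    analyte: Analyte | str,
    route: Route | str = Route.ORAL_TEGAFUR,
) -> float:
    """Terminal log-linear decline rate (1/h) of an analyte's plasma profile.

    The terminal slope is the smallest decay rate among the eigenvalues of the
    subsystem feeding the analyte.  After an oral dose this includes the gut
    exit rate ka+ka_met, so when absorption is the slowest process the
    observed terminal phase reflects input, not elimination (flip-flop
    kinetics); tegafur and 5-FU then share one terminal slope.
    """
    analyte = Analyte(analyte)
    route = Route(route)
    rates: list[float] = []
    if route is Route.ORAL_TEGAFUR:
        rates.append(params.ka + params.ka_met)
        rates.extend(
            _two_compartment_eigenvalues(
                params.cl_teg, params.cld_teg, params.v1_teg, params.v2_teg
            )
        )
        if analyte is Analyte.FU:
            rates.append(params.k_conv)
    elif analyte is Analyte.TEGAFUR:
        raise ValueError("tegafur is not dosed intravenously in this model")
    if analyte is Analyte.FU:
        rates.extend(
            _two_compartment_eigenvalues(
                params.cl_5fu, params.cld_5fu, params.v1_5fu, params.v2_5fu
            )
        )
    elif analyte is not Analyte.TEGAFUR:
        raise ValueError(f"analyte {analyte} is not part of the structural model")
    return float(min(rates))


def total_5fu_formed(params: StructuralParams, dose: float) -> float:
    """Total amount of 5-FU (mg/kg) ever formed from a single oral dose.

    The gut route contributes ka_met/(ka+ka_met) of the dose, and f_met of
    the absorbed fraction is routed through central tegafur clearance.
    """
    k_exit = params.ka + params.ka_met
    if k_exit <= 0:
        raise ValueError("degenerate input: ka + ka_met must be > 0")
    return dose * (params.ka_met + params.ka * params.f_met) / k_exit


def mass_balance_error(
    params: StructuralParams,
    doses: Iterable[DoseEvent],
    times: Sequence[float],
) -> float:
    """Maximum absolute mass-balance violation as a fraction of the total dose.

    Augments the system with cumulative-elimination states (tegafur cleared
    away from the 5-FU path, and 5-FU eliminated) so that states plus
    cumulative losses must equal the administered amount at every time point.
    """
    doses = list(doses)
    total_dose = sum(d.amount for d in doses)
    if total_dose == 0:
        return 0.0
    A = rate_matrix(params)
    A_aug = np.zeros((N_STATES + 2, N_STATES + 2))
    A_aug[:N_STATES, :N_STATES] = A
    A_aug[N_STATES, IDX_TEG1] = params.cl_teg * (1.0 - params.f_met) / params.v1_teg
    A_aug[N_STATES + 1, IDX_FU1] = params.cl_5fu / params.v1_5fu
    t = np.asarray(times, dtype=float)
    totals = np.zeros(t.size)
    dosed = np.zeros(t.size)
    for dose in doses:
        if dose.amount == 0:
            continue
        x0 = np.zeros(N_STATES + 2)
        x0[:N_STATES] = _initial_state(dose)
        after = t >= dose.time
        if not np.any(after):
            continue
        X = _propagate(A_aug, x0, t[after] - dose.time)
        totals[after] += X.sum(axis=1)
        dosed[after] += dose.amount
    return float(np.max(np.abs(totals - dosed)) / total_dose)
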