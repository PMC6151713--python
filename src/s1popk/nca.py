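"""Noncompartmental analysis: terminal slope, AUC, exposure metrics, group tests.

The terminal rate constant lambda_z is found by log-linear least squares on
the contiguous terminal subset of quantifiable post-Tmax observations (Cmax
itself excluded) that maximizes the adjusted R-squared, ties broken toward
using more points.  AUC(0-tlast) uses the linear trapezoidal rule;
AUC(0-inf) adds the observed-Clast tail Clast/lambda_z.  Apparent clearance
CL/F = dose / AUCinf (reported in mL/min/kg) and terminal volume
Vz/F = CL/F / lambda_z.

BLQ observations after the first quantifiable point are excluded (not
zeroed); a leading predose BLQ contributes a zero at t=0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import DVID_TO_ANALYTE, StudyDataset
from .model import Analyte

__all__ = [
    "PKProfile",
    "NCAResult",
    "LambdaZFit",
    "select_lambda_z",
    "compute_nca",
    "nca_dataset",
    "compare_groups",
    "summarize_groups",
]

#: adjusted-R^2 differences below this are ties (resolved toward more points)
_R2_TIE_TOL = 1e-9


@dataclass(frozen=True)
class PKProfile:
    """A single subject/analyte concentration-time course (ng/mL vs h)."""

    subject: int
    analyte: Analyte
    dose: float
    times: np.ndarray
    concentrations: np.ndarray
    blq: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        q = np.asarray(self.blq, dtype=bool)
        if not (t.size == c.size == q.size):
            raise ValueError("times, concentrations and blq must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "blq", q)

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, c) used for AUC: quantifiable points, plus 0 at t=0 for a leading BLQ."""
        keep = ~self.blq
        t, c = self.times[keep], self.concentrations[keep]
        if t.size and t[0] > 0 and self.blq.size and self.blq[0] and self.times[0] == 0:
            t = np.insert(t, 0, 0.0)
            c = np.insert(c, 0, 0.0)
        return t, c


@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float
    n_points: int
    adj_r_squared: float
    intercept: float  # ln-concentration at t=0 of the regression line
    estimable: bool

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.lambda_z if self.estimable else math.nan


_NOT_ESTIMABLE = LambdaZFit(math.nan, 0, math.nan, math.nan, False)


def _loglinear_fit(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope/intercept/adjusted-R^2 of log-concentration vs time."""
    n = t.size
    slope, intercept = np.polyfit(t, logc, 1)
    resid = logc - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    if ss_tot == 0.0:
        return slope, intercept, -math.inf
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, adj


def select_lambda_z(profile: PKProfile, min_points: int = 3) -> LambdaZFit:
    """Best contiguous terminal log-linear fit; not-estimable is a flagged result."""
    t, c = profile.quantifiable()
    positive = c > 0
    t, c = t[positive], c[positive]
    if t.size == 0:
        return _NOT_ESTIMABLE
    i_max = int(np.argmax(c))
    t_tail, c_tail = t[i_max + 1 :], c[i_max + 1 :]
    if t_tail.size < min_points:
        return _NOT_ESTIMABLE
    logc = np.log(c_tail)
    best: LambdaZFit | None = None
    for start in range(t_tail.size - min_points + 1):
        slope, intercept, adj = _loglinear_fit(t_tail[start:], logc[start:])
        if slope >= 0 or not np.isfinite(adj):
            continue
        candidate = LambdaZFit(-slope, t_tail.size - start, adj, intercept, True)
        if best is None or adj > best.adj_r_squared + _R2_TIE_TOL:
            best = candidate
    return best if best is not None else _NOT_ESTIMABLE


@dataclass(frozen=True)
class NCAResult:
    """Per-subject, per-analyte noncompartmental parameters."""

    subject: int
    analyte: Analyte
    dose: float
    cmax: float
    tmax: float
    auc_all: float
    lambda_z: float = math.nan
    t_half: float = math.nan
    auc_inf: float = math.nan
    cl_f: float = math.nan  # mL/min/kg
    vz_f: float = math.nan  # L/kg
    n_lambda: int = 0
    adj_r_squared: float = math.nan
    extrapolated_fraction: float = math.nan
    lambda_estimable: bool = False

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__}
        out["analyte"] = self.analyte.value
        return out


def compute_nca(profile: PKProfile, lambda_min_points: int = 3) -> NCAResult:
    """Full NCA for one profile; lambda_z-dependent metrics are NaN when flagged."""
    t, c = profile.quantifiable()
    if t.size == 0 or np.all(c == 0):
        return NCAResult(profile.subject, profile.analyte, profile.dose,
                         cmax=0.0, tmax=math.nan, auc_all=0.0)
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_all = float(np.trapezoid(c, t))
    fit = select_lambda_z(profile, min_points=lambda_min_points)
    if not fit.estimable:
        return NCAResult(profile.subject, profile.analyte, profile.dose,
                         cmax=cmax, tmax=tmax, auc_all=auc_all)
    c_last = float(c[-1])
    auc_inf = auc_all + c_last / fit.lambda_z
    # dose mg/kg -> ng/kg over ng.h/mL gives mL/h/kg; report per minute
    cl_f = profile.dose * 1e6 / auc_inf / 60.0
    vz_f = cl_f * 60.0 / fit.lambda_z / 1000.0
    return NCAResult(
        profile.subject, profile.analyte, profile.dose,
        cmax=cmax, tmax=tmax, auc_all=auc_all,
        lambda_z=fit.lambda_z, t_half=fit.t_half, auc_inf=auc_inf,
        cl_f=cl_f, vz_f=vz_f, n_lambda=fit.n_points,
        adj_r_squared=fit.adj_r_squared,
        extrapolated_fraction=(auc_inf - auc_all) / auc_inf,
        lambda_estimable=True,
    )


def profiles_from_dataset(ds: StudyDataset, analyte: Analyte | str) -> list[PKProfile]:
    analyte = Analyte(analyte)
    out = []
    for subject, rows in ds.iter_profiles(analyte):
        doses = ds.doses(subject)
        dose = doses[0].amount if doses else math.nan
        out.append(
            PKProfile(
                subject=subject,
                analyte=analyte,
                dose=dose,
                times=rows["TIME"].to_numpy(float),
                concentrations=rows["DV"].to_numpy(float),
                blq=rows["BLQ"].to_numpy(int).astype(bool),
            )
        )
    return out


def nca_dataset(ds: StudyDataset, gimeracil_dose: float | None = None) -> pd.DataFrame:
    """Per-subject NCA table for every analyte present in the dataset.

    Gimeracil records carry no dose row of their own (the compound is part of
    the combination dose); pass ``gimeracil_dose`` to enable its dose-scaled
    metrics.
    """
    rows = []
    for dvid in sorted(ds.table.loc[ds.table["EVID"] == 0, "DVID"].dropna().unique()):
        analyte = DVID_TO_ANALYTE[int(dvid)]
        for profile in profiles_from_dataset(ds, analyte):
            if analyte is Analyte.GIMERACIL and gimeracil_dose is not None:
                profile = PKProfile(profile.subject, analyte, gimeracil_dose,
                                    profile.times, profile.concentrations, profile.blq)
            result = compute_nca(profile)
            row = result.as_dict()
            row["group"] = ds.group_of(profile.subject)
            rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], alpha: float = 0.05,
    welch: bool = False,
) -> tuple[float, float, bool]:
    """Two-sided unpaired t-test (pooled variance unless ``welch``).

    Degenerate zero-variance inputs give p = 1 for equal means and p = 0
    otherwise, so a constant difference is always 'significant'.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return math.inf, 0.0, True
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t_stat), float(p_value), bool(p_value < alpha)


_SUMMARY_METRICS = ("t_half", "tmax", "cmax", "auc_all", "auc_inf", "cl_f", "vz_f")


def summarize_groups(
    nca_table: pd.DataFrame, metrics: Sequence[str] = _SUMMARY_METRICS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group summary (mean +/- SD per arm, significance star) per analyte/metric."""
    rows = []
    for analyte, sub in nca_table.groupby("analyte"):
        for metric in metrics:
            if metric not in sub.columns:
                continue
            a = sub.loc[sub["group"] == 0, metric].to_numpy(float)
            b = sub.loc[sub["group"] == 1, metric].to_numpy(float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size < 2 or b.size < 2:
                continue
            _, p, significant = compare_groups(a, b, alpha=alpha)
            rows.append(
                dict(
                    analyte=analyte, metric=metric,
                    control_mean=a.mean(), control_sd=a.std(ddof=1),
                    pretreated_mean=b.mean(), pretreated_sd=b.std(ddof=1),
                    p_value=p, significant=significant,
                    control=f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                    pretreated=f"{b.mean():.1f} ± {b.std(ddof=1):.1f}"
                    + (" *" if significant else ""),
                )
            )
    return pd.DataFrame(rows)
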