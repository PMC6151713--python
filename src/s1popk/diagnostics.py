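"""Simulation-based model diagnostics: VPC and NPDE.

The visual predictive check simulates many replicate studies at the observed
design and summarizes them as the 10th/25th/50th/75th/90th percentile bands
per nominal sampling time, overlaying the observations.  Bins follow the
nominal schedule (no adaptive binning) and bands are plain prediction
intervals (no prediction correction; each arm has a single dose level).

The normalized prediction distribution error decorrelates each subject's
observation vector with the inverse Cholesky factor of its empirical
simulation covariance, converts the componentwise rank of the decorrelated
observation among the decorrelated simulations to (0, 1), and maps it
through the standard-normal quantile.  Under the data-generating model the
NPDE sample is approximately N(0, 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datagen import PopulationModel, draw_subject
from .dataset import ANALYTE_TO_DVID, StudyDataset
from .model import Analyte, simulate

__all__ = ["VPCResult", "NPDEResult", "vpc", "npde", "PERCENTILES"]

PERCENTILES = (10, 25, 50, 75, 90)

_MODEL_ANALYTES = (Analyte.TEGAFUR, Analyte.FU)


def _as_population(model) -> PopulationModel:
    if isinstance(model, PopulationModel):
        return model
    if hasattr(model, "to_population"):
        return model.to_population()
    raise TypeError("expected a PopulationModel or FitResult")


@dataclass
class VPCResult:
    """Percentile bands per (group, analyte, nominal time) plus observed overlay."""

    bands: pd.DataFrame
    observed: pd.DataFrame
    n_sim: int
    seed: int

    def coverage(self, lower: int = 25, upper: int = 75) -> float:
        """Fraction of observed (non-BLQ) points inside the [lower, upper] band."""
        merged = self.observed.merge(
            self.bands, on=["group", "analyte", "time"], how="inner"
        )
        lo = merged[f"p{lower}"]
        hi = merged[f"p{upper}"]
        inside = (merged["dv"] >= lo) & (merged["dv"] <= hi)
        return float(inside.mean())


def vpc(
    model,
    dataset: StudyDataset,
    n_sim: int = 200,
    seed: int = 0,
    include_residual: bool = True,
) -> VPCResult:
    """Visual predictive check of ``model`` against ``dataset``.

    Replicate studies are simulated at each subject's own design (group,
    doses, nominal sampling times); percentiles pool subjects within a bin.
    Empty bins (no observations) are retained in the band table with
    ``n_obs = 0`` rather than dropped.
    """
    if n_sim < 100:
        raise ValueError("vpc needs n_sim >= 100")
    pop = _as_population(model)
    sim_values: dict[tuple[int, str, float], list[np.ndarray]] = {}
    obs_rows = []
    for subject in dataset.subjects:
        group = dataset.group_of(subject)
        doses = dataset.doses(subject)
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, subject]))
        sub_times: dict[Analyte, np.ndarray] = {}
        for analyte in _MODEL_ANALYTES:
            rows = dataset.observations(subject, analyte)
            rows = rows[rows["TIME"] > 0]
            if len(rows):
                sub_times[analyte] = np.sort(rows["TIME"].to_numpy(float))
                for r in rows.itertuples():
                    if not r.BLQ:
                        obs_rows.append(dict(group=group, analyte=analyte.value,
                                             time=float(r.TIME), dv=float(r.DV)))
        if not sub_times:
            continue
        all_times = np.unique(np.concatenate(list(sub_times.values())))
        sims = {a: np.empty((n_sim, t.size)) for a, t in sub_times.items()}
        for k in range(n_sim):
            params = draw_subject(pop, group, rng)
            profile = simulate(params, doses, all_times)
            for analyte, t in sub_times.items():
                pred = np.interp(t, all_times, profile.concentration(analyte))
                if include_residual:
                    err = pop.residual[analyte.value]
                    pred = np.maximum(
                        pred + err.sd(pred) * rng.standard_normal(t.size), 0.0
                    )
                sims[analyte][k] = pred
        for analyte, t in sub_times.items():
            for j, tj in enumerate(t):
                sim_values.setdefault((group, analyte.value, float(tj)), []).append(
                    sims[analyte][:, j]
                )

    observed = pd.DataFrame(obs_rows, columns=["group", "analyte", "time", "dv"])
    band_rows = []
    for (group, analyte, time), chunks in sorted(sim_values.items()):
        pooled = np.concatenate(chunks)
        pcts = np.percentile(pooled, PERCENTILES)
        n_obs = int(
            ((observed["group"] == group) & (observed["analyte"] == analyte)
             & (observed["time"] == time)).sum()
        ) if len(observed) else 0
        row = dict(group=group, analyte=analyte, time=time, n_obs=n_obs)
        row.update({f"p{p}": v for p, v in zip(PERCENTILES, pcts)})
        band_rows.append(row)
    bands = pd.DataFrame(band_rows)
    return VPCResult(bands=bands, observed=observed, n_sim=n_sim, seed=seed)


@dataclass
class NPDEResult:
    """Decorrelated normalized prediction distribution errors."""

    table: pd.DataFrame  # subject, analyte, time, npde
    mean: float
    variance: float
    normality_statistic: float
    normality_p: float

    @property
    def values(self) -> np.ndarray:
        return self.table["npde"].to_numpy(float)


def npde(
    model,
    dataset: StudyDataset,
    n_sim: int = 1000,
    seed: int = 0,
    ridge: float = 1e-10,
) -> NPDEResult:
    """Normalized prediction distribution errors of ``dataset`` under ``model``.

    BLQ observations are excluded.  A singular empirical simulation
    covariance is ridge-regularized (with a warning) before decorrelation;
    rank ties are broken by a deterministic uniform jitter.
    """
    if n_sim < 500:
        raise ValueError("npde needs n_sim >= 500")
    pop = _as_population(model)
    rows = []
    for subject in dataset.subjects:
        group = dataset.group_of(subject)
        doses = dataset.doses(subject)
        obs = dataset.observations(subject, include_blq=False)
        obs = obs[(obs["TIME"] > 0)
                  & obs["DVID"].isin([ANALYTE_TO_DVID[a] for a in _MODEL_ANALYTES])]
        if not len(obs):
            continue
        obs = obs.sort_values(["DVID", "TIME"])
        y = obs["DV"].to_numpy(float)
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, subject]))
        sims = np.empty((n_sim, y.size))
        times_by_analyte = {
            ANALYTE_TO_DVID[a]: obs.loc[obs["DVID"] == ANALYTE_TO_DVID[a], "TIME"]
            .to_numpy(float)
            for a in _MODEL_ANALYTES
        }
        all_times = np.unique(obs["TIME"].to_numpy(float))
        for k in range(n_sim):
            params = draw_subject(pop, group, rng)
            profile = simulate(params, doses, all_times)
            parts = []
            for analyte in _MODEL_ANALYTES:
                t = times_by_analyte[ANALYTE_TO_DVID[analyte]]
                if not t.size:
                    continue
                pred = np.interp(t, all_times, profile.concentration(analyte))
                err = pop.residual[analyte.value]
                parts.append(pred + err.sd(pred) * rng.standard_normal(t.size))
            sims[k] = np.concatenate(parts)
        m = sims.mean(axis=0)
        cov = np.cov(sims.T) if y.size > 1 else np.array([[sims.var(ddof=1)]])
        cov = np.atleast_2d(cov)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular simulation covariance for subject {subject}; "
                "ridge-regularizing", RuntimeWarning, stacklevel=2,
            )
            bump = max(ridge, 1e-8 * float(np.mean(np.diag(cov))) + ridge)
            L = np.linalg.cholesky(cov + bump * np.eye(cov.shape[0]))
        d_obs = np.linalg.solve(L, y - m)
        d_sim = np.linalg.solve(L, (sims - m).T)  # (n_obs, n_sim)
        counts = (d_sim < d_obs[:, None]).sum(axis=1)
        jitter = rng.uniform(0.0, 1.0, size=y.size)
        pde = np.clip((counts + jitter) / n_sim, 0.5 / n_sim, 1.0 - 0.5 / n_sim)
        values = stats.norm.ppf(pde)
        for r, v in zip(obs.itertuples(), values):
            rows.append(dict(subject=subject, group=group,
                             analyte={1: "tegafur", 2: "5fu"}[int(r.DVID)],
                             time=float(r.TIME), npde=float(v)))
    table = pd.DataFrame(rows, columns=["subject", "group", "analyte", "time", "npde"])
    values = table["npde"].to_numpy(float)
    if values.size >= 8:
        if values.size <= 5000:
            stat, p = stats.shapiro(values)
        else:  # pragma: no cover - very large datasets
            stat, p = stats.normaltest(values)
    else:
        stat, p = math.nan, math.nan
    return NPDEResult(
        table=table,
        mean=float(values.mean()) if values.size else math.nan,
        variance=float(values.var(ddof=1)) if values.size > 1 else math.nan,
        normality_statistic=float(stat),
        normality_p=float(p),
    )
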