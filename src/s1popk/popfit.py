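"""Population (NLME) estimation by importance-sampling Monte-Carlo parametric EM.

The hierarchical model: subject i in group g has transformed parameters

    phi_i = mu + beta * g + eta_i,      eta_i ~ N(0, diag(omega^2))

where the transform is log for every structural parameter except ``f_met``
(logit, so the fraction stays in (0, 1)), ``beta`` is the pretreatment effect
(log scale, control as reference) carried by a configurable subset of
parameters, and observations follow the structural model with a combined
additive + proportional Gaussian residual per analyte.

Each EM iteration runs, per subject, a Laplace approximation at the
conditional mode of eta, importance-samples around it with an inflated
proposal covariance, and accumulates self-normalized conditional moments
(E step).  Typical values and group effects are then updated as weighted
means on the transformed scale, BSV variances as mean conditional second
central moments, and the residual SDs by direct weighted likelihood
maximization (M step).  The marginal log-likelihood is estimated by the
importance-sampling normalizing constants.

Everything is deterministic given the seed; per-subject seeding makes the
result invariant to subject ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .datagen import PopulationModel, ResidualErrorModel, _default_residuals
from .dataset import StudyDataset
from .model import (
    PARAM_NAMES,
    Analyte,
    Route,
    StructuralParams,
    _propagate,
    rate_matrix,
)

__all__ = [
    "FitSpec",
    "FitResult",
    "individual_loglik",
    "mcpem_fit",
    "empirical_bayes",
    "nca_informed_init",
]

_LOG2PI = math.log(2.0 * math.pi)
_N_PARAMS = len(PARAM_NAMES)
_FMET_IDX = PARAM_NAMES.index("f_met")


# -- parameter transform -----------------------------------------------------


def to_transformed(params: StructuralParams) -> np.ndarray:
    """Map parameters to the unconstrained estimation scale (log / logit)."""
    phi = np.log(params.as_array())
    phi[_FMET_IDX] = logit(np.clip(params.f_met, 1e-12, 1 - 1e-12))
    return phi


def from_transformed(phi: np.ndarray) -> np.ndarray:
    values = np.exp(phi)
    values[_FMET_IDX] = expit(phi[_FMET_IDX])
    return values


# -- subject-level data and likelihood ---------------------------------------


@dataclass
class _Subject:
    subject: int
    group: int
    times: np.ndarray          # unique observation times, sorted
    obs_time_idx: np.ndarray   # index into times per observation
    analyte_idx: np.ndarray    # 0 = tegafur, 1 = 5-FU, per observation
    y: np.ndarray              # observed concentrations (ng/mL)
    doses: list[tuple[float, float, bool]]  # (time, amount, is_iv)


def _prepare_subjects(ds: StudyDataset, blq_policy: str) -> list[_Subject]:
    if blq_policy != "discard":
        raise ValueError(f"unsupported BLQ policy {blq_policy!r}")
    subjects = []
    for sid in ds.subjects:
        obs = ds.observations(sid, include_blq=False)
        obs = obs[obs["DVID"].isin([1, 2])].sort_values(["TIME", "DVID"])
        times = np.unique(obs["TIME"].to_numpy(float))
        t_idx = np.searchsorted(times, obs["TIME"].to_numpy(float))
        a_idx = obs["DVID"].to_numpy(int) - 1
        doses = [
            (d.time, d.amount, d.route is Route.IV_5FU) for d in ds.doses(sid)
        ]
        subjects.append(
            _Subject(sid, ds.group_of(sid), times, t_idx, a_idx,
                     obs["DV"].to_numpy(float), doses)
        )
    return subjects


def _predict(p: np.ndarray, subj: _Subject) -> np.ndarray:
    """Predicted concentration (ng/mL) for each of the subject's observations."""
    if subj.y.size == 0:
        return np.empty(0)
    A = rate_matrix(p)
    x1 = np.zeros(subj.times.size)
    x4 = np.zeros(subj.times.size)
    for t_dose, amount, is_iv in subj.doses:
        if amount == 0:
            continue
        x0 = np.zeros(6)
        x0[4 if is_iv else 0] = amount
        dt = subj.times - t_dose
        live = dt >= 0
        X = _propagate(A, x0, dt[live])
        x1[live] += X[:, 1]
        x4[live] += X[:, 4]
    conc = np.empty((2, subj.times.size))
    conc[0] = x1 / p[8] * 1000.0
    conc[1] = x4 / p[10] * 1000.0
    return conc[subj.analyte_idx, subj.obs_time_idx]


def _gaussian_loglik(
    y: np.ndarray, pred: np.ndarray, add: np.ndarray, prop: np.ndarray
) -> float:
    var = add**2 + (prop * pred) ** 2
    return float(-0.5 * np.sum(_LOG2PI + np.log(var) + (y - pred) ** 2 / var))


def individual_loglik(
    params: StructuralParams,
    times: Sequence[float],
    analytes: Sequence[Analyte | str],
    observations: Sequence[float],
    error: Mapping[str, ResidualErrorModel],
    doses: Sequence | None = None,
    dose: float = 5.0,
) -> float:
    """Gaussian log-likelihood of one subject's observations.

    ``doses`` defaults to a single oral tegafur dose of ``dose`` mg/kg at
    time 0.  BLQ records must be removed by the caller (discard policy).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(observations, dtype=float)
    a_idx = np.array([0 if Analyte(a) is Analyte.TEGAFUR else 1 for a in analytes])
    ut = np.unique(t)
    if doses is None:
        dose_list = [(0.0, float(dose), False)]
    else:
        dose_list = [(d.time, d.amount, d.route is Route.IV_5FU) for d in doses]
    subj = _Subject(0, 0, ut, np.searchsorted(ut, t), a_idx, y, dose_list)
    pred = _predict(params.as_array(), subj)
    add = np.array([error[Analyte.TEGAFUR.value].additive,
                    error[Analyte.FU.value].additive])[a_idx]
    prop = np.array([error[Analyte.TEGAFUR.value].proportional,
                     error[Analyte.FU.value].proportional])[a_idx]
    if np.any(add**2 + prop**2 == 0):
        raise ValueError("residual SD must be positive for every observation")
    return _gaussian_loglik(y, pred, add, prop)


# -- fit specification and result --------------------------------------------


@dataclass
class FitSpec:
    """Settings of the MC-PEM run.

    Parameters in ``bsv_params`` carry an estimated random effect and have
    their typical value updated each iteration; parameters outside it are
    frozen at their initial values.  ``group_params`` (must be a subset of
    ``bsv_params``) additionally carry a pretreated-vs-control effect.
    """

    group_params: tuple[str, ...] = ("ka", "ka_met", "cl_5fu")
    bsv_params: tuple[str, ...] = PARAM_NAMES
    init: StructuralParams | None = None
    init_ratios: Mapping[str, float] = field(default_factory=dict)
    omega2_init: float | Mapping[str, float] = 0.1
    error_init: Mapping[str, ResidualErrorModel] | None = None
    estimate_residual: bool = True
    n_importance: int = 300
    max_iter: int = 100
    tol: float = 1e-4
    window: int = 10
    seed: int = 0
    blq_policy: str = "discard"
    common_random_numbers: bool = False
    proposal_inflation: float = 1.2
    omega2_floor: float = 1e-4
    residual_floor: tuple[float, float] = (1e-3, 1e-4)
    mode_maxiter: tuple[int, int] = (40, 8)

    def __post_init__(self) -> None:
        if self.n_importance < 100:
            raise ValueError("importance samples per subject must be >= 100")
        unknown = set(self.bsv_params) | set(self.group_params)
        unknown -= set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        if not set(self.group_params) <= set(self.bsv_params):
            raise ValueError("group_params must be a subset of bsv_params")


@dataclass
class FitResult:
    """Population estimates plus convergence and subject-level information."""

    typical: StructuralParams
    group_ratios: dict[str, float]
    omega2: dict[str, float]
    residual: dict[str, ResidualErrorModel]
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    eta_modes: dict[int, np.ndarray] = field(default_factory=dict)
    bsv_params: tuple[str, ...] = PARAM_NAMES
    seed: int = 0

    @property
    def pretreated(self) -> StructuralParams:
        values = {
            n: getattr(self.typical, n) * self.group_ratios.get(n, 1.0)
            for n in PARAM_NAMES
        }
        if "f_met" in self.group_ratios:
            values["f_met"] = min(values["f_met"], 1.0)
        return StructuralParams(**values)

    def to_population(self) -> PopulationModel:
        return PopulationModel(
            typical=self.typical,
            group_ratios=dict(self.group_ratios),
            omega2=dict(self.omega2),
            residual=dict(self.residual),
        )

    def summary(self) -> dict[str, float]:
        out = {f"typical.{n}": getattr(self.typical, n) for n in PARAM_NAMES}
        out.update({f"ratio.{k}": v for k, v in self.group_ratios.items()})
        out.update({f"omega2.{k}": v for k, v in self.omega2.items()})
        for analyte, err in self.residual.items():
            out[f"residual.{analyte}.additive"] = err.additive
            out[f"residual.{analyte}.proportional"] = err.proportional
        out["loglik"] = self.loglik_trace[-1] if self.loglik_trace else math.nan
        out["converged"] = float(self.converged)
        return out


# -- the EM machinery --------------------------------------------------------


class _ErrorArrays:
    """Residual SDs broadcast per observation (index 0 tegafur, 1 5-FU)."""

    def __init__(self, error: Mapping[str, ResidualErrorModel]):
        self.add = np.array([error[Analyte.TEGAFUR.value].additive,
                             error[Analyte.FU.value].additive])
        self.prop = np.array([error[Analyte.TEGAFUR.value].proportional,
                              error[Analyte.FU.value].proportional])

    def loglik(self, subj: _Subject, pred: np.ndarray) -> float:
        return _gaussian_loglik(
            subj.y, pred, self.add[subj.analyte_idx], self.prop[subj.analyte_idx]
        )


def _subject_rng(seed: int, subject: int, iteration: int, crn: bool) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, subject, 0 if crn else iteration])
    )


def _pd_covariance(
    hess_inv: np.ndarray, omega2_red: np.ndarray, inflation: float
) -> np.ndarray:
    sym = 0.5 * (hess_inv + hess_inv.T)
    vals, vecs = np.linalg.eigh(sym)
    # the conditional covariance cannot far exceed the prior variance
    vals = np.clip(vals, 1e-8, 2.0 * float(np.max(omega2_red)))
    return inflation * (vecs * vals) @ vecs.T


def _e_step_subject(
    subj: _Subject,
    phi_base: np.ndarray,
    omega2_red: np.ndarray,
    bsv_idx: np.ndarray,
    errors: _ErrorArrays,
    rng: np.random.Generator,
    n_samples: int,
    warm_eta: np.ndarray,
    maxiter: int,
    inflation: float,
):
    """Laplace mode + importance sampling for one subject.

    Returns (marginal loglik, E[eta], E[eta^2], mode, weights, predictions).
    """
    d = bsv_idx.size
    inv_omega = 1.0 / omega2_red

    def neg_logpost(eta: np.ndarray) -> float:
        phi = phi_base.copy()
        phi[bsv_idx] += eta
        ll = errors.loglik(subj, _predict(from_transformed(phi), subj))
        return -(ll - 0.5 * float(eta @ (inv_omega * eta)))

    if subj.y.size == 0:
        zero = np.zeros(d)
        return 0.0, zero, omega2_red.copy(), zero, None, None

    res = minimize(neg_logpost, warm_eta, method="BFGS",
                   options={"maxiter": maxiter, "gtol": 1e-3})
    mode = res.x
    cov = _pd_covariance(np.atleast_2d(res.hess_inv), omega2_red, inflation)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_samples, d))
    etas = mode + z @ L.T
    log_det = float(np.sum(np.log(np.diag(L))))
    logq = -0.5 * np.sum(z**2, axis=1) - log_det - 0.5 * d * _LOG2PI

    logp = np.empty(n_samples)
    preds = np.empty((n_samples, subj.y.size))
    for k in range(n_samples):
        phi = phi_base.copy()
        phi[bsv_idx] += etas[k]
        preds[k] = _predict(from_transformed(phi), subj)
        ll = errors.loglik(subj, preds[k])
        logp[k] = ll - 0.5 * float(etas[k] @ (inv_omega * etas[k])) \
            - 0.5 * float(np.sum(np.log(2.0 * np.pi * omega2_red)))
    logw = logp - logq
    marginal = float(logsumexp(logw) - math.log(n_samples))
    weights = np.exp(logw - logsumexp(logw))
    e1 = weights @ etas
    e2 = weights @ etas**2
    return marginal, e1, e2, mode, weights, preds


def _update_residual(
    errors: dict[str, ResidualErrorModel],
    per_subject: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    floor: tuple[float, float],
) -> dict[str, ResidualErrorModel]:
    """Weighted ML update of (additive, proportional) SDs per analyte."""
    new = dict(errors)
    for a_code, analyte in ((0, Analyte.TEGAFUR.value), (1, Analyte.FU.value)):
        ys, fs, ws = [], [], []
        for y, a_idx, weights, preds in per_subject:
            if weights is None:
                continue
            sel = a_idx == a_code
            if not np.any(sel):
                continue
            n_obs = int(sel.sum())
            ys.append(np.broadcast_to(y[sel], preds[:, sel].shape).ravel())
            fs.append(preds[:, sel].ravel())
            ws.append(np.repeat(weights, n_obs))
        if not ys:
            continue
        y_all = np.concatenate(ys)
        f_all = np.concatenate(fs)
        w_all = np.concatenate(ws)

        def nll(x: np.ndarray) -> float:
            add, prop = np.exp(x)
            var = add**2 + (prop * f_all) ** 2
            return float(np.sum(w_all * (np.log(var) + (y_all - f_all) ** 2 / var)))

        start = np.log([max(errors[analyte].additive, floor[0]),
                        max(errors[analyte].proportional, floor[1])])
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
        add, prop = np.exp(res.x)
        new[analyte] = ResidualErrorModel(
            additive=max(add, floor[0]), proportional=max(prop, floor[1])
        )
    return new


def mcpem_fit(dataset: StudyDataset, spec: FitSpec) -> FitResult:
    """Fit the population model to a study by importance-sampling MC-PEM."""
    subjects = _prepare_subjects(dataset, spec.blq_policy)
    if not subjects:
        raise ValueError("dataset contains no usable subjects")
    init = spec.init if spec.init is not None else nca_informed_init(dataset)
    mu = to_transformed(init)
    beta = np.zeros(_N_PARAMS)
    for name, ratio in spec.init_ratios.items():
        beta[PARAM_NAMES.index(name)] = math.log(ratio)
    group_idx = np.array([PARAM_NAMES.index(n) for n in spec.group_params], dtype=int)
    bsv_idx = np.array(sorted(PARAM_NAMES.index(n) for n in spec.bsv_params), dtype=int)
    in_group = np.isin(bsv_idx, group_idx)

    if isinstance(spec.omega2_init, Mapping):
        omega2_red = np.array(
            [max(float(spec.omega2_init.get(PARAM_NAMES[j], 0.1)), spec.omega2_floor)
             for j in bsv_idx]
        )
    else:
        omega2_red = np.full(bsv_idx.size, max(float(spec.omega2_init), spec.omega2_floor))

    errors = dict(spec.error_init) if spec.error_init else _default_residuals()
    groups = np.array([s.group for s in subjects])
    warm = {s.subject: np.zeros(bsv_idx.size) for s in subjects}
    trace: list[float] = []
    converged = False
    iteration = 0

    for iteration in range(1, spec.max_iter + 1):
        err_arrays = _ErrorArrays(errors)
        maxiter = spec.mode_maxiter[0] if iteration == 1 else spec.mode_maxiter[1]
        e1s = np.empty((len(subjects), bsv_idx.size))
        e2s = np.empty((len(subjects), bsv_idx.size))
        residual_acc = []
        total_ll = 0.0
        for i, subj in enumerate(subjects):
            phi_base = mu.copy()
            if subj.group == 1:
                phi_base += beta
            rng = _subject_rng(spec.seed, subj.subject, iteration,
                              spec.common_random_numbers)
            marginal, e1, e2, mode, weights, preds = _e_step_subject(
                subj, phi_base, omega2_red, bsv_idx, err_arrays, rng,
                spec.n_importance, warm[subj.subject], maxiter,
                spec.proposal_inflation,
            )
            total_ll += marginal
            e1s[i], e2s[i] = e1, e2
            warm[subj.subject] = mode
            residual_acc.append((subj.y, subj.analyte_idx, weights, preds))

        # M step: typical values / group effects on the transformed scale
        phi_hat = mu[bsv_idx] + np.outer(groups == 1, beta[bsv_idx]) + e1s
        is_control = groups == 0
        new_mu = mu.copy()
        new_beta = beta.copy()
        for j, pidx in enumerate(bsv_idx):
            if in_group[j]:
                mu_j = float(phi_hat[is_control, j].mean())
                beta_j = float(phi_hat[~is_control, j].mean()) - mu_j
            else:
                mu_j = float(phi_hat[:, j].mean())
                beta_j = 0.0
            new_mu[pidx] = mu_j
            new_beta[pidx] = beta_j
        fitted = new_mu[bsv_idx] + np.outer(groups == 1, new_beta[bsv_idx])
        cond_var = np.maximum(e2s - e1s**2, 0.0)
        base = mu[bsv_idx] + np.outer(groups == 1, beta[bsv_idx])
        omega2_red = np.maximum(
            np.mean(cond_var + (base + e1s - fitted) ** 2, axis=0),
            spec.omega2_floor,
        )
        mu, beta = new_mu, new_beta
        if spec.estimate_residual:
            errors = _update_residual(errors, residual_acc, spec.residual_floor)

        trace.append(total_ll)
        if len(trace) > spec.window:
            recent = trace[-(spec.window + 1):]
            scale = max(abs(recent[-1]), 1.0)
            if all(abs(recent[k + 1] - recent[k]) / scale < spec.tol
                   for k in range(spec.window)):
                converged = True
                break

    typical = StructuralParams.from_array(from_transformed(mu))
    ratios = {n: float(math.exp(beta[PARAM_NAMES.index(n)])) for n in spec.group_params}
    omega2 = {PARAM_NAMES[pidx]: float(omega2_red[j]) for j, pidx in enumerate(bsv_idx)}
    return FitResult(
        typical=typical,
        group_ratios=ratios,
        omega2=omega2,
        residual=errors,
        loglik_trace=trace,
        converged=converged,
        n_iter=iteration,
        eta_modes={s.subject: warm[s.subject].copy() for s in subjects},
        bsv_params=tuple(PARAM_NAMES[j] for j in bsv_idx),
        seed=spec.seed,
    )


def empirical_bayes(
    dataset: StudyDataset, result: FitResult, maxiter: int = 100
) -> dict[int, StructuralParams]:
    """MAP (empirical Bayes) individual parameters at the final population fit."""
    subjects = _prepare_subjects(dataset, "discard")
    bsv_idx = np.array(sorted(PARAM_NAMES.index(n) for n in result.bsv_params), dtype=int)
    omega2_red = np.array(
        [max(result.omega2.get(PARAM_NAMES[j], 1e-4), 1e-10) for j in bsv_idx]
    )
    errors = _ErrorArrays(result.residual)
    mu = to_transformed(result.typical)
    beta = np.zeros(_N_PARAMS)
    for name, ratio in result.group_ratios.items():
        beta[PARAM_NAMES.index(name)] = math.log(ratio)
    inv_omega = 1.0 / omega2_red
    out: dict[int, StructuralParams] = {}
    for subj in subjects:
        phi_base = mu + (beta if subj.group == 1 else 0.0)
        if subj.y.size == 0:
            out[subj.subject] = StructuralParams.from_array(from_transformed(phi_base))
            continue

        def neg_logpost(eta: np.ndarray) -> float:
            phi = phi_base.copy()
            phi[bsv_idx] += eta
            ll = errors.loglik(subj, _predict(from_transformed(phi), subj))
            return -(ll - 0.5 * float(eta @ (inv_omega * eta)))

        start = result.eta_modes.get(subj.subject, np.zeros(bsv_idx.size))
        res = minimize(neg_logpost, start, method="BFGS",
                       options={"maxiter": maxiter, "gtol": 1e-4})
        phi = phi_base.copy()
        phi[bsv_idx] += res.x
        out[subj.subject] = StructuralParams.from_array(from_transformed(phi))
    return out


def nca_informed_init(dataset: StudyDataset) -> StructuralParams:
    """Rough starting values from noncompartmental summaries of the dataset.

    Apparent clearances come from dose/AUC, the absorption rate from the
    median tegafur Tmax, and volumes from the terminal-phase volume; shape
    parameters fall back to generic, in-domain values.  Only used when the
    caller supplies no initial estimate.
    """
    from .nca import compute_nca, profiles_from_dataset

    teg = [compute_nca(p) for p in profiles_from_dataset(dataset, Analyte.TEGAFUR)]
    fu = [compute_nca(p) for p in profiles_from_dataset(dataset, Analyte.FU)]
    teg = [r for r in teg if r.lambda_estimable]
    fu = [r for r in fu if r.lambda_estimable]

    def _median(values: list[float], fallback: float) -> float:
        values = [v for v in values if np.isfinite(v) and v > 0]
        return float(np.median(values)) if values else fallback

    cl_teg = _median([r.cl_f * 60.0 / 1000.0 for r in teg], 0.1)
    vz_teg = _median([r.vz_f for r in teg], 0.2)
    tmax = _median([r.tmax for r in teg], 1.5)
    cl_fu = _median([r.cl_f * 60.0 / 1000.0 * 0.5 for r in fu], 3.0)
    ka = 1.0 / tmax
    return StructuralParams(
        ka=ka,
        ka_met=0.3 * ka,
        k_conv=2.0,
        cl_teg=cl_teg,
        cld_teg=2.0 * cl_teg,
        f_met=0.3,
        cl_5fu=cl_fu,
        cld_5fu=0.5 * cl_fu,
        v1_teg=max(vz_teg / 4.0, 1e-3),
        v2_teg=max(vz_teg / 2.0, 1e-3),
        v1_5fu=0.5,
        v2_5fu=0.3,
    )
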