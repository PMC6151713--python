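"""Population-fit tests: likelihood values, EM fixed point, recovery, invariances."""

import math

import numpy as np
import pandas as pd
import pytest

from s1popk import reference
from s1popk.datagen import (
    PopulationModel,
    ResidualErrorModel,
    StudyDesign,
    simulate_study,
)
from s1popk.dataset import StudyDataset
from s1popk.model import PARAM_NAMES, Analyte, DoseEvent, Route, simulate
from s1popk.popfit import (
    FitResult,
    FitSpec,
    empirical_bayes,
    individual_loglik,
    mcpem_fit,
)

from conftest import noise_free_residuals


def _unit_errors(add=1.0, prop=0.0):
    if add == 0.0 and prop == 0.0:
        raise ValueError
    return {a: ResidualErrorModel(additive=add, proportional=max(prop, 1e-300))
            for a in ("tegafur", "5fu", "gimeracil")}


def _manual_result(typical, omega2, residual, ratios=None):
    return FitResult(typical=typical, group_ratios=ratios or {}, omega2=omega2,
                     residual=residual, loglik_trace=[], converged=True, n_iter=0,
                     bsv_params=tuple(omega2))


class TestIndividualLoglik:
    def test_exact_fit_additive_unit_error(self, control_params):
        """Observation equal to prediction with SD 1 contributes -ln(2*pi)/2."""
        times = [1.0, 2.0, 4.0]
        profile = simulate(control_params, [DoseEvent(0, 5.0, Route.ORAL_TEGAFUR)],
                           times)
        ll = individual_loglik(control_params, times, [Analyte.TEGAFUR] * 3,
                               profile.tegafur, _unit_errors())
        assert ll == pytest.approx(3 * (-0.5 * math.log(2 * math.pi)), rel=1e-12)

    def test_matches_hand_computed_density(self, control_params):
        """Three handmade points against the Gaussian density written out directly."""
        times = [0.5, 2.0, 8.0]
        analytes = [Analyte.TEGAFUR, Analyte.FU, Analyte.TEGAFUR]
        profile = simulate(control_params, [DoseEvent(0, 5.0, Route.ORAL_TEGAFUR)],
                           times)
        preds = np.array([profile.tegafur[0], profile.fu[1], profile.tegafur[2]])
        y = preds + np.array([30.0, -4.0, 11.0])
        add, prop = 20.0, 0.1
        expected = 0.0
        for yi, fi in zip(y, preds):
            var = add**2 + (prop * fi) ** 2
            expected += -0.5 * math.log(2 * math.pi * var) - (yi - fi) ** 2 / (2 * var)
        ll = individual_loglik(control_params, times, analytes, y,
                               _unit_errors(add, prop))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_true_parameters_dominate_perturbed(self, control_params):
        times = list(np.array(reference.SAMPLING_TIMES))
        profile = simulate(control_params, [DoseEvent(0, 5.0, Route.ORAL_TEGAFUR)],
                           times)
        y = np.concatenate([profile.tegafur, profile.fu])
        tt = times + times
        aa = [Analyte.TEGAFUR] * len(times) + [Analyte.FU] * len(times)
        errors = _unit_errors(add=10.0, prop=0.1)
        ll_true = individual_loglik(control_params, tt, aa, y, errors)
        doubled = control_params.replace(cl_teg=2 * control_params.cl_teg,
                                         cl_5fu=2 * control_params.cl_5fu)
        assert ll_true > individual_loglik(doubled, tt, aa, y, errors)

    def test_zero_residual_sd_rejected(self, control_params):
        bad = {a: ResidualErrorModel(additive=0.0, proportional=1e-300)
               for a in ("tegafur", "5fu")}
        with pytest.raises(ValueError, match="positive"):
            individual_loglik(control_params, [1.0], [Analyte.TEGAFUR], [100.0], bad)


class TestMCPEM:
    def test_fixed_point_on_noise_free_zero_bsv_data(self, deterministic_study):
        """Initialized at the truth on exact data, EM stays at the truth."""
        spec = FitSpec(init=reference.CONTROL_PARAMS,
                       init_ratios=reference.GROUP_RATIOS,
                       omega2_init=1e-4,
                       error_init=_unit_errors(add=0.1, prop=1e-3),
                       estimate_residual=False,
                       n_importance=100, max_iter=3, seed=2)
        fit = mcpem_fit(deterministic_study, spec)
        drift = np.abs(fit.typical.as_array() / reference.CONTROL_PARAMS.as_array() - 1)
        assert drift.max() < 0.02
        for name, truth in reference.GROUP_RATIOS.items():
            assert fit.group_ratios[name] == pytest.approx(truth, rel=0.05)

    def test_recovers_direction_of_all_three_group_effects(self,
                                                           reference_population):
        """A 2 x 5 study reproduces slower absorption/conversion, faster 5-FU
        clearance in the pretreated arm."""
        ds = simulate_study(reference_population, StudyDesign(n_per_group=5, seed=3,
                                                              n_iv=3))
        fit = mcpem_fit(ds, FitSpec(n_importance=100, max_iter=15, seed=11))
        assert fit.group_ratios["ka"] < 1.0
        assert fit.group_ratios["ka_met"] < 1.0
        assert fit.group_ratios["cl_5fu"] > 1.0

    def test_subject_order_invariance(self, reference_population):
        """Per-subject seeding makes estimates independent of row order."""
        ds = simulate_study(reference_population, StudyDesign(n_per_group=3, seed=9))
        reversed_rows = ds.table.sort_values("ID", ascending=False,
                                             kind="stable").reset_index(drop=True)
        spec = dict(n_importance=100, max_iter=5, seed=4)
        fit_a = mcpem_fit(ds, FitSpec(**spec))
        fit_b = mcpem_fit(StudyDataset(reversed_rows), FitSpec(**spec))
        assert np.allclose(fit_a.typical.as_array(), fit_b.typical.as_array())
        assert fit_a.group_ratios == pytest.approx(fit_b.group_ratios)

    def test_loglik_near_monotone_with_common_random_numbers(self,
                                                             reference_population):
        ds = simulate_study(reference_population, StudyDesign(n_per_group=3, seed=9))
        fit = mcpem_fit(ds, FitSpec(n_importance=100, max_iter=12, seed=4,
                                    common_random_numbers=True))
        diffs = np.diff(fit.loglik_trace)
        assert fit.loglik_trace[-1] > fit.loglik_trace[0]
        assert diffs.min() > -2.5  # Monte-Carlo noise floor of the E step

    def test_unit_multipliers_recovered_near_one(self):
        """Generated without group effects, estimated ratios stay near 1."""
        pop = PopulationModel.from_reference(group_ratios={})
        n = 6
        ds = simulate_study(pop, StudyDesign(n_per_group=n, seed=21))
        fit = mcpem_fit(ds, FitSpec(n_importance=100, max_iter=40, seed=5))
        for name in ("ka", "ka_met", "cl_5fu"):
            # 4 SD band: between-subject variance plus a per-subject estimation
            # variance allowance of 0.04 (log-scale SE ~0.2 from ~15% assay noise)
            bound = 4.0 * math.sqrt(2.0 * (reference.BSV_OMEGA2[name] + 0.04) / n)
            assert abs(math.log(fit.group_ratios[name])) < bound

    def test_importance_sample_floor_enforced(self):
        with pytest.raises(ValueError, match=">= 100"):
            FitSpec(n_importance=50)
        with pytest.raises(ValueError, match="subset"):
            FitSpec(group_params=("ka",), bsv_params=("cl_teg",))


class TestEmpiricalBayes:
    def test_subject_without_observations_gets_population_typical(self):
        table = pd.DataFrame([
            dict(ID=1, TIME=0.0, EVID=1, AMT=5.0, ROUTE="ORAL_TEG",
                 DVID=pd.NA, DV=np.nan, BLQ=0, GROUP=0),
        ])
        ds = StudyDataset(table)
        result = _manual_result(reference.CONTROL_PARAMS,
                                dict(reference.BSV_OMEGA2), _unit_errors(10.0, 0.1))
        ebes = empirical_bayes(ds, result)
        assert np.allclose(ebes[1].as_array(),
                           reference.CONTROL_PARAMS.as_array(), rtol=1e-12)

    def test_dense_noise_free_data_recovers_subject_parameters(
            self, reference_population, rng):
        from s1popk.datagen import draw_subject

        truth = draw_subject(reference_population, 0, rng)
        times = np.arange(0.25, 24.25, 0.25)
        profile = simulate(truth, [DoseEvent(0, 5.0, Route.ORAL_TEGAFUR)], times)
        rows = [dict(ID=1, TIME=0.0, EVID=1, AMT=5.0, ROUTE="ORAL_TEG",
                     DVID=pd.NA, DV=np.nan, BLQ=0, GROUP=0)]
        for dvid, series in ((1, profile.tegafur), (2, profile.fu)):
            rows += [dict(ID=1, TIME=float(t), EVID=0, AMT=np.nan, ROUTE="",
                          DVID=dvid, DV=float(c), BLQ=0, GROUP=0)
                     for t, c in zip(times, series)]
        ds = StudyDataset(pd.DataFrame(rows))
        result = _manual_result(reference.CONTROL_PARAMS,
                                dict(reference.BSV_OMEGA2),
                                _unit_errors(add=0.5, prop=0.005))
        ebe = empirical_bayes(ds, result)[1]
        # identifiable rates/clearances approach the subject's own values
        for name in ("ka", "cl_teg", "cl_5fu", "v1_teg"):
            assert getattr(ebe, name) == pytest.approx(getattr(truth, name), rel=0.15)

    def test_shrinkage_grows_with_residual_noise(self, reference_population):
        """Raising the additive residual SD (proportional held fixed) pulls
        empirical-Bayes estimates toward the population typical.  Only the
        additive component is scaled: a prediction-dependent variance does not
        flatten the likelihood as it grows."""
        ds = simulate_study(reference_population, StudyDesign(n_per_group=4, seed=6))
        typical = reference.CONTROL_PARAMS
        spread = []
        for add in (5.0, 200.0, 4000.0):
            result = _manual_result(typical, dict(reference.BSV_OMEGA2),
                                    _unit_errors(add, 0.1),
                                    ratios=dict(reference.GROUP_RATIOS))
            ebes = empirical_bayes(ds, result)
            devs = []
            for sid, params in ebes.items():
                base = typical if ds.group_of(sid) == 0 else reference.PRETREATED_PARAMS
                devs.append(abs(math.log(params.cl_5fu / base.cl_5fu)))
            spread.append(np.mean(devs))
        assert spread[0] > spread[1] > spread[2]
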