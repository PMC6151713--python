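"""NCA tests: lambda_z selection against a brute-force oracle, AUC rules, t-test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from s1popk import reference
from s1popk.datagen import GimeracilParams, PopulationModel, StudyDesign, bateman_profile
from s1popk.model import Analyte, DoseEvent, Route, analytic_auc, simulate
from s1popk.nca import (
    PKProfile,
    compare_groups,
    compute_nca,
    nca_dataset,
    select_lambda_z,
    summarize_groups,
)

SCHEDULE = np.array([0.25, 0.5, 1, 1.5, 2, 3, 4, 8, 12, 24.0])


def _profile(times, conc, dose=5.0, blq=None, analyte=Analyte.TEGAFUR):
    times = np.asarray(times, float)
    conc = np.asarray(conc, float)
    blq = np.zeros_like(times, dtype=bool) if blq is None else np.asarray(blq, bool)
    return PKProfile(subject=1, analyte=analyte, dose=dose, times=times,
                     concentrations=conc, blq=blq)


def _brute_force_lambda(times, conc):
    """Exhaustive enumeration of every contiguous terminal subset (oracle)."""
    i_max = int(np.argmax(conc))
    t_tail, c_tail = times[i_max + 1:], conc[i_max + 1:]
    best = None
    for start in range(len(t_tail) - 2):
        t, c = t_tail[start:], np.log(c_tail[start:])
        n = len(t)
        slope, intercept = np.polyfit(t, c, 1)
        if slope >= 0:
            continue
        res = c - (slope * t + intercept)
        ss_tot = np.sum((c - c.mean()) ** 2)
        if ss_tot == 0:
            continue
        adj = 1 - (1 - (1 - res @ res / ss_tot)) * (n - 1) / (n - 2)
        # ties (within 1e-9) resolved toward the longer subset, i.e. first seen
        if best is None or adj > best[0] + 1e-9:
            best = (adj, -slope, n)
    return best


class TestLambdaZ:
    def test_monoexponential_exact(self):
        conc = 100.0 * np.exp(-0.3465 * SCHEDULE)
        fit = select_lambda_z(_profile(SCHEDULE, conc))
        assert fit.estimable
        assert fit.lambda_z == pytest.approx(0.3465, abs=1e-10)
        assert fit.t_half == pytest.approx(2.0, abs=1e-3)
        assert fit.n_points == len(SCHEDULE) - 1  # every post-Cmax point, tied R^2

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed):
        """Selection equals exhaustive search over all contiguous terminal subsets."""
        rng = np.random.default_rng(seed)
        ke = rng.uniform(0.1, 0.8)
        ka = ke * rng.uniform(2.0, 8.0)
        conc = bateman_profile(SCHEDULE, 5.0, ka, ke * 0.3, 0.3)
        conc *= np.exp(rng.normal(0.0, 0.12, conc.size))
        fit = select_lambda_z(_profile(SCHEDULE, conc))
        oracle = _brute_force_lambda(SCHEDULE, conc)
        assert fit.estimable and oracle is not None
        assert fit.lambda_z == pytest.approx(oracle[1], rel=1e-12)
        assert fit.n_points == oracle[2]

    def test_too_few_points_flagged_not_raised(self):
        fit = select_lambda_z(_profile([1.0, 2.0, 3.0], [100.0, 80.0, 60.0]))
        assert not fit.estimable and math.isnan(fit.lambda_z)

    def test_noise_free_control_tegafur_half_life_in_observed_range(self,
                                                                    control_params):
        profile = simulate(control_params, [DoseEvent(0, 5.0, Route.ORAL_TEGAFUR)],
                           SCHEDULE)
        fit = select_lambda_z(_profile(SCHEDULE, profile.tegafur))
        assert 2.2 - 1.4 <= fit.t_half <= 2.2 + 1.4


class TestComputeNCA:
    def test_triangle_auc(self):
        result = compute_nca(_profile([0.0, 1.0], [0.0, 100.0]))
        assert result.auc_all == pytest.approx(50.0)
        assert not result.lambda_estimable

    def test_noise_free_5fu_auc_inf_matches_closed_form(self, control_params):
        """NCA AUCinf at the study schedule (with LLOQ censoring) is within 5%
        of the analytic AUC; without censoring the sparse terminal trapezoids
        would overestimate the exponential tail."""
        profile = simulate(control_params, [DoseEvent(0, 5.0, Route.ORAL_TEGAFUR)],
                           SCHEDULE)
        blq = profile.fu < reference.LLOQ["5fu"]
        result = compute_nca(_profile(SCHEDULE, profile.fu, blq=blq,
                                      analyte=Analyte.FU))
        _, auc_fu = analytic_auc(control_params, 5.0)
        assert abs(result.auc_inf - auc_fu) / auc_fu < 0.05

    def test_auc_invariant_to_interpolated_point(self):
        times = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        conc = np.array([0.0, 100.0, 80.0, 40.0, 10.0])
        base = compute_nca(_profile(times, conc)).auc_all
        t2 = np.insert(times, 3, 3.0)
        c2 = np.insert(conc, 3, 60.0)  # on the straight segment 2 -> 4 h
        assert compute_nca(_profile(t2, c2)).auc_all == pytest.approx(base, rel=1e-12)

    def test_dense_monoexponential_auc_inf_converges_to_c0_over_lambda(self):
        t = np.linspace(0.0, 40.0, 16001)
        conc = 100.0 * np.exp(-0.35 * t)
        result = compute_nca(_profile(t, conc))
        assert result.auc_inf == pytest.approx(100.0 / 0.35, rel=1e-3)

    def test_blq_handling(self):
        """Leading predose BLQ becomes 0 at t=0; later BLQ points are dropped."""
        times = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0])
        conc = np.array([0.0, 200.0, 150.0, 90.0, 30.0, 8.0, 2.0])
        blq = np.array([1, 0, 0, 0, 0, 1, 1], dtype=bool)
        result = compute_nca(_profile(times, conc, blq=blq))
        expected = np.trapezoid([0.0, 200.0, 150.0, 90.0, 30.0],
                                [0.0, 0.5, 1.0, 2.0, 4.0])
        assert result.auc_all == pytest.approx(expected)

    def test_cl_and_vz_unit_consistency(self, control_params):
        """CL/F in mL/min/kg and Vz/F in L/kg reproduce the dose from AUCinf."""
        times = np.concatenate([SCHEDULE, [36.0, 48.0]])
        profile = simulate(control_params, [DoseEvent(0, 5.0, Route.ORAL_TEGAFUR)],
                           times)
        r = compute_nca(_profile(times, profile.tegafur))
        assert r.cl_f * 60.0 * r.auc_inf / 1e6 == pytest.approx(5.0, rel=1e-9)
        assert r.vz_f == pytest.approx(r.cl_f * 60.0 / r.lambda_z / 1000.0, rel=1e-9)

    def test_gimeracil_pretreated_cmax_matches_summary(self):
        p = GimeracilParams()
        conc = bateman_profile(SCHEDULE, reference.GIMERACIL_DOSE,
                               p.ka * p.ka_ratio, p.cl, p.v, f=p.f_ratio)
        r = compute_nca(_profile(SCHEDULE, conc, dose=reference.GIMERACIL_DOSE,
                                 analyte=Analyte.GIMERACIL))
        assert r.cmax == pytest.approx(142.3, rel=0.05)

    def test_deterministic_study_gives_identical_results_within_group(
            self, deterministic_study):
        table = nca_dataset(deterministic_study)
        for (_, _), sub in table.groupby(["analyte", "group"]):
            for col in ("cmax", "auc_all", "auc_inf", "lambda_z"):
                assert sub[col].nunique() == 1


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        t, p, sig = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9999 and not sig

    def test_degenerate_zero_variance(self):
        assert compare_groups([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0, False)
        t, p, sig = compare_groups([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0 and sig

    def test_p_value_matches_quadrature_oracle(self, rng):
        a = rng.normal(10.0, 2.0, 5)
        b = rng.normal(12.0, 2.0, 5)
        t_stat, p, _ = compare_groups(a, b)
        df = len(a) + len(b) - 2
        density = lambda x: stats.t.pdf(x, df)
        tail, _ = quad(density, abs(t_stat), np.inf)
        assert p == pytest.approx(2.0 * tail, rel=1e-6)

    def test_summary_equivalent_gimeracil_cmax_samples_significant(self, rng):
        """Samples matching the published gimeracil Cmax summary separate at 0.05."""

        def with_moments(mean, sd, n=5):
            z = rng.standard_normal(n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        control = with_moments(347.8, 42.7)
        pretreated = with_moments(142.3, 41.8)
        _, p, sig = compare_groups(control, pretreated)
        assert sig and p < 0.05

    def test_summary_table_stars_significant_rows(self, small_study):
        table = nca_dataset(small_study)
        summary = summarize_groups(table)
        starred = summary[summary.significant]
        assert np.all(starred.p_value < 0.05)
        assert all(s.endswith("*") for s in starred.pretreated)
        unstarred = summary[~summary.significant]
        assert not any(s.endswith("*") for s in unstarred.pretreated)
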