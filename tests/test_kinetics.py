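import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turnover import (
    DomainError,
    FitConfig,
    PeptideTimecourse,
    aggregate_protein,
    build_timecourses,
    fit_peptide,
    half_life_from_slope,
    median_turnover_curve,
    percent_old,
    run_pipeline,
)
from turnover.kinetics import FLAG_ABOVE, FLAG_BELOW, FLAG_RELIABLE

from conftest import make_obs


def ols_oracle(t, y):
    """Normal-equations least squares, independent of the fitting path."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    sx, sy = t.sum(), y.sum()
    sxx, sxy, syy = (t * t).sum(), (t * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return slope, intercept, r * r


def tc(points, protein="P1", peptide="AAAK"):
    return PeptideTimecourse(
        protein_id=protein,
        peptide_seq=peptide,
        timepoints=tuple(p[0] for p in points),
        percent_old=tuple(p[1] for p in points),
    )


class TestPercentOld:
    @pytest.mark.parametrize("ar, expected", [(0.0, 100.0), (1.0, 50.0), (3.0, 25.0)])
    def test_closed_form(self, ar, expected):
        assert percent_old(ar) == pytest.approx(expected)

    def test_rejects_negative_and_nonfinite(self):
        for bad in (-0.1, math.nan, math.inf):
            with pytest.raises(DomainError):
                percent_old(bad)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=100.0))
    def test_round_trip_through_area_ratio(self, p):
        """percent_old((100 - p)/p) recovers p: the transform inverts the ratio."""
        assert percent_old((100.0 - p) / p) == pytest.approx(p, rel=1e-9)

    def test_strictly_decreasing_in_ar(self):
        ars = np.linspace(0, 50, 200)
        values = percent_old(ars)
        assert np.all(np.diff(values) < 0)


class TestBuildTimecourses:
    def test_single_peptide_three_points(self):
        obs = [make_obs(t=float(t), ar=float(t)) for t in (0, 1, 2)]
        courses = build_timecourses(obs)
        assert len(courses) == 1
        assert courses[0].timepoints == (0.0, 1.0, 2.0)

    def test_duplicate_timepoint_collapsed_by_mean(self):
        # %old 60 and 40 at the same timepoint -> a single (1, 50) point
        ar_for_60 = (100 - 60) / 60
        ar_for_40 = (100 - 40) / 40
        # same peptide observed twice at t=1 (e.g. two charge states)
        obs = [
            make_obs(t=1.0, ar=ar_for_60),
            make_obs(t=1.0, ar=ar_for_40),
        ]
        courses = build_timecourses(obs)
        assert len(courses) == 1
        assert courses[0].percent_old[0] == pytest.approx(50.0)

    def test_two_peptides_two_timecourses_points_sorted(self):
        obs = [
            make_obs(peptide="AAAK", t=2.0, ar=1.0),
            make_obs(peptide="AAAK", t=0.0, ar=0.0),
            make_obs(peptide="CCCR", t=1.0, ar=1.0),
        ]
        courses = build_timecourses(obs)
        assert len(courses) == 2
        assert courses[0].timepoints == (0.0, 2.0)


class TestFitPeptide:
    def test_exact_halving_per_day(self):
        fit = fit_peptide(tc([(0, 100), (1, 50), (2, 25), (3, 12.5)]))
        assert fit.slope_k == pytest.approx(-math.log(2), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.passed

    def test_flat_line_fails_on_slope_sign(self):
        fit = fit_peptide(tc([(0, 80), (1, 80), (2, 80)]))
        assert fit.slope_k == pytest.approx(0.0, abs=1e-12)
        assert not fit.passed

    def test_matches_frozen_normal_equations_solution(self):
        # ln(%old) regressed on t for (0,100),(1,60),(2,30),(3,20); expected
        # values computed once with the normal-equations oracle above.
        fit = fit_peptide(tc([(0, 100), (1, 60), (2, 30), (3, 20)]))
        assert fit.slope_k == pytest.approx(-0.552146091786, abs=1e-10)
        assert fit.intercept_a == pytest.approx(4.602330238536, abs=1e-10)
        assert fit.r_squared == pytest.approx(0.991014915403, abs=1e-10)
        assert fit.passed

    def test_two_points_fit_but_fail_min_timepoints(self):
        fit = fit_peptide(tc([(0, 100), (1, 50)]))
        assert fit.slope_k == pytest.approx(-math.log(2))
        assert not fit.passed  # only 2 of the required 3 timepoints

    def test_single_point_marked_failed_with_undefined_slope(self):
        fit = fit_peptide(tc([(1, 50)]))
        assert not fit.passed and math.isnan(fit.slope_k)

    def test_ols_equivalence_on_random_timecourses(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 8))
            t = np.sort(rng.uniform(0, 5, size=n))
            t += np.arange(n) * 1e-3  # ensure strictly increasing
            p = rng.uniform(1, 100, size=n)
            fit = fit_peptide(tc(list(zip(t, p))))
            slope, intercept, r2 = ols_oracle(t, np.log(p))
            assert fit.slope_k == pytest.approx(slope, abs=1e-10)
            assert fit.intercept_a == pytest.approx(intercept, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_slope_invariant_under_positive_scaling(self, rng):
        """Scaling %old by a constant shifts the intercept, not the slope."""
        for _ in range(20):
            t = np.arange(4, dtype=float)
            p = rng.uniform(10, 100, size=4)
            base = fit_peptide(tc(list(zip(t, p))))
            scaled = fit_peptide(tc(list(zip(t, 0.37 * p))))
            assert scaled.slope_k == pytest.approx(base.slope_k, abs=1e-12)
            assert scaled.intercept_a == pytest.approx(
                base.intercept_a + math.log(0.37), abs=1e-12
            )

    def test_rejects_nonpositive_percent_old(self):
        with pytest.raises(DomainError):
            tc([(0, 0.0), (1, 50)])


class TestAggregateProtein:
    def test_single_fit_half_life_one_day(self):
        fit = fit_peptide(tc([(0, 100), (1, 50), (2, 25), (3, 12.5)]))
        result = aggregate_protein([fit])
        assert result.half_life_days == pytest.approx(1.0, abs=1e-12)
        assert result.sd_slope == 0.0 and result.sem_slope == 0.0
        assert result.n_peptides_used == 1
        assert result.precision_flag == FLAG_RELIABLE  # 1.0 is not < 1

    def test_mean_of_two_slopes(self):
        fits = [
            fit_peptide(tc([(t, 100 * math.exp(-0.2 * t)) for t in range(4)], peptide="A")),
            fit_peptide(tc([(t, 100 * math.exp(-0.4 * t)) for t in range(4)], peptide="B")),
        ]
        result = aggregate_protein(fits)
        assert result.mean_slope == pytest.approx(-0.3, abs=1e-12)
        # ln(2)/0.3, computed by hand
        assert result.half_life_days == pytest.approx(2.3104906018664844, abs=1e-10)
        assert result.sd_slope == pytest.approx(np.std([-0.2, -0.4], ddof=1), abs=1e-12)
        assert result.sem_slope == pytest.approx(result.sd_slope / math.sqrt(2))

    def test_no_passing_fits_returns_none(self):
        failing = fit_peptide(tc([(0, 80), (1, 80), (2, 80)]))
        assert aggregate_protein([failing]) is None

    @pytest.mark.parametrize(
        "true_halflife, flag",
        [(0.5, FLAG_BELOW), (1.5, FLAG_RELIABLE), (12.0, FLAG_ABOVE)],
    )
    def test_precision_window_flags(self, true_halflife, flag):
        k = -math.log(2) / true_halflife
        fit = fit_peptide(tc([(t, 100 * math.exp(k * t)) for t in range(4)]))
        assert aggregate_protein([fit]).precision_flag == flag

    def test_halflife_monotone_in_slope_magnitude(self):
        hl = [
            half_life_from_slope(k) for k in (-2.0, -1.0, -0.5, -0.25, -0.125)
        ]
        assert hl == sorted(hl)
        assert all(h > 0 for h in hl)


class TestRunPipeline:
    def test_noiseless_recovery_to_numerical_precision(self):
        truth = {}
        observations = []
        for i, half_life in enumerate(np.linspace(1, 8, 10)):
            protein = f"P{i}"
            truth[protein] = half_life
            k = -math.log(2) / half_life
            for pep in ("AAAK", "CCCR"):
                for t in range(4):
                    f = math.exp(k * t)
                    observations.append(
                        make_obs(protein=protein, peptide=pep, t=float(t),
                                 ar=(1 - f) / f)
                    )
        result = run_pipeline(observations)
        assert len(result.proteins) == 10
        for protein in result.proteins:
            assert protein.half_life_days == pytest.approx(
                truth[protein.protein_id], rel=1e-9
            )

    def test_all_profile_failures_yield_empty_results(self):
        observations = [
            make_obs(protein=f"P{i}", t=float(t), ar=1.0, profile=0.0)
            for i in range(3)
            for t in range(4)
        ]
        result = run_pipeline(observations)
        assert result.proteins == []
        assert result.qc_report.n_dropped_profile == result.qc_report.n_input == 12
        assert result.summary["n_proteins_with_halflife"] == 0

    def test_summary_counts_attrition_stages(self):
        observations = []
        # P_good: clean decay; P_short: only 2 timepoints; P_flat: no negative slope
        k = -math.log(2) / 2.0
        for t in range(4):
            f = math.exp(k * t)
            observations.append(make_obs(protein="P_good", t=float(t), ar=(1 - f) / f))
        for t in range(2):
            f = math.exp(k * t)
            observations.append(make_obs(protein="P_short", t=float(t), ar=(1 - f) / f))
        for t in range(4):
            observations.append(make_obs(protein="P_flat", t=float(t), ar=1.0))
        result = run_pipeline(observations)
        assert result.summary["n_proteins_min_timepoints"] == 2  # good + flat
        assert result.summary["n_proteins_with_halflife"] == 1
        assert result.summary["n_proteins_excluded_no_passing_fit"] == 1


class TestMedianTurnoverCurve:
    def test_identical_proteins_median_sd(self):
        courses = [
            tc([(1.0, 50.0)], protein=f"P{i}", peptide="AAAK") for i in range(5)
        ]
        curve = median_turnover_curve(courses)
        row = curve[curve.timepoint == 1.0].iloc[0]
        assert row.median_percent_old == 50.0 and row.sd_percent_old == 0.0

    def test_median_of_three_proteins(self):
        values = {"P1": 40.0, "P2": 50.0, "P3": 90.0}
        courses = [
            tc([(2.0, v)], protein=p, peptide="AAAK") for p, v in values.items()
        ]
        curve = median_turnover_curve(courses)
        assert curve[curve.timepoint == 2.0].iloc[0].median_percent_old == 50.0

    def test_matches_brute_force_recomputation(self, rng):
        """Direct recomputation over the protein x timepoint matrix."""
        courses = []
        per_protein = {}
        for i in range(12):
            protein = f"P{i}"
            for j in range(3):
                points = [(float(t), float(rng.uniform(5, 100))) for t in range(4)]
                courses.append(tc(points, protein=protein, peptide=f"PEP{j}K"))
                for t, p in points:
                    per_protein.setdefault((protein, t), []).append(p)
        curve = median_turnover_curve(courses).set_index("timepoint")
        for t in (0.0, 1.0, 2.0, 3.0):
            protein_means = [
                np.mean(vals) for (p, tt), vals in per_protein.items() if tt == t
            ]
            assert curve.loc[t, "median_percent_old"] == pytest.approx(
                np.median(protein_means)
            )
            assert curve.loc[t, "sd_percent_old"] == pytest.approx(
                np.std(protein_means)
            )
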