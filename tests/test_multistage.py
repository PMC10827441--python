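import math

import numpy as np
import pytest
from scipy import optimize

from caninecancer.io_datasets import BreedRecord, DatasetTable
from caninecancer.lifespan import DEFAULT_LIFESPAN
from caninecancer.multistage import (
    CrossSpeciesParams,
    aic,
    design_matrix,
    division_rate,
    fit_fixed_powers,
    predict,
    solve_cross_species,
    stepwise_select,
)


def _table_from(w, p, source="t"):
    return DatasetTable(
        source, [BreedRecord(f"b{i}", float(wi), float(pi)) for i, (wi, pi) in enumerate(zip(w, p))]
    )


class TestDesignMatrix:
    def test_single_entry_arithmetic(self):
        X = design_matrix([30.0], [10.9], [4])
        assert X[0, 0] == pytest.approx(30 * 10.9**4)

    def test_unit_lifespan_columns_equal_weight(self):
        w = np.array([3.0, 7.0, 11.0])
        X = design_matrix(w, np.ones(3), [2, 3, 4, 5, 6])
        for j in range(5):
            assert X[:, j] == pytest.approx(w)

    def test_column_ratio_is_lifespan(self):
        w = np.array([3.0, 7.0])
        t = np.array([12.0, 9.5])
        X = design_matrix(w, t, [2, 3])
        assert X[:, 1] / X[:, 0] == pytest.approx(t)

    def test_empty_powers_errors(self):
        with pytest.raises(ValueError):
            design_matrix([1.0], [1.0], [])


class TestAic:
    def test_direct_arithmetic(self):
        assert aic(1.0, 10, 1) == pytest.approx(10 * math.log(0.1) + 4)

    def test_doubling_rss_shifts_by_n_log2(self):
        assert aic(2.0, 20, 2) - aic(1.0, 20, 2) == pytest.approx(20 * math.log(2))

    def test_delta_aic_invariant_to_response_rescaling(self, noiseless_m4_table, lifespan_model):
        rng = np.random.default_rng(5)
        w = noiseless_m4_table.weights()
        t = lifespan_model.predict(w)
        p = 7.84e-7 * w * t**4 + rng.normal(0, 0.02, size=w.size)
        p = np.clip(p, 0, 1)
        for c in (1.0, 0.5):
            tab = _table_from(w, c * p)
            f3 = fit_fixed_powers(tab, lifespan_model, (3,))
            f4 = fit_fixed_powers(tab, lifespan_model, (4,))
            if c == 1.0:
                base = f3.aic - f4.aic
        assert f3.aic - f4.aic == pytest.approx(base, abs=1e-9)

    def test_perfect_fit_is_minus_inf_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert aic(0.0, 10, 1) == -math.inf


class TestFitFixedPowers:
    def test_noiseless_single_power_recovery(self, noiseless_m4_table, lifespan_model):
        fit = fit_fixed_powers(noiseless_m4_table, lifespan_model, (4,))
        assert fit.coefficients[4].estimate == pytest.approx(7.84e-7, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_nested_fit_zeroes_redundant_term(self, noiseless_m4_table, lifespan_model):
        fit = fit_fixed_powers(noiseless_m4_table, lifespan_model, (3, 4))
        assert fit.coefficients[4].estimate == pytest.approx(7.84e-7, rel=1e-8)
        assert abs(fit.coefficients[3].estimate) < 1e-12

    def test_direct_solution_equals_iterative_minimum(self, lifespan_model, default_panel):
        # the model is linear in the A_m: Levenberg-Marquardt from zeros must
        # land on the direct linear solution
        table, _ = default_panel
        w = table.weights()
        y = table.mortalities()
        t = lifespan_model.predict(w)
        for powers in [(4,), (3, 4), (2, 3, 4)]:
            fit = fit_fixed_powers(table, lifespan_model, powers)
            X = design_matrix(w, t, powers)
            res = optimize.least_squares(
                lambda beta: X @ beta - y, x0=np.zeros(len(powers)), method="lm"
            )
            rss_iter = float(np.sum(res.fun**2))
            assert rss_iter == pytest.approx(fit.rss, rel=1e-9)

    def test_adding_power_never_increases_rss(self, lifespan_model, default_panel):
        table, _ = default_panel
        prev = np.inf
        for powers in [(4,), (3, 4), (3, 4, 5)]:
            rss = fit_fixed_powers(table, lifespan_model, powers).rss
            assert rss <= prev + 1e-15
            prev = rss

    def test_scale_equivariance_in_weight(self, lifespan_model, default_panel):
        # with lifespans held fixed, scaling W by c scales each A_m by 1/c
        table, _ = default_panel
        t = lifespan_model.predict(table.weights())
        fit1 = fit_fixed_powers(table, lifespan_model, (3, 4), lifespans=t)
        c = 3.0
        scaled = DatasetTable(
            "scaled",
            [
                BreedRecord(r.breed_name, r.weight_kg * c, r.cancer_mortality)
                for r in table
            ],
        )
        fit2 = fit_fixed_powers(scaled, lifespan_model, (3, 4), lifespans=t)
        for m in (3, 4):
            assert fit2.coefficients[m].estimate == pytest.approx(
                fit1.coefficients[m].estimate / c, rel=1e-9
            )

    def test_too_few_breeds(self, lifespan_model):
        t = _table_from([5, 10], [0.1, 0.2])
        with pytest.raises(ValueError):
            fit_fixed_powers(t, lifespan_model, (4,))


class TestStepwise:
    def test_noiseless_m3_identified_exactly(self, lifespan_model):
        rng = np.random.default_rng(2)
        w = np.sort(rng.uniform(2, 60, size=30))
        t = lifespan_model.predict(w)
        table = _table_from(w, 5e-5 * w * t**3)
        report = stepwise_select(table, lifespan_model)
        assert report.best.powers == (3,)
        row4 = report.row((4,))
        assert row4 is not None and row4 not in report.equivalent_set

    def test_synthetic_default_selects_m4(self, lifespan_model, default_panel):
        table, _ = default_panel
        report = stepwise_select(table, lifespan_model)
        assert report.best.powers == (4,)
        assert report.best.admissible

    def test_report_contains_all_nine_candidate_rows(self, lifespan_model, default_panel):
        table, _ = default_panel
        report = stepwise_select(table, lifespan_model)
        keys = {c.powers for c in report.candidates}
        singles = {(m,) for m in (2, 3, 4, 5, 6)}
        pairs = {(m, m + 1) for m in (2, 3, 4, 5)}
        assert singles | pairs <= keys

    def test_delta_aic_reference_is_single_power_four(self, lifespan_model, default_panel):
        table, _ = default_panel
        report = stepwise_select(table, lifespan_model)
        assert report.reference_powers == (4,)
        assert report.row((4,)).delta_aic == pytest.approx(0.0)


class TestPredict:
    def test_direct_arithmetic(self, noiseless_m4_table, lifespan_model):
        fit = fit_fixed_powers(noiseless_m4_table, lifespan_model, (4,))
        assert predict(fit, lifespan_model, 30.0) == pytest.approx(
            7.84e-7 * 30 * 10.9**4, rel=1e-9
        )

    def test_vanishes_with_weight(self, noiseless_m4_table, lifespan_model):
        # proportionality to W: prediction at W scales linearly near zero
        fit = fit_fixed_powers(noiseless_m4_table, lifespan_model, (4,))
        p1 = predict(fit, lifespan_model, 1e-6)
        p2 = predict(fit, lifespan_model, 2e-6)
        assert p1 == pytest.approx(0.0, abs=1e-7)
        assert p2 == pytest.approx(2 * p1, rel=1e-4)

    def test_unimodal_over_weight_domain(self, noiseless_m4_table, lifespan_model):
        fit = fit_fixed_powers(noiseless_m4_table, lifespan_model, (4,))
        grid = np.linspace(0.5, lifespan_model.max_weight - 0.5, 400)
        vals = predict(fit, lifespan_model, grid)
        diffs = np.sign(np.diff(vals))
        # one sign change at most: rises then falls
        changes = np.sum(np.diff(diffs[diffs != 0]) != 0)
        assert changes <= 1


class TestCrossSpecies:
    def test_reference_parameterisation(self):
        uk = solve_cross_species(CrossSpeciesParams(2, 5, 10, 5, 4))
        assert uk == pytest.approx(1.6e-5, rel=1e-12)

    def test_symmetric_species_reduce_to_reciprocal_lifespan(self):
        for t in (1.0, 7.0, 12.0):
            uk = solve_cross_species(CrossSpeciesParams(1, 1, t, 5, 4))
            assert uk == pytest.approx(1.0 / t)

    def test_matches_bisection_root_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            params = CrossSpeciesParams(
                cell_ratio=rng.uniform(0.5, 5),
                lifespan_ratio=rng.uniform(1.1, 8),
                t_low=rng.uniform(2, 30),
                m_high=int(rng.integers(3, 7)),
                m_low=int(rng.integers(1, 3)),
            )
            closed = solve_cross_species(params)

            def log_gap(log_uk, p=params):
                uk = math.exp(log_uk)
                high = math.log(p.cell_ratio) + p.m_high * math.log(
                    uk * p.lifespan_ratio * p.t_low
                )
                low = p.m_low * math.log(uk * p.t_low)
                return high - low

            root = optimize.brentq(log_gap, -60, 10)
            assert closed == pytest.approx(math.exp(root), rel=1e-10)

    def test_equal_driver_counts_unsolvable(self):
        with pytest.raises(ValueError):
            CrossSpeciesParams(2, 5, 10, 4, 4)


class TestDivisionRate:
    def test_reference_values(self):
        k, days = division_rate(1.6e-5, 1e-6)
        assert k == pytest.approx(16.0)
        assert days == 23

    def test_identity_rate(self):
        k, days = division_rate(1e-6, 1e-6)
        assert k == pytest.approx(1.0)
        assert days == 365

    def test_scaling_consistency(self):
        uk = solve_cross_species(CrossSpeciesParams(2, 5, 10, 5, 4))
        k1, _ = division_rate(uk, 1e-6)
        k2, _ = division_rate(uk, 2e-6)
        assert k1 == pytest.approx(2 * k2)
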