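import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logit

from migcube.age_structures import (
    AgeGrouping,
    ExposureCurve,
    GroupedMigrationTable,
)
from migcube.outmigration import _irls, fit_topals, select_penalty
from migcube.ratios import (
    BinomialRatioModel,
    assemble_cube,
    conditional_to_ratios,
    conditional_weight_matrix,
    fit_conditional_ratio,
    fit_conditional_ratios,
    ratios_to_conditional,
    risk_counts,
)
from migcube.splines import BasisSpec
from migcube.synthetic import default_scenario, make_true_cube, sample_counts

from conftest import random_contiguous_grouping


class TestConditionalDecomposition:
    def test_two_destinations(self):
        c = np.array([[0.3, 0.7]])
        a = ratios_to_conditional(c)
        assert a[0, 0] == pytest.approx(0.3)
        assert a[0, 1] == 1.0

    def test_three_destinations_hand_arithmetic(self):
        c = np.array([[0.2, 0.3, 0.5]])
        a = ratios_to_conditional(c)
        assert a[0, 0] == pytest.approx(0.2)
        assert a[0, 1] == pytest.approx(0.375)
        # the last ratio is the survival product 0.8 * 0.625
        assert 0.8 * 0.625 == pytest.approx(0.5)
        np.testing.assert_allclose(conditional_to_ratios(a), c, atol=1e-15)

    def test_round_trip_random(self, rng):
        c = rng.dirichlet(np.ones(5), size=40)
        back = conditional_to_ratios(ratios_to_conditional(c))
        np.testing.assert_allclose(back, c, atol=1e-12)

    def test_unreached_branch(self):
        # first destination takes everything: later branches are unreached
        c = np.array([[1.0, 0.0, 0.0]])
        a = ratios_to_conditional(c)
        assert a[0, 0] == 1.0 and a[0, 1] == 0.0

    def test_bad_column_sums_rejected(self):
        with pytest.raises(ValueError):
            ratios_to_conditional(np.array([[0.5, 0.4]]))


class TestRiskCounts:
    def test_cumulative_from_last(self):
        grouping = AgeGrouping(((0, 10),), omega=9)
        table = GroupedMigrationTable(
            grouping, np.array([[10.0, 20.0, 30.0]]), np.array([100.0]), 1
        )
        np.testing.assert_array_equal(risk_counts(table), [[60.0, 50.0, 30.0]])

    def test_single_destination_is_movers(self):
        grouping = AgeGrouping(((0, 5),), omega=4)
        table = GroupedMigrationTable(
            grouping, np.array([[7.0]]), np.array([50.0]), 1
        )
        np.testing.assert_array_equal(risk_counts(table), table.movers)

    def test_zero_movers(self):
        grouping = AgeGrouping(((0, 5),), omega=4)
        table = GroupedMigrationTable(
            grouping, np.zeros((1, 3)), np.array([50.0]), 1
        )
        assert risk_counts(table).sum() == 0


class TestConditionalWeights:
    def test_single_year_indicators(self):
        grouping = AgeGrouping.single_year(omega=4)
        table = GroupedMigrationTable(
            grouping, np.ones((5, 2)), np.full(5, 10.0), 1
        )
        T = conditional_weight_matrix(
            0, table, ExposureCurve(np.full(5, 10.0)), np.full(5, 0.1)
        )
        np.testing.assert_allclose(T, np.eye(5))

    def test_constant_risk_equal_weights(self):
        grouping = AgeGrouping(((0, 5),), omega=4)
        table = GroupedMigrationTable(
            grouping, np.ones((1, 2)), np.array([50.0]), 1
        )
        T = conditional_weight_matrix(
            0, table, ExposureCurve(np.full(5, 10.0)), np.full(5, 0.2)
        )
        np.testing.assert_allclose(T[0], np.full(5, 0.2))

    def test_exposure_doubling(self):
        grouping = AgeGrouping(((0, 2),), omega=1)
        table = GroupedMigrationTable(
            grouping, np.ones((1, 2)), np.array([3.0]), 1
        )
        T = conditional_weight_matrix(
            0, table, ExposureCurve(np.array([1.0, 2.0])), np.full(2, 0.1)
        )
        np.testing.assert_allclose(T[0], [1 / 3, 2 / 3])

    def test_zero_risk_uniform_fallback(self):
        grouping = AgeGrouping(((0, 4),), omega=3)
        table = GroupedMigrationTable(
            grouping, np.ones((1, 2)), np.array([8.0]), 1
        )
        T = conditional_weight_matrix(
            0, table, ExposureCurve(np.full(4, 2.0)), np.zeros(4)
        )
        np.testing.assert_allclose(T[0], np.full(4, 0.25))


class TestFitConditionalRatio:
    def test_constant_truth_exact_for_any_lambda(self, small_basis):
        # noise-free grouped ratios from a constant truth: constants are
        # penalty-free and likelihood-optimal, so the fit is exact
        omega = 29
        grouping = AgeGrouping(((0, 10), (10, 10), (20, 10)), omega=omega)
        K = np.array([200.0, 300.0, 150.0])
        a_true = 0.3
        y = K * a_true
        movers = np.column_stack([y, K - y])
        table = GroupedMigrationTable(grouping, movers, np.full(3, 1e4), 1)
        mask = grouping.age_mask().astype(float)
        T = mask / mask.sum(1, keepdims=True)
        for lam in (0.01, 1e4):
            fit = fit_conditional_ratio(
                0, table, T, basis_spec=small_basis, lam=lam
            )
            np.testing.assert_allclose(fit.a, a_true, rtol=1e-6)

    def test_balanced_data_logit_zero(self, small_basis):
        omega = 29
        grouping = AgeGrouping(((0, 15), (15, 15)), omega=omega)
        movers = np.array([[50.0, 50.0], [80.0, 80.0]])
        table = GroupedMigrationTable(grouping, movers, np.full(2, 1e3), 1)
        mask = grouping.age_mask().astype(float)
        T = mask / mask.sum(1, keepdims=True)
        fit = fit_conditional_ratio(0, table, T, basis_spec=small_basis, lam=1e8)
        np.testing.assert_allclose(logit(fit.a), 0.0, atol=1e-4)

    def test_oracle_equivalence(self, rng, small_basis):
        for _ in range(5):
            omega = 29
            grouping = random_contiguous_grouping(rng, omega=omega)
            g = grouping.n_groups
            K = rng.integers(50, 500, size=g).astype(float)
            y = np.round(K * rng.uniform(0.1, 0.9, size=g))
            mask = grouping.age_mask().astype(float)
            T = mask / mask.sum(1, keepdims=True)
            lam = float(10 ** rng.uniform(-1, 2))
            model = BinomialRatioModel(K, y, T, small_basis, 1)
            phi, _, _, _ = _irls(model, lam, None, 200, 1e-12)
            sol = minimize(
                lambda p: -model.penalized_loglik(p, lam),
                model.default_start(),
                jac=lambda p: -model.gradient(p, lam),
                method="BFGS",
                options=dict(gtol=1e-11, maxiter=5000),
            )
            assert abs(model.penalized_loglik(phi, lam) + sol.fun) < 1e-8
            assert np.max(np.abs(phi - sol.x)) < 1e-5

    def test_all_zero_risk_fallback(self, small_basis):
        grouping = AgeGrouping(((0, 30),), omega=29)
        table = GroupedMigrationTable(
            grouping, np.zeros((1, 3)), np.array([100.0]), 1
        )
        mask = grouping.age_mask().astype(float)
        T = mask / mask.sum(1, keepdims=True)
        fit = fit_conditional_ratio(0, table, T, basis_spec=small_basis)
        assert fit.fallback
        np.testing.assert_allclose(fit.a, 1.0 / 3.0)


@pytest.fixture(scope="module")
def fitted():
    scenario = default_scenario(
        seed=5, n_origins=2, n_destinations=3, exposure_per_age=1e5
    )
    truth = make_true_cube(scenario)
    tables = sample_counts(scenario)
    out_fits, ratio_sets = {}, {}
    for origin, table in tables.items():
        _, fit = select_penalty(
            table.totals_only(), criterion="BIC",
            lambda_grid=np.logspace(-2, 8, 11),
        )
        rs = fit_conditional_ratios(
            table, fit, lambda_grid=np.logspace(-2, 8, 11)
        )
        out_fits[origin], ratio_sets[origin] = fit, rs
    cube = assemble_cube(out_fits, ratio_sets, scenario.interval_n)
    return scenario, truth, tables, out_fits, cube


class TestCubeAssembly:
    def test_ratio_columns_sum_to_one(self, fitted):
        _, _, _, _, cube = fitted
        np.testing.assert_allclose(cube.ratios.sum(axis=2), 1.0, atol=1e-12)

    def test_probabilities_factorise(self, fitted):
        _, _, _, out_fits, cube = fitted
        for o, origin in enumerate(cube.origin_labels):
            np.testing.assert_allclose(
                cube.probabilities[o].sum(axis=0),
                out_fits[origin].fitted_nyr,
                atol=1e-12,
            )

    def test_large_sample_recovery(self, fitted):
        scenario, truth, _, _, cube = fitted
        for origin in scenario.origins:
            sl = cube.slice(origin)
            true_dest = truth.nyr_dest[origin]
            sel = true_dest > 1e-3
            rel = np.abs(sl[sel] / true_dest[sel] - 1)
            assert np.median(rel) < 0.05

    def test_label_mismatch_rejected(self, fitted):
        _, _, _, out_fits, cube = fitted
        with pytest.raises(ValueError):
            assemble_cube(out_fits, {"bogus": None}, 5)

    def test_single_destination_cube_is_outmigration(self, small_basis):
        grouping = AgeGrouping(((0, 10), (10, 20)), omega=29)
        table = GroupedMigrationTable(
            grouping, np.array([[30.0], [20.0]]), np.array([500.0, 400.0]), 1
        )
        fit = fit_topals(table, basis_spec=small_basis, lam=1.0)
        rs = fit_conditional_ratios(table, fit, basis_spec=small_basis)
        cube = assemble_cube({table.origin_label: fit}, {table.origin_label: rs}, 1)
        np.testing.assert_allclose(cube.probabilities[0, 0], fit.fitted_nyr)

    def test_destination_order_closeness(self, fitted):
        # the decomposition is order-dependent; on large samples the cubes
        # from two orders must agree closely in shape (not identically)
        scenario, _, tables, out_fits, cube = fitted
        origin = scenario.origins[0]
        table = tables[origin]
        rs_rev = fit_conditional_ratios(
            table, out_fits[origin], order="by_movers",
            lambda_grid=np.logspace(-2, 8, 11),
        )
        from migcube.metrics import shape_deviation

        sl = cube.slice(origin)
        dest_rev = out_fits[origin].fitted_nyr[:, None] * rs_rev.ratios()
        for j in range(sl.shape[1]):
            assert shape_deviation(sl[:, j], dest_rev[:, j]) < 1.0
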