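import numpy as np
import pytest
from scipy.optimize import minimize

from migcube.age_structures import (
    AgeGrouping,
    ExposureCurve,
    GroupedMigrationTable,
    compose_multi_year,
    weight_matrix,
)
from migcube.outmigration import (
    PoissonTopalsModel,
    fit_topals,
    information_criterion,
    select_penalty,
)
from migcube.splines import BasisSpec

from conftest import random_total_table


def smooth_truth(omega, level=0.003, peak=0.05, mu=22.0, width=8.0):
    x = np.arange(omega + 1)
    return level + peak * np.exp(-0.5 * ((x - mu) / width) ** 2)


def noise_free_table(m_true, grouping, n, exposure=1e6):
    """Grouped counts exactly equal to their expectation under the truth."""
    omega = grouping.omega
    curve = ExposureCurve(np.full(omega + 1, float(exposure)))
    w = weight_matrix(curve, grouping)
    nm = compose_multi_year(m_true, n)
    exposures = grouping.age_mask() @ curve.values
    movers = exposures * (w @ nm)
    return GroupedMigrationTable(grouping, movers[:, None], exposures, n)


class TestPenalizedLoglik:
    def test_worked_value(self):
        # one age, one group, constant model probability 0.25
        grouping = AgeGrouping.single_year(omega=0)
        table = GroupedMigrationTable(
            grouping, np.array([[20.0]]), np.array([100.0]), 1
        )
        spec = BasisSpec(knot_start=0, knot_end=2, knot_spacing=1.0, degree=0)
        model = PoissonTopalsModel(table, basis_spec=spec)
        theta = np.full(model.l, np.log(0.25))
        expected = 100.0 * (0.2 * np.log(0.25) - 0.25)
        assert model.penalized_loglik(theta, lam=0.0) == pytest.approx(expected)

    def test_constant_theta_penalty_free(self, rng, small_basis):
        table = random_total_table(rng)
        model = PoissonTopalsModel(table, basis_spec=small_basis)
        theta = np.full(model.l, -2.0)
        assert model.penalized_loglik(theta, 1e6) == pytest.approx(
            model.loglik(theta)
        )

    def test_likelihood_maximal_at_sample_probs(self, rng, small_basis):
        # the Poisson kernel N (p log q - q) is maximised over q at q = p
        table = random_total_table(rng, n_max=1)
        model = PoissonTopalsModel(table, basis_spec=small_basis)

        def kernel(q):
            return float(np.sum(table.exposures * (model.mtilde * np.log(q) - q)))

        at_sample = kernel(np.clip(model.mtilde, 1e-12, None))
        for _ in range(20):
            q = np.clip(model.mtilde * rng.uniform(0.5, 1.5, model.g), 1e-12, 1)
            assert kernel(q) <= at_sample + 1e-12


class TestFitTopals:
    def test_self_consistency_standard_equals_truth(self):
        omega = 60
        m_true = smooth_truth(omega)
        grouping = AgeGrouping(tuple((a, 5) for a in range(0, 60, 5)), omega=omega)
        table = noise_free_table(m_true, grouping, n=5)
        spec = BasisSpec(knot_start=0, knot_end=70, knot_spacing=2.5, degree=2)
        for lam in (0.1, 100.0):
            fit = fit_topals(table, standard=m_true, basis_spec=spec, lam=lam)
            np.testing.assert_allclose(fit.fitted_m, m_true, rtol=1e-5)

    def test_interpolation_limit_single_year(self, rng):
        omega = 60
        m_true = smooth_truth(omega)
        grouping = AgeGrouping.single_year(omega)
        N = np.full(omega + 1, 20000.0)
        M = rng.binomial(20000, m_true).astype(float)
        table = GroupedMigrationTable(grouping, M[:, None], N, 1)
        spec = BasisSpec(knot_start=0, knot_end=70, knot_spacing=1.0, degree=2)
        fit = fit_topals(table, basis_spec=spec, lam=1e-6)
        err = np.abs(fit.fitted_grouped - table.sample_out_probs)[M > 0]
        assert err.max() < 1e-3

    def test_oracle_equivalence_small_instances(self, rng, small_basis):
        for _ in range(5):
            table = random_total_table(rng)
            lam = float(10 ** rng.uniform(-1, 2))
            fit = fit_topals(table, basis_spec=small_basis, lam=lam, tol=1e-12)
            model = PoissonTopalsModel(table, basis_spec=small_basis)
            sol = minimize(
                lambda th: -model.penalized_loglik(th, lam),
                model.default_start(),
                jac=lambda th: -model.gradient(th, lam),
                method="BFGS",
                options=dict(gtol=1e-11, maxiter=5000),
            )
            assert abs(model.penalized_loglik(fit.theta, lam) + sol.fun) < 1e-8
            assert np.max(np.abs(fit.theta - sol.x)) < 1e-5

    def test_all_zero_movers_degenerate(self, small_basis):
        grouping = AgeGrouping(((0, 10), (10, 20)), omega=29)
        table = GroupedMigrationTable(
            grouping, np.zeros((2, 1)), np.array([100.0, 100.0]), 1
        )
        fit = fit_topals(table, basis_spec=small_basis, lam=1.0)
        assert fit.degenerate and not fit.converged
        assert np.all(fit.fitted_m < 1e-6)


class TestEffectiveDimension:
    def test_limits_and_monotonicity(self, rng):
        # single-year groups so the unpenalized fit is identifiable; the age
        # grid must reach into the support of every basis column
        omega = 49
        m_true = smooth_truth(omega)
        grouping = AgeGrouping.single_year(omega)
        N = np.full(omega + 1, 50000.0)
        M = np.round(N * m_true)
        table = GroupedMigrationTable(grouping, M[:, None], N, 1)
        spec = BasisSpec(knot_start=0, knot_end=50, knot_spacing=10.0, degree=2)
        l = spec.n_basis
        edfs = []
        theta = None
        for lam in [1e-8, 1e-2, 1, 1e2, 1e4, 1e8, 1e12]:
            fit = fit_topals(table, basis_spec=spec, lam=lam, theta0=theta)
            theta = fit.theta
            edfs.append(fit.edf)
        assert edfs[0] == pytest.approx(l, abs=1e-3)  # unpenalized limit
        assert edfs[-1] == pytest.approx(1.0, abs=1e-3)  # constant-fit limit, k=1
        assert all(a >= b - 1e-6 for a, b in zip(edfs, edfs[1:]))
        assert all(1 - 1e-6 <= e <= l + 1e-6 for e in edfs)


class TestSelectPenalty:
    def test_singleton_grid(self, rng, small_basis):
        table = random_total_table(rng)
        lam, fit = select_penalty(
            table, basis_spec=small_basis, criterion="BIC", lambda_grid=[3.7]
        )
        assert lam == 3.7 and fit.lam == 3.7

    def test_bic_recomputed_by_hand(self, rng, small_basis):
        table = random_total_table(rng)
        lam, fit = select_penalty(
            table,
            basis_spec=small_basis,
            criterion="BIC",
            lambda_grid=np.logspace(-1, 4, 11),
        )
        by_hand = -2.0 * fit.loglik + np.log(table.grouping.n_groups) * fit.edf
        assert fit.criterion_value == pytest.approx(by_hand, rel=1e-12)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            information_criterion(0.0, 1.0, 5, "HQC")

    def test_heavier_noise_selects_fewer_effective_parameters(self):
        # the criterion adapts to sampling noise: heavier noise (smaller
        # exposed population) leads to stronger smoothing, i.e. a lower
        # selected effective dimension
        omega = 60
        m_true = smooth_truth(omega)
        grouping = AgeGrouping.single_year(omega)
        spec = BasisSpec(knot_start=0, knot_end=70, knot_spacing=2.5, degree=2)
        grid = np.logspace(-2, 6, 17)
        rng = np.random.default_rng(99)
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            edfs = {}
            for exposure in (150, 15000):
                pop = np.full(omega + 1, exposure)
                movers = rng.binomial(pop, m_true)
                table = GroupedMigrationTable(
                    grouping, movers[:, None].astype(float), pop.astype(float), 1
                )
                _, fit = select_penalty(
                    table, basis_spec=spec, criterion="AIC", lambda_grid=grid
                )
                edfs[exposure] = fit.edf
            wins += edfs[150] <= edfs[15000]
        assert wins >= 0.8 * n_rep
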