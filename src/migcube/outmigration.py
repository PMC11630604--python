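"""Penalized relational (P-TOPALS) estimation of out-migration schedules.

The complete one-year out-migration schedule m is represented relative to a
positive standard schedule m_hat,

    m = m_hat * exp(B theta),

with B a B-spline basis over single years of age and theta the spline
weights.  The grouped interval-n model probabilities follow from the
survival-product composition and the exposure weight matrix, and theta is
chosen to maximise a penalized Poisson log-likelihood of the grouped mover
counts,

    L(theta) = sum_i N_i (mtilde_i log M_i(theta) - M_i(theta))
               - (lambda/2) theta' D_k' D_k theta,

where mtilde are grouped sample probabilities and D_k is the k-th order
difference matrix.  Maximisation uses Fisher scoring (iterated penalized
weighted regressions) with step halving; the penalty size lambda is chosen
on a grid by an information criterion (AIC, AICc or BIC) using the
effective dimension (trace of the influence matrix) as the parameter
count.

For small penalties the fit approaches an interpolation of the sample
probabilities (when the knot spacing is finer than the age grouping); for
large penalties the spline component B theta approaches a polynomial of
order k - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .age_structures import (
    AgeGrouping,
    ExposureCurve,
    GroupedMigrationTable,
    compose_multi_year,
    expand_exposure,
    survival_window_matrix,
    weight_matrix,
)
from .splines import BasisSpec, bspline_basis, penalty_matrix

_PCLIP = 1e-12
DEFAULT_LAMBDA_GRID = np.logspace(-2, 8, 41)


def flat_standard(omega: int = 110) -> np.ndarray:
    """The flat standard schedule m_hat = 1."""
    return np.ones(omega + 1)


@dataclass
class TopalsFit:
    """Result of a penalized relational fit.

    ``fitted_m`` is the complete one-year schedule ``m_hat * exp(B theta)``
    (clipped to (0, 1]); ``fitted_grouped`` the grouped interval-n model
    probabilities.  ``edf`` is the effective dimension at the chosen
    penalty, and ``criterion_value`` the information-criterion value when
    the penalty was selected automatically.
    """

    theta: np.ndarray
    lam: float
    standard: np.ndarray
    fitted_m: np.ndarray
    fitted_nyr: np.ndarray
    fitted_grouped: np.ndarray
    loglik: float
    edf: float
    converged: bool
    iterations: int
    criterion_value: float | None = None
    criterion: str | None = None
    degenerate: bool = False


class PoissonTopalsModel:
    """The grouped Poisson likelihood of a relational spline schedule.

    Bundles the data (one origin's grouped total movers and exposures), the
    standard, the basis evaluated on ages 0..omega, the exposure weight
    matrix and the penalty kernel, and exposes the likelihood, gradient and
    Fisher information used by the solver.
    """

    def __init__(
        self,
        table: GroupedMigrationTable,
        standard: np.ndarray | None = None,
        basis_spec: BasisSpec = BasisSpec(),
        penalty_order: int = 1,
        exposure: ExposureCurve | None = None,
    ) -> None:
        self.table = table
        self.grouping = table.grouping
        omega = self.grouping.omega
        self.omega = omega
        self.n = table.interval_n
        self.standard = (
            flat_standard(omega) if standard is None else np.asarray(standard, float)
        )
        if np.any(self.standard <= 0):
            raise ValueError("standard schedule must be strictly positive")
        if len(self.standard) != omega + 1:
            raise ValueError("standard length must be omega + 1")
        self.B = bspline_basis(np.arange(omega + 1, dtype=float), basis_spec)
        self.l = self.B.shape[1]
        self.penalty_order = penalty_order
        self.P = penalty_matrix(self.l, penalty_order)
        self.S = survival_window_matrix(omega, self.n)
        if exposure is None:
            exposure = expand_exposure(table.exposures, self.grouping)
        self.exposure = exposure
        self.w = weight_matrix(exposure, self.grouping)
        self.N = table.exposures
        self.y = table.total_movers
        self.mtilde = self.y / self.N
        self.g = self.grouping.n_groups

    # -- model curves ------------------------------------------------------

    def default_start(self) -> np.ndarray:
        """Constant theta matching the pooled crude implied one-year level.

        Starting the iteration at the crude level keeps the schedule far
        from the probability bounds, where the relational parameterisation
        is ill-conditioned.
        """
        p_nyr = np.clip(self.y.sum() / self.N.sum(), 1e-10, 1 - 1e-10)
        m_one = 1.0 - (1.0 - p_nyr) ** (1.0 / self.n)
        level = np.log(m_one) - np.mean(np.log(self.standard))
        return np.full(self.l, level)

    def curves(self, theta: np.ndarray):
        """One-year schedule, composed schedule and grouped probabilities."""
        m = self.standard * np.exp(np.clip(self.B @ theta, -300.0, 300.0))
        m = np.clip(m, _PCLIP, 1 - _PCLIP)
        nm = np.clip(compose_multi_year(m, self.n), _PCLIP, 1 - _PCLIP)
        M = np.clip(self.w @ nm, _PCLIP, 1 - _PCLIP)
        return m, nm, M

    def loglik(self, theta: np.ndarray) -> float:
        """Poisson log-likelihood term of Eq-style grouped counts (no penalty)."""
        _, _, M = self.curves(theta)
        return float(np.sum(self.N * (self.mtilde * np.log(M) - M)))

    def penalized_loglik(self, theta: np.ndarray, lam: float) -> float:
        theta = np.asarray(theta, float)
        return self.loglik(theta) - 0.5 * lam * float(theta @ self.P @ theta)

    def _score_matrix(self, m, nm):
        """dM/dtheta: chain rule through composition and grouping."""
        r = m / (1 - m)
        J = (1 - nm)[:, None] * (self.S @ (r[:, None] * self.B))
        return self.w @ J  # g x l

    def gradient(self, theta: np.ndarray, lam: float) -> np.ndarray:
        m, nm, M = self.curves(theta)
        G = self._score_matrix(m, nm)
        u = self.N * (self.mtilde - M) / M
        return G.T @ u - lam * (self.P @ theta)

    def fisher(self, theta: np.ndarray, lam: float) -> np.ndarray:
        m, nm, M = self.curves(theta)
        G = self._score_matrix(m, nm)
        Wd = self.N / M
        return G.T @ (Wd[:, None] * G) + lam * self.P

    def edf(self, theta: np.ndarray, lam: float) -> float:
        """Trace of the influence matrix of the final weighted regression."""
        m, nm, M = self.curves(theta)
        G = self._score_matrix(m, nm)
        Wd = self.N / M
        F0 = G.T @ (Wd[:, None] * G)
        F = F0 + lam * self.P
        try:
            H = linalg.solve(F, F0, assume_a="pos")
        except linalg.LinAlgError:
            H = np.linalg.lstsq(F, F0, rcond=None)[0]
        return float(np.trace(H))


def penalized_loglik(
    theta: np.ndarray,
    table: GroupedMigrationTable,
    standard: np.ndarray | None = None,
    basis_spec: BasisSpec = BasisSpec(),
    penalty_order: int = 1,
    lam: float = 0.0,
) -> float:
    """Penalized Poisson log-likelihood of grouped total movers.

    Convenience wrapper around :class:`PoissonTopalsModel`; uses the
    convention ``0 * log(0) = 0`` (model probabilities are clipped away
    from 0 and 1, so a zero model probability with a positive count yields
    a very large negative, not an exception).
    """
    model = PoissonTopalsModel(table, standard, basis_spec, penalty_order)
    return model.penalized_loglik(np.asarray(theta, float), lam)


def _irls(
    model, lam: float, theta0: np.ndarray | None, max_iter: int, tol: float
):
    """Fisher scoring with step halving; shared by both estimators."""
    theta = (
        model.default_start()
        if theta0 is None
        else np.asarray(theta0, float).copy()
    )
    L = model.penalized_loglik(theta, lam)
    converged = False
    it = 0
    ridge = 1e-10 * np.eye(model.l)
    for it in range(1, max_iter + 1):
        grad = model.gradient(theta, lam)
        F = model.fisher(theta, lam) + ridge
        try:
            delta = linalg.solve(F, grad, assume_a="pos")
        except linalg.LinAlgError:
            delta = np.linalg.lstsq(F, grad, rcond=None)[0]
        step = 1.0
        theta_new, L_new = theta, L
        for _ in range(40):
            cand = theta + step * delta
            L_cand = model.penalized_loglik(cand, lam)
            if L_cand >= L - 1e-14:
                theta_new, L_new = cand, L_cand
                break
            step *= 0.5
        else:
            converged = True  # no ascent direction left: at a maximum
            break
        if abs(L_new - L) < tol:
            theta, L = theta_new, L_new
            converged = True
            break
        theta, L = theta_new, L_new
    return theta, L, converged, it


def fit_topals(
    table: GroupedMigrationTable,
    standard: np.ndarray | None = None,
    basis_spec: BasisSpec = BasisSpec(),
    penalty_order: int = 1,
    lam: float = 1.0,
    theta0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> TopalsFit:
    """Fit the relational schedule at a fixed penalty size.

    Non-convergence after ``max_iter`` iterations is flagged on the
    returned fit rather than raised.  An all-zero mover table cannot pin
    down the level (theta would diverge); it returns the standard scaled to
    a floor crude probability, flagged degenerate.
    """
    model = PoissonTopalsModel(table, standard, basis_spec, penalty_order)
    if table.total_movers.sum() == 0:
        floor = 1e-8
        fitted_m = model.standard * (floor / model.standard.mean())
        nm = compose_multi_year(np.clip(fitted_m, 0, 1), model.n)
        return TopalsFit(
            theta=np.zeros(model.l),
            lam=lam,
            standard=model.standard,
            fitted_m=fitted_m,
            fitted_nyr=nm,
            fitted_grouped=model.w @ nm,
            loglik=model.loglik(np.zeros(model.l)),
            edf=float("nan"),
            converged=False,
            iterations=0,
            degenerate=True,
        )
    theta, L, converged, it = _irls(model, lam, theta0, max_iter, tol)
    m, nm, M = model.curves(theta)
    return TopalsFit(
        theta=theta,
        lam=lam,
        standard=model.standard,
        fitted_m=m,
        fitted_nyr=nm,
        fitted_grouped=M,
        loglik=model.loglik(theta),
        edf=model.edf(theta, lam),
        converged=converged,
        iterations=it,
    )


def effective_dimension(fit: TopalsFit, model: PoissonTopalsModel) -> float:
    """Effective number of parameters of a converged fit.

    The trace of the hat matrix of the working weighted penalized
    regression at the fitted theta; lies between the penalty order k and
    the basis size l and decreases in lambda.
    """
    return model.edf(fit.theta, fit.lam)


def information_criterion(
    loglik: float, edf: float, g: int, criterion: str
) -> float:
    """-2 loglik plus the complexity charge of the named criterion.

    The sample size for BIC/AICc is the number of grouped observations g.
    """
    crit = criterion.upper()
    if crit == "AIC":
        return -2.0 * loglik + 2.0 * edf
    if crit == "AICC":
        denom = g - edf - 1.0
        if denom <= 0:
            return np.inf
        return -2.0 * loglik + 2.0 * edf + 2.0 * edf * (edf + 1.0) / denom
    if crit == "BIC":
        return -2.0 * loglik + np.log(g) * edf
    raise ValueError(f"unknown criterion {criterion!r}")


def select_penalty(
    table: GroupedMigrationTable,
    standard: np.ndarray | None = None,
    basis_spec: BasisSpec = BasisSpec(),
    penalty_order: int = 1,
    criterion: str = "BIC",
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    max_iter: int = 200,
    tol: float = 1e-8,
):
    """Choose the penalty size on a grid by an information criterion.

    Returns ``(lambda_star, fit)`` where the fit carries its criterion
    value.  The grid is scanned in ascending order with warm starts; ties
    are broken toward the larger penalty.
    """
    grid = np.sort(np.asarray(lambda_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    best = None
    best_crit = np.inf
    theta_warm = None
    for lam in grid:
        fit = fit_topals(
            table,
            standard,
            basis_spec,
            penalty_order,
            lam=float(lam),
            theta0=theta_warm,
            max_iter=max_iter,
            tol=tol,
        )
        theta_warm = fit.theta
        if fit.degenerate:
            return float(lam), fit
        crit = information_criterion(
            fit.loglik, fit.edf, table.grouping.n_groups, criterion
        )
        if crit <= best_crit:
            best_crit = crit
            fit.criterion_value = crit
            fit.criterion = criterion
            best = fit
    return best.lam, best
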