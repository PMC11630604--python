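"""Destination-specific migration ratios via continuation-ratio P-splines.

For an origin with d destinations the destination-specific probability
factorises into out-migration times a migration ratio, ``nm^j = nm * nc^j``
with the ratios summing to one over destinations at every age.  Instead of
fitting the constrained ratios directly, they are re-expressed as
conditional (continuation) ratios

    a^j = probability of migrating to destination j, conditional on not
          migrating to destinations 1..j-1,

which are only constrained to [0, 1].  Each a^j (j < d; the last
destination is the remainder) is modelled on the logit scale as a B-spline,
``logit a^j = B phi^j``, and fitted by maximising a penalized binomial
log-likelihood of the grouped counts of migrants to j among those still "at
risk" (movers to destinations j..d),

    L(phi^j) = sum_i K^j_i (atilde^j_i log A_i + (1 - atilde^j_i) log(1 - A_i))
               - (lambda/2) phi' D'D phi,

where A = T^j a^j relates grouped and single-year conditional ratios by a
weighted average.  The weights in T^j are proportional to the expected
migrants at risk at each exact age (exposure times fitted out-migration
times the survival product of previously fitted conditionals), mirroring
the exposure weighting of the out-migration stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit, logit

from .age_structures import (
    AgeGrouping,
    ExposureCurve,
    GroupedMigrationTable,
    compose_multi_year,
    expand_exposure,
)
from .outmigration import (
    DEFAULT_LAMBDA_GRID,
    TopalsFit,
    _irls,
    information_criterion,
)
from .splines import BasisSpec, bspline_basis, penalty_matrix

_PCLIP = 1e-12


# ---------------------------------------------------------------------------
# conditional decomposition


def ratios_to_conditional(c: np.ndarray) -> np.ndarray:
    """Continuation (conditional) ratios from destination ratios.

    ``a^j = c^j / s^j`` with ``s^j`` the product of ``1 - a^k`` over prior
    destinations; where a branch is unreachable (``s^j = 0``) the
    conditional is set to 0.  The last column is identically 1.
    """
    c = np.atleast_2d(np.asarray(c, dtype=float))
    sums = c.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-8):
        raise ValueError("ratio columns must sum to 1 at every age")
    n_age, d = c.shape
    a = np.zeros_like(c)
    s = np.ones(n_age)
    for j in range(d):
        with np.errstate(invalid="ignore", divide="ignore"):
            aj = np.where(s > 1e-300, c[:, j] / np.maximum(s, 1e-300), 0.0)
        a[:, j] = np.clip(aj, 0.0, 1.0)
        s = s * (1.0 - a[:, j])
    a[:, -1] = 1.0
    return a


def conditional_to_ratios(a: np.ndarray) -> np.ndarray:
    """Destination ratios from continuation ratios (exact inverse map).

    The last destination absorbs the remainder so the columns sum to one
    exactly by construction.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    n_age, d = a.shape
    c = np.zeros_like(a)
    s = np.ones(n_age)
    for j in range(d - 1):
        c[:, j] = s * a[:, j]
        s = s * (1.0 - a[:, j])
    c[:, d - 1] = s
    return c


def risk_counts(table: GroupedMigrationTable) -> np.ndarray:
    """At-risk counts ``K^j_i = sum_{k >= j} M^k_i`` (movers to j..d)."""
    return np.cumsum(table.movers[:, ::-1], axis=1)[:, ::-1]


# ---------------------------------------------------------------------------
# grouped/single-year weights for conditionals


def conditional_weight_matrix(
    j: int,
    table: GroupedMigrationTable,
    exposure: ExposureCurve,
    out_nyr: np.ndarray,
    prior_conditionals: np.ndarray | None = None,
) -> np.ndarray:
    """Weights T^j relating grouped and single-year conditional ratios.

    Row i is supported on the group's own age range and is proportional to
    the expected migrants at risk at exact age x,

        N_x * nm_x * prod_{k < j} (1 - a^k_x),

    using the stage-1 fitted out-migration and the previously fitted
    conditionals (``prior_conditionals``: age x (j-1), may be None for
    j = 1).  Rows sum to one; a group with zero expected risk falls back to
    uniform weights.
    """
    grouping = table.grouping
    risk = exposure.values * np.asarray(out_nyr, dtype=float)
    if prior_conditionals is not None and prior_conditionals.shape[1] > 0:
        risk = risk * np.prod(1.0 - prior_conditionals, axis=1)
    mask = grouping.age_mask()
    T = mask * risk[None, :]
    totals = T.sum(axis=1)
    fallback = totals <= 0
    if np.any(fallback):
        T[fallback] = mask[fallback] / mask[fallback].sum(axis=1, keepdims=True)
        totals = T.sum(axis=1)
    return T / totals[:, None]


class BinomialRatioModel:
    """Penalized binomial likelihood of one conditional-ratio curve."""

    def __init__(
        self,
        k_risk: np.ndarray,
        y: np.ndarray,
        T: np.ndarray,
        basis_spec: BasisSpec = BasisSpec(),
        penalty_order: int = 1,
    ) -> None:
        self.K = np.asarray(k_risk, dtype=float)
        self.y = np.asarray(y, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.atilde = np.where(self.K > 0, self.y / np.maximum(self.K, 1e-300), 0.0)
        self.T = np.asarray(T, dtype=float)
        omega = self.T.shape[1] - 1
        self.omega = omega
        self.B = bspline_basis(np.arange(omega + 1, dtype=float), basis_spec)
        self.l = self.B.shape[1]
        self.P = penalty_matrix(self.l, penalty_order)
        self.g = len(self.K)

    def default_start(self) -> np.ndarray:
        """Constant phi at the pooled empirical logit."""
        pooled = np.clip(self.y.sum() / max(self.K.sum(), 1e-300), 1e-6, 1 - 1e-6)
        return np.full(self.l, logit(pooled))

    def curves(self, phi: np.ndarray):
        a = expit(self.B @ phi)
        a = np.clip(a, _PCLIP, 1 - _PCLIP)
        A = np.clip(self.T @ a, _PCLIP, 1 - _PCLIP)
        return a, A

    def loglik(self, phi: np.ndarray) -> float:
        _, A = self.curves(phi)
        terms = self.K * (
            self.atilde * np.log(A) + (1 - self.atilde) * np.log(1 - A)
        )
        return float(terms.sum())

    def penalized_loglik(self, phi: np.ndarray, lam: float) -> float:
        phi = np.asarray(phi, float)
        return self.loglik(phi) - 0.5 * lam * float(phi @ self.P @ phi)

    def _score_matrix(self, a):
        return self.T @ ((a * (1 - a))[:, None] * self.B)

    def gradient(self, phi: np.ndarray, lam: float) -> np.ndarray:
        a, A = self.curves(phi)
        G = self._score_matrix(a)
        u = self.K * (self.atilde - A) / (A * (1 - A))
        return G.T @ u - lam * (self.P @ phi)

    def fisher(self, phi: np.ndarray, lam: float) -> np.ndarray:
        a, A = self.curves(phi)
        G = self._score_matrix(a)
        Wd = self.K / (A * (1 - A))
        return G.T @ (Wd[:, None] * G) + lam * self.P

    def edf(self, phi: np.ndarray, lam: float) -> float:
        a, A = self.curves(phi)
        G = self._score_matrix(a)
        Wd = self.K / (A * (1 - A))
        F0 = G.T @ (Wd[:, None] * G)
        F = F0 + lam * self.P
        try:
            H = linalg.solve(F, F0, assume_a="pos")
        except linalg.LinAlgError:
            H = np.linalg.lstsq(F, F0, rcond=None)[0]
        return float(np.trace(H))


@dataclass
class ConditionalRatioFit:
    """One fitted conditional-ratio curve."""

    a: np.ndarray
    phi: np.ndarray
    lam: float
    loglik: float
    edf: float
    converged: bool
    iterations: int
    criterion_value: float | None = None
    fallback: bool = False


@dataclass
class ConditionalRatioSet:
    """Fitted conditional ratios for all destinations of one origin.

    ``a`` is an (omega+1) x d matrix with the last column identically 1;
    the implied destination ratios (columns summing to one at every age)
    are available via :meth:`ratios`.
    """

    a: np.ndarray
    fits: list
    destination_labels: tuple
    origin_label: str = "origin"

    def ratios(self) -> np.ndarray:
        return conditional_to_ratios(self.a)


def fit_conditional_ratio(
    j: int,
    table: GroupedMigrationTable,
    T: np.ndarray,
    basis_spec: BasisSpec = BasisSpec(),
    penalty_order: int = 1,
    criterion: str | None = "AICc",
    lam: float | None = None,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ConditionalRatioFit:
    """Fit the j-th conditional-ratio curve (j is 0-based, j < d - 1 + 1).

    With ``lam`` given the penalty is fixed; otherwise it is selected on
    the grid by ``criterion`` (AICc by default).  If no one is at risk for
    this branch the uniform fallback ``a^j = 1 / (d - j)`` is returned,
    flagged.
    """
    K = risk_counts(table)[:, j]
    y = table.movers[:, j]
    d = table.n_destinations
    if K.sum() == 0:
        a = np.full(table.grouping.omega + 1, 1.0 / (d - j))
        return ConditionalRatioFit(
            a=a,
            phi=np.zeros(1),
            lam=0.0,
            loglik=0.0,
            edf=float("nan"),
            converged=False,
            iterations=0,
            fallback=True,
        )
    model = BinomialRatioModel(K, y, T, basis_spec, penalty_order)

    def one_fit(lam_val: float, phi0=None):
        phi, L, converged, it = _irls(model, lam_val, phi0, max_iter, tol)
        a, _ = model.curves(phi)
        return ConditionalRatioFit(
            a=a,
            phi=phi,
            lam=lam_val,
            loglik=model.loglik(phi),
            edf=model.edf(phi, lam_val),
            converged=converged,
            iterations=it,
        )

    if lam is not None:
        return one_fit(float(lam))

    grid = np.sort(np.asarray(lambda_grid, dtype=float))
    best, best_crit, phi_warm = None, np.inf, None
    for lam_val in grid:
        fit = one_fit(float(lam_val), phi_warm)
        phi_warm = fit.phi
        crit = information_criterion(fit.loglik, fit.edf, model.g, criterion)
        if crit <= best_crit:
            best_crit = crit
            fit.criterion_value = crit
            best = fit
    return best


def fit_conditional_ratios(
    table: GroupedMigrationTable,
    out_fit: TopalsFit,
    exposure: ExposureCurve | None = None,
    basis_spec: BasisSpec = BasisSpec(),
    penalty_order: int = 1,
    criterion: str = "AICc",
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    order: str = "given",
) -> ConditionalRatioSet:
    """Sequentially fit all conditional-ratio curves for one origin.

    Destinations are processed in the given label order, or by descending
    total movers when ``order="by_movers"`` (more data for the early
    branches of the decomposition); results are reported back in the input
    order regardless.
    """
    d = table.n_destinations
    omega = table.grouping.omega
    if exposure is None:
        exposure = expand_exposure(table.exposures, table.grouping)

    if order == "by_movers":
        perm = list(np.argsort(-table.movers.sum(axis=0), kind="stable"))
    elif order == "given":
        perm = list(range(d))
    else:
        raise ValueError("order must be 'given' or 'by_movers'")

    work = GroupedMigrationTable(
        grouping=table.grouping,
        movers=table.movers[:, perm],
        exposures=table.exposures,
        interval_n=table.interval_n,
        destination_labels=tuple(table.destination_labels[p] for p in perm),
        origin_label=table.origin_label,
    )

    a = np.ones((omega + 1, d))
    fits: list = [None] * d
    for j in range(d - 1):
        T = conditional_weight_matrix(
            j, work, exposure, out_fit.fitted_nyr, a[:, :j]
        )
        fit = fit_conditional_ratio(
            j,
            work,
            T,
            basis_spec=basis_spec,
            penalty_order=penalty_order,
            criterion=criterion,
            lambda_grid=lambda_grid,
        )
        a[:, j] = fit.a
        fits[j] = fit
    # undo the permutation: conditionals are order-dependent, so convert to
    # ratios in fitting order and map the ratio columns back
    c_perm = conditional_to_ratios(a)
    inv = np.argsort(perm)
    c = c_perm[:, inv]
    a_given = ratios_to_conditional(c)
    fits_given = [fits[perm.index(jj)] if perm.index(jj) < d - 1 else None for jj in range(d)]
    return ConditionalRatioSet(
        a=a_given,
        fits=fits_given,
        destination_labels=tuple(table.destination_labels),
        origin_label=table.origin_label,
    )


# ---------------------------------------------------------------------------
# cube assembly


@dataclass
class MigrationCube:
    """Origin x destination x age array of interval-n probabilities.

    ``probabilities[o, j, x] = out_migration[o, x] * ratios[o, x, j]`` with
    the ratios summing to one over destinations at every age.
    """

    probabilities: np.ndarray
    out_migration: np.ndarray
    ratios: np.ndarray
    interval_n: int
    origin_labels: tuple
    destination_labels: tuple

    @property
    def omega(self) -> int:
        return self.probabilities.shape[2] - 1

    def slice(self, origin) -> np.ndarray:
        """(omega+1) x d destination schedules for one origin."""
        o = self.origin_labels.index(origin)
        return self.probabilities[o].T

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o, ol in enumerate(self.origin_labels):
            for j, dl in enumerate(self.destination_labels[o]):
                for x in range(self.omega + 1):
                    rows.append(
                        (ol, dl, x, self.interval_n, self.probabilities[o, j, x])
                    )
        return pd.DataFrame(
            rows, columns=["origin", "destination", "age", "interval_n", "probability"]
        )

    def write_csv(self, path) -> None:
        """Long-format cube CSV: origin, destination, age, interval_n, probability."""
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def assemble_cube(
    out_fits: dict, ratio_sets: dict, interval_n: int
) -> MigrationCube:
    """Combine per-origin out-migration fits and ratio sets into a cube.

    The factorisation makes the cube invariants (ratio columns summing to
    one; destination probabilities summing to out-migration) hold exactly
    by construction.
    """
    origins = tuple(out_fits.keys())
    if set(origins) != set(ratio_sets.keys()):
        raise ValueError("origin labels of out-fits and ratio sets differ")
    omega = len(next(iter(out_fits.values())).fitted_nyr) - 1
    d = ratio_sets[origins[0]].a.shape[1]
    probs = np.zeros((len(origins), d, omega + 1))
    outm = np.zeros((len(origins), omega + 1))
    rat = np.zeros((len(origins), omega + 1, d))
    dest_labels = []
    for o, origin in enumerate(origins):
        rs = ratio_sets[origin]
        if rs.a.shape[1] != d:
            raise ValueError("destination counts differ across origins")
        c = rs.ratios()
        nm = out_fits[origin].fitted_nyr
        outm[o] = nm
        rat[o] = c
        probs[o] = (nm[:, None] * c).T
        dest_labels.append(tuple(rs.destination_labels))
    return MigrationCube(
        probabilities=probs,
        out_migration=outm,
        ratios=rat,
        interval_n=interval_n,
        origin_labels=origins,
        destination_labels=tuple(dest_labels),
    )
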