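"""Hybrid spline / model-migration-schedule expansion (comparison method).

The classical alternative to penalized-likelihood smoothing expands grouped
migration probabilities in two stages:

1. each closed-group sample probability is placed at the midpoint of its
   age group and a natural cubic spline is interpolated through the
   midpoints (the open interval is not used);
2. the interpolated curve is fitted with a student-peak model migration
   schedule — a sum of exponential (childhood), double-exponential (labour
   force and student), Gaussian (retirement) and exponential-growth
   (elderly) components plus a constant — which extends the estimate to
   all ages.

Destination-specific schedules are produced by a three-step cascade:
best-fit parameters for total migration (Step 1) warm-start the fit of
origin out-migration (Step 2), whose parameters are carried to each
destination with only the level parameters re-fitted (Step 3).  A
non-constant component dropped at an earlier step stays dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .age_structures import AgeGrouping, GroupedMigrationTable, OPEN

_LEVELS = ("a1", "a2", "a3", "a4", "a5", "c")
_COMPONENT_PARAMS = {
    "childhood": ("a1", "alpha1"),
    "labour": ("a2", "alpha2", "mu2", "lambda2"),
    "retirement": ("a3", "mu3", "sigma3"),
    "elderly": ("a4", "alpha4"),
    "student": ("a5", "alpha5", "mu5", "lambda5"),
}
_BOUNDS = {
    "a1": (0.0, np.inf),
    "alpha1": (1e-4, 5.0),
    "a2": (0.0, np.inf),
    "alpha2": (1e-4, 5.0),
    "mu2": (10.0, 60.0),
    "lambda2": (1e-4, 10.0),
    "a3": (0.0, np.inf),
    "mu3": (45.0, 90.0),
    "sigma3": (0.5, 50.0),
    "a4": (0.0, np.inf),
    "alpha4": (1e-6, 0.2),
    "a5": (0.0, np.inf),
    "alpha5": (1e-4, 5.0),
    "mu5": (12.0, 25.0),
    "lambda5": (1e-4, 10.0),
    "c": (0.0, np.inf),
}


@dataclass(frozen=True)
class MMSParams:
    """Parameters of the student-peak model migration schedule.

    Levels (a1..a5, c) are nonnegative; rate, location and width parameters
    only matter for components with a positive level.  ``components`` names
    the active non-constant components; inactive components evaluate to
    zero and are never fitted.
    """

    a1: float = 0.0
    alpha1: float = 0.1
    a2: float = 0.0
    alpha2: float = 0.1
    mu2: float = 22.0
    lambda2: float = 0.4
    a3: float = 0.0
    mu3: float = 65.0
    sigma3: float = 8.0
    a4: float = 0.0
    alpha4: float = 0.01
    a5: float = 0.0
    alpha5: float = 0.5
    mu5: float = 17.0
    lambda5: float = 1.0
    c: float = 0.0
    components: frozenset = frozenset({"childhood", "labour"})

    def __post_init__(self) -> None:
        unknown = set(self.components) - set(_COMPONENT_PARAMS)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")
        for name in _LEVELS:
            if getattr(self, name) < 0:
                raise ValueError(f"level parameter {name} must be nonnegative")

    def free_parameters(self, levels_only: bool = False) -> tuple:
        """Names of the parameters fitted for the active components."""
        names = ["c"]
        for comp in ("childhood", "labour", "retirement", "elderly", "student"):
            if comp in self.components:
                params = _COMPONENT_PARAMS[comp]
                names.extend(params[:1] if levels_only else params)
        return tuple(names)


def mms_evaluate(params: MMSParams, ages: np.ndarray) -> np.ndarray:
    """Evaluate the model migration schedule at the given ages."""
    x = np.asarray(ages, dtype=float)
    out = np.full_like(x, params.c, dtype=float)
    if "childhood" in params.components:
        out += params.a1 * np.exp(-params.alpha1 * x)
    if "labour" in params.components:
        z = x - params.mu2
        out += params.a2 * np.exp(-params.alpha2 * z - np.exp(-params.lambda2 * z))
    if "retirement" in params.components:
        out += params.a3 * np.exp(-(((x - params.mu3) / params.sigma3) ** 2))
    if "elderly" in params.components:
        out += params.a4 * np.exp(params.alpha4 * x)
    if "student" in params.components:
        z = x - params.mu5
        out += params.a5 * np.exp(-params.alpha5 * z - np.exp(-params.lambda5 * z))
    return out


@dataclass
class HybridFit:
    """Result of the two-stage expansion for one schedule."""

    spline_ages: np.ndarray
    spline_values: np.ndarray
    params: MMSParams
    fitted_m: np.ndarray
    residual_norm: float
    success: bool = True


def midpoint_spline(
    grouped_probs: np.ndarray, grouping: AgeGrouping, n: int = 1
):
    """Natural cubic spline through the group-midpoint sample probabilities.

    Each closed group's sample probability is placed at ``a_i + b_i / 2``;
    the open interval is excluded.  Returns ``(ages, values)`` on the
    integer ages between the first and last midpoint; outside that range
    the curve is undefined (left to the model-schedule stage).
    """
    probs = np.asarray(grouped_probs, dtype=float)
    if probs.shape != (grouping.n_groups,):
        raise ValueError("grouped probabilities must be a g-vector")
    knots_x, knots_y = [], []
    for (a, b), p in zip(grouping.groups, probs):
        if b == OPEN:
            continue
        knots_x.append(a + b / 2.0)
        knots_y.append(p)
    if len(knots_x) < 2:
        raise ValueError("midpoint spline needs at least 2 closed groups")
    spline = CubicSpline(knots_x, knots_y, bc_type="natural")
    lo = int(np.ceil(knots_x[0]))
    hi = int(np.floor(knots_x[-1]))
    ages = np.arange(lo, hi + 1, dtype=float)
    return ages, spline(ages)


def fit_mms(
    target_ages: np.ndarray,
    target_values: np.ndarray,
    start: MMSParams,
    free: tuple | None = None,
    rng: np.random.Generator | None = None,
    n_starts: int = 5,
    jitter: float = 0.2,
    max_nfev: int = 2000,
) -> tuple:
    """Least-squares fit of the model schedule to a target curve.

    Fits the parameters named in ``free`` (default: all parameters of the
    active components plus the constant) on the probability scale with a
    trust-region solver, from the given start plus ``n_starts - 1``
    multiplicatively jittered restarts.  The returned residual norm never
    exceeds the residual at the start; an optimizer failure returns the
    start, flagged.

    Returns ``(params, residual_norm, success)``.
    """
    x = np.asarray(target_ages, dtype=float)
    y = np.asarray(target_values, dtype=float)
    if free is None:
        free = start.free_parameters()
    free = tuple(free)
    rng = np.random.default_rng(0) if rng is None else rng

    def unpack(vec: np.ndarray) -> MMSParams:
        return replace(start, **dict(zip(free, vec)))

    def residual(vec: np.ndarray) -> np.ndarray:
        return mms_evaluate(unpack(vec), x) - y

    lo = np.array([_BOUNDS[name][0] for name in free])
    hi = np.array([_BOUNDS[name][1] for name in free])
    x0 = np.clip(np.array([getattr(start, name) for name in free]), lo, hi)
    # the trust-region solver scales steps with |x|, so a start pinned at a
    # zero bound cannot move; nudge such starts to a data-scaled interior
    scale = float(np.mean(np.abs(y))) + 1e-12
    pinned = x0 <= lo + 1e-12
    x0[pinned] = np.minimum(lo[pinned] + np.maximum(0.1 * scale, 1e-6), hi[pinned])

    starts = [x0]
    for _ in range(n_starts - 1):
        fac = 1.0 + jitter * rng.uniform(-1.0, 1.0, size=len(free))
        starts.append(np.clip(x0 * fac, lo, hi))

    best_vec, best_cost, success = x0, np.inf, False
    for s0 in starts:
        try:
            sol = least_squares(
                residual, s0, bounds=(lo, hi), method="trf", max_nfev=max_nfev
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best_vec, best_cost, success = sol.x, sol.cost, True
    start_norm = float(np.linalg.norm(residual(x0)))
    if not success:
        return start, start_norm, False
    best_norm = float(np.sqrt(2.0 * best_cost))
    if best_norm > start_norm:
        return unpack(x0), start_norm, True
    return unpack(best_vec), best_norm, True


def _aic_rss(rss: float, n_obs: int, n_params: int) -> float:
    rss = max(rss, 1e-300)
    return n_obs * np.log(rss / n_obs) + 2.0 * n_params


def _select_components(
    ages: np.ndarray,
    values: np.ndarray,
    rng: np.random.Generator,
) -> tuple:
    """Step-1 fit with greedy component selection.

    Starts from childhood + labour + constant (levels scaled to the
    target) and adds student, retirement and elderly components one at a
    time when doing so improves a residual-based AIC.
    """
    level = float(np.clip(np.mean(values), 1e-6, None))
    base = MMSParams(
        a1=level,
        a2=2.0 * level,
        mu2=float(np.clip(ages[np.argmax(values)], 12.0, 55.0)),
        c=0.1 * level,
        components=frozenset({"childhood", "labour"}),
    )
    params, norm, _ = fit_mms(ages, values, base, rng=rng)
    n_obs = len(ages)
    if norm < 1e-8 * max(1.0, float(np.linalg.norm(values))):
        return params, norm  # already an essentially exact fit
    best_aic = _aic_rss(norm**2, n_obs, len(params.free_parameters()))
    seeds = {
        "student": dict(a5=0.5 * level),
        "retirement": dict(a3=0.2 * level),
        "elderly": dict(a4=0.01 * level),
    }
    for comp, seed in seeds.items():
        cand_start = replace(
            params, components=params.components | {comp}, **seed
        )
        cand, cand_norm, ok = fit_mms(ages, values, cand_start, rng=rng)
        if not ok:
            continue
        cand_aic = _aic_rss(cand_norm**2, n_obs, len(cand.free_parameters()))
        if cand_aic < best_aic:
            params, norm, best_aic = cand, cand_norm, cand_aic
    return params, norm


@dataclass
class HybridCascadeResult:
    """Fits from the three-step cascade for one origin."""

    total: HybridFit
    origin: HybridFit
    destinations: dict


def _expand(table: GroupedMigrationTable, probs, params, rng, free=None):
    ages, values = midpoint_spline(probs, table.grouping, table.interval_n)
    fitted, norm, ok = fit_mms(ages, values, params, free=free, rng=rng)
    omega = table.grouping.omega
    curve = np.maximum(mms_evaluate(fitted, np.arange(omega + 1)), 0.0)
    return HybridFit(ages, values, fitted, curve, norm, ok)


def hybrid_cascade(
    table: GroupedMigrationTable,
    totals_table: GroupedMigrationTable,
    seed: int = 0,
) -> HybridCascadeResult:
    """Run the three-step origin -> destination parameter cascade.

    Step 1 fits total first-level migration (with component selection);
    Step 2 warm-starts from Step 1 for the origin's out-migration with all
    active parameters free; Step 3 re-fits the level parameters only for
    each destination.  Components dropped at Step 1 stay dropped.
    """
    rng = np.random.default_rng(seed)
    tot_ages, tot_values = midpoint_spline(
        totals_table.sample_out_probs, totals_table.grouping, totals_table.interval_n
    )
    tot_params, tot_norm = _select_components(tot_ages, tot_values, rng)
    omega = totals_table.grouping.omega
    total_fit = HybridFit(
        tot_ages,
        tot_values,
        tot_params,
        np.maximum(mms_evaluate(tot_params, np.arange(omega + 1)), 0.0),
        tot_norm,
    )

    origin_fit = _expand(table, table.sample_out_probs, tot_params, rng)

    level_free = tuple(
        n for n in origin_fit.params.free_parameters(levels_only=True)
    )
    dest_fits = {}
    for j, label in enumerate(table.destination_labels):
        dest_fits[label] = _expand(
            table,
            table.sample_dest_probs[:, j],
            origin_fit.params,
            rng,
            free=level_free,
        )
    return HybridCascadeResult(total=total_fit, origin=origin_fit, destinations=dest_fits)
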