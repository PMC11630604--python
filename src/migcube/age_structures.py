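"""Grouped-age data structures for transition-style migration data.

Transition data record, for an origin region, how many people in each age
group were living in each destination region n years later, out of an
exposed population counted at the start of the interval.  Age groups are
half-open intervals ``[a, a + b)`` with age measured in completed years at
the start of the migration interval; the last group may be open (``b``
infinite).  Groups are usually contiguous but may overlap or be disjoint.

This module houses those containers plus the three primitives connecting
grouped and single-year quantities:

* exposure expansion (grouped exposures -> a single-year exposure curve),
* the weight matrix turning a single-year schedule into grouped
  probabilities as an exposure-weighted average, and
* the survival-product composition turning implied one-year migration
  probabilities into multi-year (interval-n) probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

OPEN = math.inf
"""Sentinel width for an open terminal age interval."""

DEFAULT_OMEGA = 110
"""Default maximum age (limit of the single-year age range 0..omega)."""


@dataclass(frozen=True)
class AgeGrouping:
    """An ordered set of age intervals ``[a_i, a_i + b_i)``.

    ``groups`` is a sequence of ``(start, width)`` pairs; the width of the
    last group may be :data:`OPEN` (infinity).  ``omega`` is the maximum
    single year of age considered; an open group spans ``a_g .. omega``.
    """

    groups: tuple
    omega: int = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        groups = tuple((int(a), (OPEN if b == OPEN else int(b))) for a, b in self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) == 0:
            raise ValueError("grouping must contain at least one group")
        for i, (a, b) in enumerate(groups):
            if a < 0:
                raise ValueError(f"group start {a} is negative")
            if b == OPEN:
                if i != len(groups) - 1:
                    raise ValueError("only the last group may be open")
            else:
                if b <= 0:
                    raise ValueError(f"group width {b} must be positive")
                if a + b > self.omega + 1:
                    raise ValueError(
                        f"group [{a}, {a + b}) extends past omega={self.omega}"
                    )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def has_open(self) -> bool:
        return self.groups[-1][1] == OPEN

    def bounds(self) -> list:
        """Per-group integer age ranges ``(start, stop_exclusive)``.

        Open groups are truncated at ``omega + 1``.
        """
        out = []
        for a, b in self.groups:
            stop = self.omega + 1 if b == OPEN else a + b
            out.append((a, min(stop, self.omega + 1)))
        return out

    def age_mask(self) -> np.ndarray:
        """Boolean ``g x (omega+1)`` membership matrix."""
        mask = np.zeros((self.n_groups, self.omega + 1), dtype=bool)
        for i, (a, stop) in enumerate(self.bounds()):
            mask[i, a:stop] = True
        return mask

    def is_contiguous(self) -> bool:
        for (a0, b0), (a1, _) in zip(self.groups, self.groups[1:]):
            if b0 == OPEN or a0 + b0 != a1:
                return False
        return True

    @classmethod
    def single_year(cls, omega: int = DEFAULT_OMEGA) -> "AgeGrouping":
        return cls(tuple((a, 1) for a in range(omega + 1)), omega=omega)

    @classmethod
    def five_year(
        cls, open_start: int = 85, omega: int = DEFAULT_OMEGA
    ) -> "AgeGrouping":
        """Standard abridgement: 5-year groups with an open interval."""
        groups = [(a, 5) for a in range(0, open_start, 5)]
        groups.append((open_start, OPEN))
        return cls(tuple(groups), omega=omega)


@dataclass(frozen=True)
class ExposureCurve:
    """Single-year exposures ``N_x`` for ``x = 0..omega``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("exposure curve must be one-dimensional")
        if np.any(v < 0):
            raise ValueError("exposures must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def omega(self) -> int:
        return len(self.values) - 1


@dataclass(frozen=True)
class Schedule:
    """A vector indexed by single year of age 0..omega.

    ``kind`` distinguishes one-year probabilities, interval-n probabilities,
    ratios and weights; probability/ratio kinds are checked to lie in
    ``[0, 1]``.
    """

    values: np.ndarray
    kind: str = "probability_1yr"
    interval_n: int = 1

    _KINDS = ("probability_1yr", "probability_nyr", "ratio", "weight")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind in ("probability_1yr", "probability_nyr", "ratio"):
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError("probability/ratio values must lie in [0, 1]")

    @property
    def omega(self) -> int:
        return len(self.values) - 1


@dataclass(frozen=True)
class GroupedMigrationTable:
    """Grouped mover counts and exposures for one origin.

    ``movers[i, j]`` is the count of people in age group i (at the start of
    the interval) observed in destination j after ``interval_n`` years;
    ``exposures[i]`` is the exposed population of the group (people at the
    origin at the start who are still in the country at the end).
    """

    grouping: AgeGrouping
    movers: np.ndarray
    exposures: np.ndarray
    interval_n: int
    destination_labels: tuple = ()
    origin_label: str = "origin"

    def __post_init__(self) -> None:
        movers = np.atleast_2d(np.asarray(self.movers, dtype=float))
        exposures = np.asarray(self.exposures, dtype=float)
        object.__setattr__(self, "movers", movers)
        object.__setattr__(self, "exposures", exposures)
        g = self.grouping.n_groups
        if movers.shape[0] != g:
            raise ValueError(f"movers has {movers.shape[0]} rows, expected {g}")
        if exposures.shape != (g,):
            raise ValueError("exposures must be a g-vector")
        if self.interval_n < 1:
            raise ValueError("interval_n must be >= 1")
        if np.any(movers < 0) or np.any(exposures <= 0):
            raise ValueError("movers must be nonnegative and exposures positive")
        if np.any(movers.sum(axis=1) > exposures + 1e-9):
            raise ValueError("movers exceed exposures in some group")
        if not self.destination_labels:
            labels = tuple(f"D{j + 1}" for j in range(movers.shape[1]))
            object.__setattr__(self, "destination_labels", labels)
        elif len(self.destination_labels) != movers.shape[1]:
            raise ValueError("destination_labels length mismatch")

    @property
    def n_destinations(self) -> int:
        return self.movers.shape[1]

    @property
    def total_movers(self) -> np.ndarray:
        """Total out-movers per group, irrespective of destination."""
        return self.movers.sum(axis=1)

    @property
    def sample_out_probs(self) -> np.ndarray:
        """Grouped sample out-migration probabilities M / N."""
        return self.total_movers / self.exposures

    @property
    def sample_dest_probs(self) -> np.ndarray:
        """Grouped sample destination-specific probabilities M^j / N."""
        return self.movers / self.exposures[:, None]

    def totals_only(self) -> "GroupedMigrationTable":
        """Collapse destinations into a single 'moved' column."""
        return GroupedMigrationTable(
            grouping=self.grouping,
            movers=self.total_movers[:, None],
            exposures=self.exposures,
            interval_n=self.interval_n,
            destination_labels=("any",),
            origin_label=self.origin_label,
        )


# ---------------------------------------------------------------------------
# exposure expansion


def _geometric_tail(count: float, density: float, n_ages: int) -> np.ndarray:
    """Geometric exposures over an open interval.

    Finds the decay ratio r such that ``density * (r + r^2 + ... + r^T)``
    equals the open-group count, i.e. the tail continues from the mean
    per-age exposure of the last closed group, then rescales so the sum is
    exact.
    """
    if n_ages == 1:
        return np.array([count])

    def gap(r: float) -> float:
        return density * np.sum(r ** np.arange(1, n_ages + 1)) - count

    lo, hi = 1e-9, 2.0
    while gap(hi) < 0 and hi < 1e6:
        hi *= 2.0
    if gap(lo) > 0:
        r = lo
    else:
        r = brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14)
    tail = density * r ** np.arange(1, n_ages + 1)
    return tail * (count / tail.sum())


def expand_exposure(
    grouped_exposures: np.ndarray, grouping: AgeGrouping
) -> ExposureCurve:
    """Expand grouped exposures to a single-year exposure curve.

    Closed groups are expanded with a monotone (PCHIP) interpolating spline
    through the cumulative grouped counts, differenced at integer ages and
    rescaled within each group so the grouped totals are conserved exactly.
    An open terminal interval receives a geometrically decreasing profile,
    continuous with the mean per-age exposure of the last closed group and
    summing exactly to the open-group count (truncated at omega).

    Non-contiguous (overlapping or disjoint) groupings fall back to a
    uniform within-group allocation, which still conserves group totals.
    """
    counts = np.asarray(grouped_exposures, dtype=float)
    if counts.shape != (grouping.n_groups,):
        raise ValueError("grouped exposures must be a g-vector")
    if np.any(counts <= 0):
        raise ValueError("grouped exposures must be positive")

    omega = grouping.omega
    values = np.zeros(omega + 1)
    closed = [
        (a, b, c)
        for (a, b), c in zip(grouping.groups, counts)
        if b != OPEN
    ]

    contiguous = all(
        a0 + b0 == a1 for (a0, b0, _), (a1, _, _) in zip(closed, closed[1:])
    )

    if closed:
        if contiguous and len(closed) >= 2:
            # cumulative counts at the group boundaries
            knots = [closed[0][0]] + [a + b for a, b, _ in closed]
            cum = np.concatenate([[0.0], np.cumsum([c for _, _, c in closed])])
            interp = PchipInterpolator(knots, cum)
            lo, hi = closed[0][0], closed[-1][0] + closed[-1][1]
            grid = np.arange(lo, hi + 1)
            diffs = np.diff(interp(grid))
            values[lo:hi] = np.maximum(diffs, 0.0)
        else:
            for a, b, c in closed:
                values[a : a + b] = c / b
        # exact conservation per closed group
        for a, b, c in closed:
            s = values[a : a + b].sum()
            if s > 0:
                values[a : a + b] *= c / s
            else:
                values[a : a + b] = c / b

    if grouping.has_open:
        a_open = grouping.groups[-1][0]
        c_open = counts[-1]
        n_ages = omega - a_open + 1
        if n_ages <= 0:
            raise ValueError("open group starts past omega")
        if closed:
            a_last, b_last, c_last = closed[-1]
            density = c_last / b_last
            values[a_open:] = _geometric_tail(c_open, density, n_ages)
        else:
            values[a_open:] = c_open / n_ages

    return ExposureCurve(values)


def weight_matrix(exposure: ExposureCurve, grouping: AgeGrouping) -> np.ndarray:
    """Exposure weights ``w[i, x] = N_x / N_i`` over each group's age range.

    Each row sums to one; open-group rows span ``a_g .. omega``.  A group
    with zero total exposure has undefined weights and is rejected.
    """
    if exposure.omega != grouping.omega:
        raise ValueError("exposure curve and grouping disagree on omega")
    mask = grouping.age_mask()
    w = mask * exposure.values[None, :]
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.argmin(totals))
        raise ValueError(f"group {bad} has zero total exposure; weights undefined")
    return w / totals[:, None]


# ---------------------------------------------------------------------------
# multi-year composition


def compose_multi_year(m: np.ndarray, n: int) -> np.ndarray:
    """Interval-n probabilities implied by one-year probabilities.

    ``nm_x = 1 - prod_{x <= k < x+n} (1 - m_k)`` with the product truncated
    at ``k = omega`` (ages past omega contribute no factor).  ``n = 1`` is
    the identity, and the map is elementwise monotone in ``m``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("one-year probabilities must lie in [0, 1]")
    if n == 1:
        return m.copy()
    omega = len(m) - 1
    # log-survival cumulative sums give the truncated window products
    logq = np.log1p(-np.minimum(m, 1 - 1e-300))
    cum = np.concatenate([[0.0], np.cumsum(logq)])
    idx_hi = np.minimum(np.arange(omega + 1) + n, omega + 1)
    window = cum[idx_hi] - cum[: omega + 1]
    return -np.expm1(window)


def survival_window_matrix(omega: int, n: int) -> np.ndarray:
    """Indicator matrix S with ``S[x, k] = 1`` for ``x <= k < min(x+n, omega+1)``.

    Used by the estimators to push gradients through the multi-year
    composition.
    """
    idx = np.arange(omega + 1)
    return ((idx[None, :] >= idx[:, None]) & (idx[None, :] < idx[:, None] + n)).astype(
        float
    )


def grouped_probability(m: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Grouped interval-n probabilities from a one-year schedule.

    The weighted average ``w . nm`` of the composed schedule; each grouped
    value averages ``m`` over the age range ``[a_i, a_i + b_i + n)``.
    """
    m = np.asarray(m, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape[1] != len(m):
        raise ValueError("weight matrix and schedule dimensions do not conform")
    return w @ compose_multi_year(m, n)


# ---------------------------------------------------------------------------
# CSV interfaces


def _width_to_str(b) -> str:
    return "open" if b == OPEN else str(int(b))


def _width_from_str(s) -> float:
    return OPEN if str(s).strip().lower() == "open" else int(s)


def write_grouped_tables(
    tables: dict, movers_path, exposures_path
) -> None:
    """Write grouped tables (one per origin) to a movers/exposures CSV pair."""
    mov_rows, exp_rows = [], []
    for origin, t in tables.items():
        for (a, b), mrow, nexp in zip(t.grouping.groups, t.movers, t.exposures):
            for lab, cnt in zip(t.destination_labels, mrow):
                mov_rows.append(
                    dict(
                        origin=origin,
                        destination=lab,
                        age_start=a,
                        age_width=_width_to_str(b),
                        movers=int(round(cnt)),
                    )
                )
            exp_rows.append(
                dict(
                    origin=origin,
                    age_start=a,
                    age_width=_width_to_str(b),
                    exposure=int(round(nexp)),
                )
            )
    pd.DataFrame(mov_rows).to_csv(movers_path, index=False)
    pd.DataFrame(exp_rows).to_csv(exposures_path, index=False)


def read_grouped_tables(
    movers_path, exposures_path, interval_n: int, omega: int = DEFAULT_OMEGA
) -> dict:
    """Read the movers/exposures CSV pair back into per-origin tables."""
    mov = pd.read_csv(movers_path)
    exp = pd.read_csv(exposures_path)
    tables = {}
    for origin, mgrp in mov.groupby("origin", sort=False):
        egrp = exp[exp["origin"] == origin]
        groups = tuple(
            (int(r.age_start), _width_from_str(r.age_width))
            for r in egrp.itertuples()
        )
        grouping = AgeGrouping(groups, omega=omega)
        dests = list(dict.fromkeys(mgrp["destination"]))
        movers = np.zeros((len(groups), len(dests)))
        starts = {a: i for i, (a, _) in enumerate(groups)}
        for r in mgrp.itertuples():
            movers[starts[int(r.age_start)], dests.index(r.destination)] = r.movers
        tables[origin] = GroupedMigrationTable(
            grouping=grouping,
            movers=movers,
            exposures=egrp["exposure"].to_numpy(dtype=float),
            interval_n=interval_n,
            destination_labels=tuple(dests),
            origin_label=str(origin),
        )
    return tables
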