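"""B-spline bases and difference penalties shared by the penalized estimators.

The default basis follows the protocol configuration used throughout the
package: quadratic B-splines on an open-uniform knot vector with knots
spaced 2.5 years apart from age 0 to age 180.  Schedules are only ever
evaluated on integer ages 0..omega (omega <= 110 by default); the wide knot
range keeps the basis well conditioned near the top of the age range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class BasisSpec:
    """Configuration of an open-uniform B-spline basis.

    Parameters
    ----------
    knot_start, knot_end : float
        Range covered by the knots.  Ages passed to :func:`bspline_basis`
        must lie inside ``[knot_start, knot_end)``.
    knot_spacing : float
        Distance between adjacent interior knots, in years.
    degree : int
        Polynomial degree of the B-splines (2 = quadratic).
    """

    knot_start: float = 0.0
    knot_end: float = 180.0
    knot_spacing: float = 2.5
    degree: int = 2

    def __post_init__(self) -> None:
        if self.knot_end <= self.knot_start:
            raise ValueError("knot_end must exceed knot_start")
        if self.knot_spacing <= 0:
            raise ValueError("knot_spacing must be positive")
        if self.degree < 0:
            raise ValueError("degree must be nonnegative")

    @property
    def knots(self) -> np.ndarray:
        """Full (clamped) knot vector with boundary knots replicated."""
        n_steps = int(round((self.knot_end - self.knot_start) / self.knot_spacing))
        inner = self.knot_start + self.knot_spacing * np.arange(n_steps + 1)
        # force exact endpoint to avoid round-off at the right boundary
        inner[-1] = self.knot_end
        return np.concatenate(
            [np.full(self.degree, self.knot_start), inner, np.full(self.degree, self.knot_end)]
        )

    @property
    def n_basis(self) -> int:
        """Number of B-spline columns l implied by the knots and degree."""
        return len(self.knots) - self.degree - 1


def bspline_basis(ages: np.ndarray, spec: BasisSpec = BasisSpec()) -> np.ndarray:
    """Evaluate the B-spline basis on a grid of ages.

    Returns a dense ``(len(ages), l)`` matrix whose rows sum to one
    (partition of unity of the clamped basis).

    Raises
    ------
    ValueError
        If any age lies outside ``[knot_start, knot_end)``.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1:
        raise ValueError("ages must be one-dimensional")
    if np.any(ages < spec.knot_start) or np.any(ages >= spec.knot_end):
        raise ValueError(
            f"ages must lie in [{spec.knot_start}, {spec.knot_end}); "
            f"got range [{ages.min()}, {ages.max()}]"
        )
    dm = BSpline.design_matrix(ages, spec.knots, spec.degree, extrapolate=False)
    return np.asarray(dm.todense())


def difference_matrix(l: int, k: int) -> np.ndarray:
    """k-th order finite-difference matrix D_k of shape ``(l - k, l)``.

    ``D_k @ theta`` are the k-th differences of ``theta``; the matrix
    annihilates polynomials of degree < k in the index.
    """
    if not 1 <= k < l:
        raise ValueError(f"need 1 <= k < l, got k={k}, l={l}")
    D = np.eye(l)
    for _ in range(k):
        D = np.diff(D, axis=0)
    return D


def penalty_matrix(l: int, k: int) -> np.ndarray:
    """The quadratic penalty kernel ``D_k' D_k``."""
    D = difference_matrix(l, k)
    return D.T @ D
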