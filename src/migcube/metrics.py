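"""Goodness-of-fit and plausibility metrics for fitted migration schedules.

Two deviance-based fitting errors compare grouped sample probabilities with
grouped model probabilities: a scaled multinomial deviance over all
destinations plus the stay category (``dev``), and a scaled binomial
deviance for total out-migration (``dev_m``).  Both are zero iff the model
reproduces the sample exactly, and use the convention 0 * log 0 = 0.

Plausibility is measured by the shape deviation: the sum over destinations
of 100 * (1 - cosine similarity) between each fitted schedule and a
reference profile, which is scale-invariant in each destination schedule.
"""

from __future__ import annotations

import numpy as np

from .age_structures import GroupedMigrationTable, compose_multi_year


def _xlogy_ratio(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """p * log(p / q) with 0 * log 0 = 0 and +inf when q = 0 < p."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    out = np.zeros(np.broadcast(p, q).shape)
    pos = p > 0
    with np.errstate(divide="ignore"):
        out[pos] = p[pos] * (np.log(p[pos]) - np.log(q[pos]))
    return out


def migration_deviance(
    table: GroupedMigrationTable, fitted_grouped: np.ndarray
) -> float:
    """Scaled multinomial deviance of all destination-specific fits.

    ``fitted_grouped`` is the g x d matrix of grouped model probabilities
    for each destination; the stay category uses one minus the row sums.
    The 1/(gd) scaling controls for the number of observations and
    destinations so values are comparable across groupings and spatial
    decompositions.
    """
    fitted = np.atleast_2d(np.asarray(fitted_grouped, dtype=float))
    g, d = fitted.shape
    if fitted.shape != table.movers.shape:
        raise ValueError("fitted grouped probabilities must match movers shape")
    samp = table.sample_dest_probs
    stay_s = 1.0 - samp.sum(axis=1)
    stay_f = 1.0 - fitted.sum(axis=1)
    kernel = _xlogy_ratio(stay_s, stay_f) + _xlogy_ratio(samp, fitted).sum(axis=1)
    return float(2.0 / (g * d) * np.sum(table.exposures * kernel))


def outmigration_deviance(
    table: GroupedMigrationTable, fitted_out: np.ndarray
) -> float:
    """Scaled binomial deviance of the grouped total out-migration fit.

    ``fitted_out`` is the g-vector of grouped model out-migration
    probabilities; depends only on totals so it is invariant to how movers
    split across destinations.
    """
    fitted = np.asarray(fitted_out, dtype=float)
    g = table.grouping.n_groups
    if fitted.shape != (g,):
        raise ValueError("fitted grouped out-migration must be a g-vector")
    samp = table.sample_out_probs
    kernel = _xlogy_ratio(1.0 - samp, 1.0 - fitted) + _xlogy_ratio(samp, fitted)
    return float(2.0 / g * np.sum(table.exposures * kernel))


def shape_deviation(
    schedules: np.ndarray, reference: np.ndarray, per_destination: bool = False
):
    """Shape deviation of destination schedules from a reference profile.

    ``schedules`` is (omega+1) x d (or a single vector); each destination
    contributes ``100 * (1 - cos(m_ref, m^j))``, invariant to positive
    rescaling of either vector.  A zero-norm schedule is undefined and
    rejected.
    """
    sched = np.asarray(schedules, dtype=float)
    if sched.ndim == 1:
        sched = sched[:, None]
    ref = np.asarray(reference, dtype=float)
    ref_norm = np.linalg.norm(ref)
    norms = np.linalg.norm(sched, axis=0)
    if ref_norm == 0 or np.any(norms == 0):
        raise ValueError("shape deviation undefined for zero-norm schedules")
    cos = (ref @ sched) / (ref_norm * norms)
    terms = 100.0 * (1.0 - cos)
    if per_destination:
        return terms
    return float(terms.sum())


def reference_schedule(schedules, n: int = 1) -> np.ndarray:
    """Average profile of a set of one-year schedules, composed to interval n.

    Each schedule is rescaled to unit sum over ages 0..omega, the scaled
    curves are averaged, and the average composed to the requested interval
    with the survival product.  All-zero schedules are excluded.
    """
    kept = []
    for s in schedules:
        s = np.asarray(s, dtype=float)
        total = s.sum()
        if total > 0:
            kept.append(s / total)
    if not kept:
        raise ValueError("no nonzero schedules to average")
    mref = np.mean(kept, axis=0)
    if n == 1:
        return mref
    return compose_multi_year(np.clip(mref, 0.0, 1.0), n)
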