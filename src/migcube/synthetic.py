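"""Synthetic migration scenarios: known truth, sampled counts, age heaping.

The generator produces fully specified datasets on which the whole
estimation pipeline can be exercised without any external data: a true
one-year migration cube built from model migration schedules, an exposed
population per origin, multinomially sampled grouped mover counts over an
arbitrary age grouping (including an open interval), and optional
digit-preference heaping of single-year population counts.

The interval-n truth follows a no-return model: each year a person at the
origin out-migrates with probability ``m_x`` and, conditional on moving,
chooses destination j with probability ``c^j_x``; movers do not move
again within the interval.  Under this model the n-year out-migration
probability is exactly the survival-product composition of the one-year
schedule, and the n-year destination probabilities sum to it by
construction.

The default scenario mirrors a typical census setting: five destinations,
five-year age groups with an open interval at 85+, a five-year migration
interval, ages 0..110, and a constant exposed population of 10^6 per
single year of age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .age_structures import (
    AgeGrouping,
    ExposureCurve,
    GroupedMigrationTable,
    compose_multi_year,
)
from .hybrid import MMSParams, mms_evaluate


@dataclass(frozen=True)
class SyntheticScenario:
    """A fully specified synthetic migration setting.

    ``out_params`` maps each origin to the model-schedule parameters of its
    one-year out-migration; ``ratio_profiles`` maps each origin to an
    (omega+1) x d matrix of one-year destination ratios (columns per
    destination, rows summing to one).  ``population`` maps each origin to
    a single-year exposure curve.
    """

    origins: tuple
    destinations: tuple
    out_params: dict
    ratio_profiles: dict
    population: dict
    grouping: AgeGrouping
    interval_n: int = 5
    heaping_strength: float = 0.0
    seed: int = 0

    @property
    def omega(self) -> int:
        return self.grouping.omega


def _default_ratio_profiles(
    origins, destinations, omega: int, seed: int
) -> dict:
    """Smooth, mildly age-dependent destination ratios per origin.

    Each destination gets a log-linear age trend plus a Gaussian bump at a
    destination-specific age, normalised over destinations; parameters are
    drawn reproducibly from the scenario seed.
    """
    rng = np.random.default_rng(seed + 1)
    x = np.arange(omega + 1, dtype=float)
    profiles = {}
    for origin in origins:
        d = len(destinations)
        logw = np.empty((omega + 1, d))
        for j in range(d):
            base = rng.uniform(-0.5, 0.5)
            slope = rng.uniform(-0.8, 0.8)
            bump_age = rng.uniform(15.0, 60.0)
            bump_size = rng.uniform(0.0, 0.6)
            logw[:, j] = (
                base
                + slope * x / omega
                + bump_size * np.exp(-(((x - bump_age) / 15.0) ** 2))
            )
        w = np.exp(logw)
        profiles[origin] = w / w.sum(axis=1, keepdims=True)
    return profiles


def default_scenario(
    seed: int = 0,
    n_origins: int = 2,
    n_destinations: int = 5,
    exposure_per_age: float = 1e6,
    interval_n: int = 5,
    open_start: int = 85,
    omega: int = 110,
    heaping_strength: float = 0.0,
) -> SyntheticScenario:
    """The default study scenario (five-year groups, open 85+, n = 5).

    Out-migration truths are labour-peak-only model schedules (labour
    component plus a constant floor), giving unimodal one-year schedules
    peaking in the twenties; origins differ slightly in level and peak
    location so that hierarchical standards are exercised.
    """
    origins = tuple(f"O{i + 1}" for i in range(n_origins))
    destinations = tuple(f"D{j + 1}" for j in range(n_destinations))
    out_params = {}
    for i, origin in enumerate(origins):
        out_params[origin] = MMSParams(
            a2=0.05 * (1.0 + 0.1 * i),
            alpha2=0.10,
            mu2=20.0 + 1.5 * i,
            lambda2=0.35,
            c=0.003,
            components=frozenset({"labour"}),
        )
    ratio_profiles = _default_ratio_profiles(origins, destinations, omega, seed)
    population = {
        origin: ExposureCurve(np.full(omega + 1, float(exposure_per_age)))
        for origin in origins
    }
    return SyntheticScenario(
        origins=origins,
        destinations=destinations,
        out_params=out_params,
        ratio_profiles=ratio_profiles,
        population=population,
        grouping=AgeGrouping.five_year(open_start=open_start, omega=omega),
        interval_n=interval_n,
        heaping_strength=heaping_strength,
        seed=seed,
    )


@dataclass(frozen=True)
class TrueCube:
    """The scenario's truth at both the one-year and interval-n scales."""

    one_year_m: dict
    one_year_ratios: dict
    nyr_m: dict
    nyr_dest: dict
    interval_n: int

    def nyr_ratios(self, origin) -> np.ndarray:
        nm = self.nyr_m[origin]
        return self.nyr_dest[origin] / np.clip(nm[:, None], 1e-300, None)


def make_true_cube(scenario: SyntheticScenario) -> TrueCube:
    """Evaluate the scenario's true one-year and interval-n schedules.

    One-year out-migration comes from the model-schedule parameters (must
    stay below 0.5 so probabilities remain meaningful after composition);
    interval-n destination probabilities follow the no-return model
    described in the module docstring.
    """
    omega = scenario.omega
    ages = np.arange(omega + 1, dtype=float)
    n = scenario.interval_n
    one_m, one_c, nyr_m, nyr_dest = {}, {}, {}, {}
    for origin in scenario.origins:
        m = mms_evaluate(scenario.out_params[origin], ages)
        if np.any(m <= 0) or np.any(m >= 0.5):
            raise ValueError(
                f"true one-year out-migration for {origin} must lie in (0, 0.5)"
            )
        c = np.asarray(scenario.ratio_profiles[origin], dtype=float)
        if c.shape != (omega + 1, len(scenario.destinations)):
            raise ValueError("ratio profile shape mismatch")
        if np.any(np.abs(c.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("one-year ratios must sum to 1 over destinations")
        one_m[origin] = m
        one_c[origin] = c
        nyr_m[origin] = compose_multi_year(m, n)
        # no-return model: probability of first out-migrating at age k and
        # choosing destination j, summed over the k within the window
        surv = np.cumprod(np.concatenate([[1.0], 1.0 - m]))
        dest = np.zeros((omega + 1, c.shape[1]))
        for x in range(omega + 1):
            ks = np.arange(x, min(x + n, omega + 1))
            first_move = surv[ks] / surv[x] * m[ks]
            dest[x] = first_move @ c[ks]
        nyr_dest[origin] = dest
    return TrueCube(
        one_year_m=one_m,
        one_year_ratios=one_c,
        nyr_m=nyr_m,
        nyr_dest=nyr_dest,
        interval_n=n,
    )


def sample_counts(
    scenario: SyntheticScenario,
    truth: TrueCube | None = None,
    seed: int | None = None,
) -> dict:
    """Draw grouped mover counts per origin from the scenario's truth.

    For each single year of age the movers are drawn multinomially over
    (destinations, stay) with the interval-n destination probabilities;
    counts are then aggregated to the scenario's age grouping.  Ages not
    covered by any group are discarded.  Reproducible: the same seed gives
    byte-identical tables.
    """
    if truth is None:
        truth = make_true_cube(scenario)
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    omega = scenario.omega
    grouping = scenario.grouping
    mask = grouping.age_mask()
    tables = {}
    for origin in scenario.origins:
        pop = np.round(scenario.population[origin].values).astype(np.int64)
        dest = truth.nyr_dest[origin]
        d = dest.shape[1]
        movers_by_age = np.zeros((omega + 1, d), dtype=np.int64)
        for x in range(omega + 1):
            p = np.concatenate([dest[x], [max(1.0 - dest[x].sum(), 0.0)]])
            p = p / p.sum()
            draw = rng.multinomial(pop[x], p)
            movers_by_age[x] = draw[:d]
        movers = mask @ movers_by_age
        exposures = mask @ pop
        tables[origin] = GroupedMigrationTable(
            grouping=grouping,
            movers=movers.astype(float),
            exposures=exposures.astype(float),
            interval_n=scenario.interval_n,
            destination_labels=scenario.destinations,
            origin_label=origin,
        )
    return tables


def apply_heaping(values: np.ndarray, strength: float) -> np.ndarray:
    """Move a fraction of each age's count to the nearest multiple of 5.

    ``strength`` in [0, 1] is the transferred fraction (ties go to the
    lower multiple); the total population is conserved.  Strength 0 is the
    identity; strength 1 puts all mass on multiples of five.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    v = np.asarray(values, dtype=float)
    out = v * (1.0 - strength)
    for x in range(len(v)):
        lower = 5 * (x // 5)
        upper = lower + 5
        if upper >= len(v) or (x - lower) <= (upper - x):
            target = lower
        else:
            target = upper
        out[target] += strength * v[x]
    return out
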