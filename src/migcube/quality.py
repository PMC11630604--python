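"""Age-reporting quality indices and the pre-estimation grouping policy.

Reported ages in census data often show digit preference (heaping on
multiples of 5 and 10) and old-age overstatement.  Before estimation, data
quality is assessed with three indices and the results drive how ages must
be aggregated:

* Whipple's index W of preference for ages ending in 0 or 5, assessed on
  the single-year window 23..62; W >= 110 (the UN "approximate or worse"
  band) triggers aggregation into five-year groups.
* A sawtooth index ST of residual preference for 0-digits over 5-digits in
  five-year grouped counts; ST >= 1.11 triggers ten-year groups above a
  configurable age (default 40).
* An overstatement index OS comparing the open-age-group share of the
  population over 70 against the same share in a reference population
  (after Coale-Kisker style checks); OS >= 100 drops the open interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

WHIPPLE_THRESHOLD = 110.0
SAWTOOTH_THRESHOLD = 1.11
OVERSTATEMENT_THRESHOLD = 100.0
TEN_YEAR_START_AGE = 40


@dataclass
class QualityReport:
    """Quality indices plus the grouping decisions they imply."""

    whipple: float
    sawtooth: float | None = None
    overstatement: float | None = None
    group_to_5yr: bool = False
    group_to_10yr_above: int | None = None
    drop_open_interval: bool = False

    def to_dict(self) -> dict:
        return {
            "whipple": self.whipple,
            "sawtooth": self.sawtooth,
            "overstatement": self.overstatement,
            "decisions": {
                "group_to_5yr": self.group_to_5yr,
                "group_to_10yr_above": self.group_to_10yr_above,
                "drop_open_interval": self.drop_open_interval,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def whipple_index(counts: np.ndarray, start_age: int = 0) -> float:
    """Whipple's index of digit preference on the window 23..62.

    ``counts`` are single-year population counts; ``counts[i]`` is the
    population aged ``start_age + i``.  W = 100 times the population at
    ages 25, 30, ..., 60 over one fifth of the population aged 23..62;
    uniform counts give 100, complete heaping on multiples of five gives
    500.  Undefined (rejected) if the window is not fully covered.
    """
    counts = np.asarray(counts, dtype=float)
    lo, hi = 23, 62
    if start_age > lo or start_age + len(counts) - 1 < hi:
        raise ValueError("Whipple's index requires single-year counts covering ages 23..62")
    window = counts[lo - start_age : hi - start_age + 1]
    ages = np.arange(lo, hi + 1)
    numer = window[(ages % 5 == 0) & (ages >= 25) & (ages <= 60)].sum()
    denom = window.sum() / 5.0
    if denom <= 0:
        raise ValueError("empty population in the assessment window")
    return float(100.0 * numer / denom)


def sawtooth_index(
    counts5: np.ndarray, start_ages: np.ndarray, min_age: int = 40
) -> float | None:
    """Sawtooth index of 0-digit vs 5-digit preference in five-year groups.

    For each interior five-year group starting at a multiple of 10 within
    the assessed range (``min_age`` and above), the count is compared with
    the mean of its two neighbours: ST is the average of
    ``2 P_i / (P_{i-1} + P_{i+1})``.  Smooth or linear schedules give
    ST = 1; values above 1 indicate decade-heaping surviving the five-year
    grouping.  Returns None when no assessable group exists.
    """
    counts5 = np.asarray(counts5, dtype=float)
    start_ages = np.asarray(start_ages, dtype=int)
    if len(counts5) != len(start_ages):
        raise ValueError("counts and start ages must align")
    in_range = start_ages >= min_age
    if in_range.sum() < 3:
        raise ValueError("need at least 3 consecutive five-year groups in the assessed range")
    terms = []
    for i in range(1, len(counts5) - 1):
        if start_ages[i] % 10 != 0 or start_ages[i] < min_age:
            continue
        if start_ages[i - 1] != start_ages[i] - 5 or start_ages[i + 1] != start_ages[i] + 5:
            continue
        neighbour_sum = counts5[i - 1] + counts5[i + 1]
        if neighbour_sum <= 0:
            continue
        terms.append(2.0 * counts5[i] / neighbour_sum)
    if not terms:
        return None
    return float(np.mean(terms))


def overstatement_index(
    open_count: float,
    count_70_plus: float,
    ref_open_count: float,
    ref_count_70_plus: float,
) -> float:
    """Old-age overstatement index: ratio of open-group shares of the 70+.

    OS = 100 * (open/70+ in the assessed population) divided by the same
    ratio in a reference population (for example a UN estimate for the
    same country and year).  Equal shares give 100; returns NaN when the
    reference share is zero (undefined).
    """
    if count_70_plus <= 0 or ref_count_70_plus <= 0:
        raise ValueError("populations over 70 must be positive")
    ref_share = ref_open_count / ref_count_70_plus
    if ref_share == 0:
        return float("nan")
    share = open_count / count_70_plus
    return float(100.0 * share / ref_share)


def overstatement_from_curves(
    pop: np.ndarray, ref: np.ndarray, open_start: int
) -> float:
    """Overstatement index from two single-year curves and an open-start age."""
    pop = np.asarray(pop, dtype=float)
    ref = np.asarray(ref, dtype=float)
    return overstatement_index(
        pop[open_start:].sum(), pop[70:].sum(), ref[open_start:].sum(), ref[70:].sum()
    )


def grouping_policy(
    whipple: float,
    sawtooth: float | None = None,
    overstatement: float | None = None,
    ten_year_start_age: int = TEN_YEAR_START_AGE,
    whipple_threshold: float = WHIPPLE_THRESHOLD,
    sawtooth_threshold: float = SAWTOOTH_THRESHOLD,
    os_threshold: float = OVERSTATEMENT_THRESHOLD,
) -> QualityReport:
    """Grouping decisions implied by the quality indices.

    W at or above its threshold forces five-year grouping; a high sawtooth
    index additionally forces ten-year groups above ``ten_year_start_age``;
    a high overstatement index drops the open interval.  The decisions are
    a pure function of the indices and thresholds.
    """
    group5 = whipple >= whipple_threshold
    group10 = (
        ten_year_start_age
        if (group5 and sawtooth is not None and sawtooth >= sawtooth_threshold)
        else None
    )
    drop_open = overstatement is not None and overstatement >= os_threshold
    return QualityReport(
        whipple=whipple,
        sawtooth=sawtooth,
        overstatement=overstatement,
        group_to_5yr=group5,
        group_to_10yr_above=group10,
        drop_open_interval=drop_open,
    )
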