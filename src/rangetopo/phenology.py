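"""Fruit-abundance index from fortnightly phenology tables.

For one monitoring period the index of fruit abundance is the sum over
species of (fraction of trees with fruit) x (summed DBH of fruiting trees)
x (species density):

    IFA = sum_i Tf_i * DBH_i * Den_i

Seasons are summarised by the arithmetic mean of the per-period values and
their coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = ["PhenologyRecord", "IFASeries", "ifa", "ifa_series", "season_summary"]


@dataclass(frozen=True)
class PhenologyRecord:
    """One species in one fortnight.

    ``tf`` is the proportion of monitored trees with fruit in [0, 1];
    ``dbh`` the summed diameter at breast height (cm) over sampled fruiting
    trees; ``den`` the species density (trees per hectare).
    """

    species: str
    period: int
    tf: float
    dbh: float
    den: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tf <= 1.0:
            raise ValueError(f"tf must lie in [0, 1], got {self.tf}")
        if self.dbh < 0 or self.den < 0:
            raise ValueError("dbh and den must be non-negative")


def ifa(records: Sequence[PhenologyRecord]) -> float:
    """Index of fruit abundance for a single period.

    All records must share the period and have distinct species; species not
    recorded contribute 0 (no fruiting trees observed).
    """
    if not records:
        return 0.0
    periods = {r.period for r in records}
    if len(periods) != 1:
        raise ValueError(f"records span several periods: {sorted(periods)}")
    species = [r.species for r in records]
    if len(set(species)) != len(species):
        raise ValueError("duplicate species within one period")
    return sum(r.tf * r.dbh * r.den for r in records)


def ifa_series(records: Sequence[PhenologyRecord]) -> dict[int, float]:
    """Per-period index values, keyed by period, periods ascending."""
    by_period: dict[int, list[PhenologyRecord]] = {}
    for r in records:
        by_period.setdefault(r.period, []).append(r)
    return {p: ifa(rows) for p, rows in sorted(by_period.items())}


def season_summary(values: Sequence[float] | Mapping[int, float]) -> tuple[float, float]:
    """Mean and coefficient of variation of a per-period index series.

    Uses the sample (n-1) standard deviation.  When the mean is zero the
    coefficient of variation is undefined and reported as NaN.
    """
    if isinstance(values, Mapping):
        values = list(values.values())
    if len(values) < 2:
        raise ValueError("need at least two periods for a season summary")
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    cv = sd / mean if mean > 0 else float("nan")
    return mean, cv


@dataclass(frozen=True)
class IFASeries:
    """Season-level summary: per-period values plus mean and cv."""

    season: str
    values: dict[int, float]
    mean: float
    cv: float

    @classmethod
    def from_records(cls, records: Sequence[PhenologyRecord], season: str) -> "IFASeries":
        values = ifa_series(records)
        mean, cv = season_summary(values)
        return cls(season=season, values=values, mean=mean, cv=cv)
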