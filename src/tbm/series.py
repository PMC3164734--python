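"""The age-rate series container shared by fitting, forecasting and simulation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["AgeRateSeries"]


@dataclass(frozen=True)
class AgeRateSeries:
    """An observed or simulated table of death rates by age.

    ``ages`` are the point coordinates used for model evaluation; when the
    series was reported in age groups, ``intervals`` holds the half-open
    ``[low, high)`` bounds and ``ages`` their midpoints.  Rates are deaths
    per 100,000 person-years.  ``population`` (persons at risk per row) is
    optional and used for Poisson simulation and group aggregation.
    """

    ages: np.ndarray
    rates: np.ndarray
    intervals: Optional[np.ndarray] = None  # shape (n, 2)
    population: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        ages = np.atleast_1d(np.asarray(self.ages, dtype=float))
        rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if ages.size == 0:
            raise ValueError("series must contain at least one point")
        if ages.shape != rates.shape:
            raise ValueError(
                f"ages and rates differ in length: {ages.size} vs {rates.size}"
            )
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        if self.intervals is not None:
            iv = np.asarray(self.intervals, dtype=float)
            if iv.shape != (ages.size, 2):
                raise ValueError("intervals must have shape (n_points, 2)")
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("intervals must satisfy low < high")
            object.__setattr__(self, "intervals", iv)
        if self.population is not None:
            pop = np.atleast_1d(np.asarray(self.population, dtype=float))
            if pop.shape != ages.shape:
                raise ValueError("population must match ages in length")
            if np.any(pop <= 0):
                raise ValueError("population counts must be positive")
            object.__setattr__(self, "population", pop)

    @classmethod
    def from_intervals(
        cls,
        low,
        high,
        rates,
        population=None,
        label: str = "",
    ) -> "AgeRateSeries":
        """Build an interval series; point coordinates are the midpoints."""
        low = np.asarray(low, dtype=float)
        high = np.asarray(high, dtype=float)
        mid = 0.5 * (low + high)
        return cls(
            ages=mid,
            rates=np.asarray(rates, dtype=float),
            intervals=np.column_stack([low, high]),
            population=population,
            label=label,
        )

    @property
    def n_points(self) -> int:
        return int(self.ages.size)

    @property
    def has_intervals(self) -> bool:
        return self.intervals is not None

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (age or age_low/age_high, rate, population)."""
        if self.has_intervals:
            data = {
                "age_low": self.intervals[:, 0],
                "age_high": self.intervals[:, 1],
                "rate": self.rates,
            }
        else:
            data = {"age": self.ages, "rate": self.rates}
        if self.population is not None:
            data["population"] = self.population
        return pd.DataFrame(data)
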