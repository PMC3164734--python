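"""Synthetic age-rate series with known TBM structure and controlled noise.

Everything downstream of the model core (fitting, forecasting, the CLI) is
testable without external mortality tables: series are generated from known
parameters under no noise, additive Gaussian noise (truncated at zero — rates
cannot be negative) or Poisson count noise at a supplied population at risk.
Randomness always flows through an explicit seed and NumPy's PCG64 generator
(``numpy.random.default_rng``), so identical specifications reproduce
identical series on any platform.

Published parameter sets ship as named fixtures (``table1_fixture``) keyed
``country-year-gender``, e.g. ``"usa-2001-both"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Union

import numpy as np

from .core import PARAMETER_NAMES, ParameterEstimate, TBMParameters, evaluate_rate
from .series import AgeRateSeries

__all__ = [
    "NoiseSpec",
    "generate_series",
    "aggregate_groups",
    "default_age_grid",
    "table1_fixture",
    "fixture_statistics",
    "available_fixtures",
]

RATE_SCALE = 1e5  # rates are per 100,000 person-years


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for simulated series.

    ``kind`` is one of ``"none"``, ``"gaussian"`` (additive i.i.d. noise of
    standard deviation ``sigma`` in rate units, truncated at zero) or
    ``"poisson"`` (death counts drawn at the expectation
    ``rate * population / 100000`` and converted back to rates).  The seed
    is mandatory for the random kinds.
    """

    kind: str = "none"
    sigma: Optional[float] = None
    population: Optional[Union[float, np.ndarray]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.sigma is None or not self.sigma > 0:
                raise ValueError("gaussian noise requires sigma > 0")
            if self.seed is None:
                raise ValueError("gaussian noise requires an explicit seed")
        if self.kind == "poisson":
            pop = self.population
            if pop is None or np.any(np.asarray(pop, dtype=float) <= 0):
                raise ValueError("poisson noise requires population > 0")
            if self.seed is None:
                raise ValueError("poisson noise requires an explicit seed")


def default_age_grid() -> np.ndarray:
    """Single-year ages 10–84, the default support of simulated series."""
    return np.arange(10.0, 85.0)


def generate_series(
    params: TBMParameters,
    ages=None,
    noise: NoiseSpec = NoiseSpec(),
    label: str = "",
) -> AgeRateSeries:
    """Simulate an age-rate series from known TBM parameters.

    ``ages`` may be a 1-D grid of point ages or an ``(n, 2)`` array of
    ``[low, high)`` intervals (evaluated at midpoints).  With no noise the
    rates equal :func:`~tbm.core.evaluate_rate` exactly; the random kinds
    are deterministic given ``noise.seed``.
    """
    if ages is None:
        ages = default_age_grid()
    ages = np.asarray(ages, dtype=float)
    intervals = None
    if ages.ndim == 2:
        intervals = ages
        ages = intervals.mean(axis=1)
    clean = np.asarray(evaluate_rate(ages, params), dtype=float)

    population = None
    if noise.kind == "none":
        rates = clean
    elif noise.kind == "gaussian":
        rng = np.random.default_rng(noise.seed)
        rates = np.maximum(clean + rng.normal(0.0, noise.sigma, clean.shape), 0.0)
    else:  # poisson
        rng = np.random.default_rng(noise.seed)
        population = np.broadcast_to(
            np.asarray(noise.population, dtype=float), clean.shape
        ).copy()
        counts = rng.poisson(clean * population / RATE_SCALE)
        rates = counts / population * RATE_SCALE

    return AgeRateSeries(
        ages=ages,
        rates=rates,
        intervals=intervals,
        population=population,
        label=label,
    )


def aggregate_groups(
    series: AgeRateSeries,
    group_width: float,
    population=None,
) -> AgeRateSeries:
    """Collapse a fine series into wide age groups.

    Emulates the coarse reporting (ten-year groups and similar) that loses
    within-group information; the grouped rate is the population-weighted
    mean of the member rates.  ``population`` falls back on the series' own
    counts and, failing that, on uniform weights.
    """
    if group_width < 1:
        raise ValueError("group_width must be >= 1 year")
    ages = series.ages
    spacing = np.min(np.diff(ages)) if ages.size > 1 else 1.0
    if group_width < spacing:
        raise ValueError(
            f"group_width {group_width} is narrower than the grid spacing {spacing}"
        )
    if population is None:
        population = series.population
    weights = (
        np.ones_like(ages)
        if population is None
        else np.asarray(population, dtype=float)
    )
    if weights.shape != ages.shape:
        raise ValueError("population must match the series length")

    start = np.floor(ages[0])
    # the final edge must lie strictly beyond the last age so no point drops
    n_groups = int(np.ceil((ages[-1] - start + 1e-9) / group_width)) + 1
    edges = start + group_width * np.arange(n_groups + 1)
    low, high, grouped, pop_out = [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (ages >= lo) & (ages < hi)
        if not mask.any():
            continue
        w = weights[mask]
        low.append(lo)
        high.append(hi)
        grouped.append(float(np.average(series.rates[mask], weights=w)))
        pop_out.append(float(w.sum()) if population is not None else np.nan)
    return AgeRateSeries.from_intervals(
        low,
        high,
        grouped,
        population=pop_out if population is not None else None,
        label=series.label,
    )


@lru_cache(maxsize=1)
def _registry() -> dict:
    text = resources.files("tbm").joinpath("fixtures.json").read_text("utf-8")
    return json.loads(text)


def available_fixtures() -> tuple[str, ...]:
    """Keys of the published parameter-set registry."""
    return tuple(_registry()["fixtures"])


def table1_fixture(name: str) -> ParameterEstimate:
    """Published parameter set (values and standard errors) by registry key.

    Keys follow ``country-year-gender`` (see :func:`available_fixtures`).
    Parameters without a standard error were held fixed during the original
    fit.  The returned ``critical_age`` is the reported value.
    """
    reg = _registry()
    try:
        row = reg["fixtures"][name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(reg['fixtures'])}"
        ) from None
    values = {p: row[p][0] for p in PARAMETER_NAMES}
    errors = {p: row[p][1] for p in PARAMETER_NAMES}
    fixed = frozenset(p for p in PARAMETER_NAMES if errors[p] is None)
    params = TBMParameters(exponent=int(reg["exponent"]), **values)
    return ParameterEstimate(
        params=params,
        std_errors=errors,
        critical_age=row["critical_age"][0],
        critical_age_stderr=row["critical_age"][1],
        fixed=fixed,
    )


def fixture_statistics(name: str) -> dict:
    """Reported goodness-of-fit numbers for a fixture (chi-squares, dof, p)."""
    reg = _registry()
    try:
        row = reg["fixtures"][name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(reg['fixtures'])}"
        ) from None
    return {
        k: row[k]
        for k in ("chi2_origin", "chi2_conventional", "dof", "p_value", "year")
    }
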