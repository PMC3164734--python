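"""Rate forecasting by linear extrapolation of per-year fitted parameters.

A future year's curve is predicted in three steps: fit the model to each
past year, extrapolate every parameter (and its standard error) linearly in
calendar year, and evaluate the model at the extrapolated parameter set with
first-order uncertainty propagation.  With exactly two past years the line
interpolates them; with more it is the ordinary least-squares trend.

Bands come from the delta method: the band half-width at each age is the
normal quantile for the requested level times the root of the propagated
parameter variance (confidence band) plus, for prediction bands, a residual
variance term for a new observation.  Cross-parameter covariance is not
propagated — per-parameter errors are what parameter tables report — which
is documented as a caveat rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .core import (
    PARAMETER_NAMES,
    ParameterEstimate,
    TBMParameters,
    critical_age,
    evaluate_rate,
)
from .fitting import (
    FitResult,
    chi_square_conventional,
    p_value as _p_value,
)
from .series import AgeRateSeries

__all__ = [
    "ParameterTrajectory",
    "BandCurve",
    "extrapolate_parameters",
    "predict_curve",
    "evaluate_prediction",
]

EstimateLike = Union[FitResult, ParameterEstimate]

#: Relative step for the central finite differences of the rate with
#: respect to each parameter (of the parameter's own scale).
_FD_RELATIVE_STEP = 1e-6


def _as_estimate(entry: EstimateLike) -> ParameterEstimate:
    if isinstance(entry, FitResult):
        return entry.estimate
    if isinstance(entry, ParameterEstimate):
        return entry
    raise TypeError(
        f"trajectory entries must be FitResult or ParameterEstimate, "
        f"got {type(entry).__name__}"
    )


@dataclass(frozen=True)
class ParameterTrajectory:
    """Per-year parameter estimates ordered by calendar year."""

    entries: tuple[tuple[int, EstimateLike], ...]

    def __post_init__(self) -> None:
        entries = tuple((int(y), _as_estimate(e)) for y, e in self.entries)
        if len(entries) == 0:
            raise ValueError("trajectory must not be empty")
        years = [y for y, _ in entries]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(self, "entries", entries)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(y for y, _ in self.entries)


@dataclass(frozen=True)
class BandCurve:
    """A central rate curve with lower/upper envelopes at a stated level."""

    ages: np.ndarray
    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    band_type: str  # "confidence-band" | "prediction-band"

    def __post_init__(self) -> None:
        for name in ("ages", "central", "lower", "upper"):
            object.__setattr__(
                self, name, np.atleast_1d(np.asarray(getattr(self, name), float))
            )
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")
        if self.band_type not in ("confidence-band", "prediction-band"):
            raise ValueError(f"unknown band_type {self.band_type!r}")
        if np.any(self.lower > self.central) or np.any(self.central > self.upper):
            raise ValueError("band must satisfy lower <= central <= upper")


def _extrapolate_line(years: np.ndarray, values: np.ndarray, target: float) -> float:
    if np.allclose(values, values[0]):
        return float(values[0])  # constant line, exact at any year
    slope, intercept = np.polyfit(years, values, 1)
    return float(slope * target + intercept)


def extrapolate_parameters(
    trajectory: ParameterTrajectory, target_year: int
) -> ParameterEstimate:
    """Extrapolate each parameter linearly in calendar year.

    Values and standard errors are both carried forward by the same linear
    rule (exact through two years, least squares beyond); a parameter fixed
    in every entry stays fixed at its common value.  The reported critical
    age is extrapolated from the entries' reported critical ages.  All
    entries must share the exponent and the fixed-parameter layout.
    """
    entries = trajectory.entries
    if len(entries) < 2:
        raise ValueError("extrapolation needs at least two years")
    estimates = [e for _, e in entries]
    first = estimates[0]
    for est in estimates[1:]:
        if est.params.exponent != first.params.exponent:
            raise ValueError("entries disagree on the exponent")
        if est.fixed != first.fixed:
            raise ValueError("entries disagree on the fixed-parameter layout")

    years = np.asarray(trajectory.years, dtype=float)
    values: dict[str, float] = {}
    errors: dict[str, Optional[float]] = {}
    for name in PARAMETER_NAMES:
        v = np.array([getattr(e.params, name) for e in estimates], dtype=float)
        values[name] = _extrapolate_line(years, v, target_year)
        if name in first.fixed:
            errors[name] = None
        else:
            s = np.array([e.std_errors.get(name) for e in estimates], dtype=float)
            errors[name] = (
                _extrapolate_line(years, s, target_year)
                if np.all(np.isfinite(s))
                else None
            )

    tc_vals = [e.critical_age for e in estimates]
    tc_errs = [e.critical_age_stderr for e in estimates]
    t_c = (
        _extrapolate_line(years, np.asarray(tc_vals, float), target_year)
        if all(v is not None for v in tc_vals)
        else None
    )
    tc_err = (
        _extrapolate_line(years, np.asarray(tc_errs, float), target_year)
        if all(v is not None for v in tc_errs)
        else None
    )

    params = TBMParameters(exponent=first.params.exponent, **values)
    return ParameterEstimate(
        params=params,
        std_errors=errors,
        critical_age=t_c,
        critical_age_stderr=tc_err,
        fixed=first.fixed,
    )


def predict_curve(
    estimate: EstimateLike,
    ages,
    level: float = 0.682,
    band_type: str = "prediction-band",
    residual_variance: float = 0.0,
) -> BandCurve:
    """Evaluate the model with a first-order uncertainty band.

    The central curve is the rate at the central parameter values; the band
    half-width propagates each free parameter's standard error through the
    rate via central finite differences and scales by the normal quantile
    for ``level`` (1.0 at the one-standard-deviation level 0.682).
    ``residual_variance`` (rate units squared) is added inside prediction
    bands to cover a new observation; confidence bands ignore it.
    """
    est = _as_estimate(estimate)
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    params = est.params
    central = np.asarray(evaluate_rate(ages, params), dtype=float)

    var = np.zeros_like(central)
    for name in PARAMETER_NAMES:
        if name in est.fixed:
            continue
        sigma = est.std_errors.get(name)
        if sigma is None:
            raise ValueError(f"missing standard error for free parameter {name!r}")
        if sigma == 0:
            continue
        v = getattr(params, name)
        step = _FD_RELATIVE_STEP * (abs(v) if v != 0 else 1.0)
        hi = params.replace(**{name: v + step})
        lo = params.replace(**{name: v - step})
        grad = (
            np.asarray(evaluate_rate(ages, hi), float)
            - np.asarray(evaluate_rate(ages, lo), float)
        ) / (2 * step)
        var += (grad * sigma) ** 2
    if band_type == "prediction-band":
        var = var + residual_variance

    z = float(norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(var)
    return BandCurve(
        ages=ages,
        central=central,
        lower=central - half,
        upper=central + half,
        level=level,
        band_type=band_type,
    )


def evaluate_prediction(series: AgeRateSeries, params: TBMParameters) -> FitResult:
    """Goodness of a forecast curve against observations, no free parameters.

    Computes the conventional chi-square between the series and the curve at
    the extrapolated parameters with dof equal to the number of points
    (nothing was fitted) and its upper-tail p-value.  The non-conventional
    statistic is reported absent — it belongs to a fitting session.
    """
    expected = np.asarray(evaluate_rate(series.ages, params), dtype=float)
    chi2c = chi_square_conventional(series.rates, expected)
    dof = series.n_points
    return FitResult(
        params=params,
        std_errors={},
        covariance=None,
        var_names=(),
        critical_age=critical_age(params),
        critical_age_stderr=None,
        critical_age_source="derived",
        chi2_origin=None,
        chi2_conventional=chi2c,
        dof=dof,
        p_value=_p_value(chi2c, dof),
        n_points=series.n_points,
        n_excluded=int(np.sum(expected <= 1e-6)),
        iterations=0,
        converged=True,
        fixed=frozenset(PARAMETER_NAMES),
        label=series.label,
    )
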