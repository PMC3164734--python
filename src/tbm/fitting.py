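"""Levenberg–Marquardt estimation of TBM parameters from an age-rate series.

The objective is the unweighted residual sum of squares between observed
rates and the model curve at the series' age coordinates (interval series
are evaluated at midpoints).  Standard errors follow the convention of the
interactive fitting packages this workflow mirrors: the square roots of the
diagonal of the covariance scaled by the residual variance at convergence.
Two goodness-of-fit statistics are reported:

* ``chi_square_origin`` — the non-conventional "reduced" form used by those
  packages, the squared-residual sum divided by (points − free parameters);
* ``chi_square_conventional`` — the Pearson form ``sum((O-E)**2 / E)``,
  from which upper-tail p-values are estimated at dof = points − free
  parameters.

The maturational exponent ``n`` is never optimised (the objective is not
differentiable in an integer); ``select_exponent`` grids over odd candidates
and keeps the fit with the smallest conventional chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import lmfit
import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .core import (
    PARAMETER_NAMES,
    ParameterEstimate,
    TBMParameters,
    critical_age,
    evaluate_rate,
)
from .series import AgeRateSeries

__all__ = [
    "FitConfig",
    "FitResult",
    "FitError",
    "initialize_parameters",
    "fit_tbm",
    "select_exponent",
    "chi_square_origin",
    "chi_square_conventional",
    "p_value",
    "EXPECTED_RATE_FLOOR",
    "DEFAULT_INITIAL",
]

#: Points whose expected rate falls below this floor (ages at or below the
#: critical age, the far tail) are excluded from the conventional chi-square
#: to avoid division by (numerical) zero.
EXPECTED_RATE_FLOOR = 1e-6

#: Package-default starting values for quantities the initialisation
#: heuristics cannot read off the data: threshold (dimensionless),
#: maturation rate (1/years), quiescent drive (1/years), exponent.
DEFAULT_INITIAL = {
    "threshold": 15.0,
    "maturation_rate": 0.1,
    "quiescent_drive": 0.002,
    "exponent": 9,
}


class FitError(RuntimeError):
    """Raised when a fit cannot be set up or every candidate fit fails."""


@dataclass(frozen=True)
class FitConfig:
    """Configuration of a single fit or an exponent scan.

    ``fixed`` names parameters excluded from optimisation (the published
    female fits, for instance, hold ``middle_age`` and ``quiescent_drive``
    constant to achieve convergence).  ``critical_age_free`` switches the
    critical age from the derived closed form to a freely fitted cutoff
    parameter, matching parameter tables that report a standard error for
    it; the choice is recorded on the result.
    """

    initial: TBMParameters
    fixed: frozenset = frozenset()
    exponent_candidates: Sequence[int] = (7, 9, 11, 13, 15)
    max_iterations: int = 500
    tolerance: float = 1e-8
    critical_age_free: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.fixed) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")
        for n in self.exponent_candidates:
            if n < 1 or n % 2 == 0:
                raise ValueError(
                    f"exponent candidates must be odd integers >= 1, got {n}"
                )
        object.__setattr__(self, "fixed", frozenset(self.fixed))


@dataclass(frozen=True)
class FitResult:
    """A converged (or best-so-far) fit with errors and fit statistics."""

    params: TBMParameters
    std_errors: dict[str, Optional[float]]
    covariance: Optional[np.ndarray]
    var_names: tuple[str, ...]
    critical_age: float
    critical_age_stderr: Optional[float]
    critical_age_source: str  # "derived" | "free"
    chi2_origin: Optional[float]
    chi2_conventional: Optional[float]
    dof: int
    p_value: Optional[float]
    n_points: int
    n_excluded: int
    iterations: int
    converged: bool
    fixed: frozenset = frozenset()
    label: str = ""

    @property
    def n_free(self) -> int:
        return len(self.var_names)

    @property
    def estimate(self) -> ParameterEstimate:
        """The parameter-set view used by forecasting."""
        return ParameterEstimate(
            params=self.params,
            std_errors=dict(self.std_errors),
            critical_age=self.critical_age,
            critical_age_stderr=self.critical_age_stderr,
            fixed=self.fixed,
        )


def chi_square_origin(observed, expected, n_free: int) -> float:
    """Non-conventional chi-square: ``sum((O-E)**2) / (N - n_free)``.

    This is the statistic printed by the interactive fitting software's
    reports; dividing the squared-residual sum by points minus free
    parameters (rather than by the expectation) is what makes it differ
    from the Pearson form on the same fit.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have equal length")
    if o.size <= n_free:
        raise ValueError("need more points than free parameters")
    return float(np.sum((o - e) ** 2) / (o.size - n_free))


def chi_square_conventional(
    observed, expected, floor: float = EXPECTED_RATE_FLOOR
) -> float:
    """Pearson chi-square ``sum((O-E)**2 / E)`` over admitted points.

    Points whose expected value is at or below ``floor`` (the model is
    identically zero below the critical age) are excluded; if no point
    survives, the statistic is undefined and an error is raised.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have equal length")
    mask = e > floor
    if not mask.any():
        raise ValueError("no expected value exceeds the floor; statistic undefined")
    return float(np.sum((o[mask] - e[mask]) ** 2 / e[mask]))


def p_value(chi2: float, dof: int) -> float:
    """Upper-tail chi-square survival probability."""
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    return float(_chi2_dist.sf(chi2, dof))


def initialize_parameters(
    series: AgeRateSeries,
    life_expectancy: Optional[float] = None,
    exponent: Optional[int] = None,
) -> TBMParameters:
    """Starting values from the standard initialisation heuristics.

    The middle age starts at half the population's life expectancy when one
    is supplied, otherwise at the series' central plateau (the rate-weighted
    median age).  The product threshold × apex equals the model rate at the
    middle age exactly, so the apex constant is chosen to match the observed
    rate nearest the middle-age start at the default threshold.  The
    remaining constants come from :data:`DEFAULT_INITIAL`.
    """
    rates = series.rates
    if not np.any(rates > 0):
        raise ValueError("cannot initialise from an all-zero series")
    if life_expectancy is not None:
        t_m = life_expectancy / 2.0
    else:
        order = np.cumsum(rates) / rates.sum()
        t_m = float(np.interp(0.5, order, series.ages))
    theta = DEFAULT_INITIAL["threshold"]
    rate_at_tm = float(series.rates[np.argmin(np.abs(series.ages - t_m))])
    if rate_at_tm <= 0:
        rate_at_tm = float(rates[rates > 0].mean())
    return TBMParameters(
        apex_constant=rate_at_tm / theta,
        threshold=theta,
        maturation_rate=DEFAULT_INITIAL["maturation_rate"],
        middle_age=t_m,
        quiescent_drive=DEFAULT_INITIAL["quiescent_drive"],
        exponent=int(exponent if exponent is not None else DEFAULT_INITIAL["exponent"]),
    )


# Lower bounds keeping every trial step inside the model's valid domain.
_BOUNDS = {
    "apex_constant": 1e-12,
    "threshold": 0.0,
    "maturation_rate": 1e-12,
    "middle_age": 0.0,
    "quiescent_drive": -np.inf,
}


def _model_rates(
    ages: np.ndarray, p: lmfit.Parameters, exponent: int, tc_free: bool
) -> np.ndarray:
    params = TBMParameters(
        exponent=exponent, **{name: p[name].value for name in PARAMETER_NAMES}
    )
    rates = np.asarray(evaluate_rate(ages, params), dtype=float)
    if tc_free:
        # Free cutoff: the rate is additionally zeroed below the fitted t_c.
        rates = np.where(ages > p["crit_age"].value, rates, 0.0)
    return rates


def _derived_tc_stderr(
    params: TBMParameters,
    var_names: Sequence[str],
    covar: Optional[np.ndarray],
) -> Optional[float]:
    """First-order (delta-method) error of t_c = t_m - theta^(1/n)/a."""
    if covar is None:
        return None
    th, a, n = params.threshold, params.maturation_rate, params.exponent
    grads = {
        "middle_age": 1.0,
        "threshold": (-th ** (1.0 / n - 1.0) / (n * a)) if th > 0 else 0.0,
        "maturation_rate": th ** (1.0 / n) / a**2,
    }
    g = np.array([grads.get(name, 0.0) for name in var_names])
    var = float(g @ covar @ g)
    return float(np.sqrt(var)) if var >= 0 else None


def fit_tbm(series: AgeRateSeries, config: FitConfig) -> FitResult:
    """Fit the TBM to a series by Levenberg–Marquardt least squares.

    Returns a complete :class:`FitResult`; non-convergence within the
    iteration cap is flagged (``converged=False``) with the best-so-far
    state rather than raised.  A singular covariance leaves the standard
    errors absent with a warning.
    """
    init = config.initial
    tc_free = config.critical_age_free
    n_free = (len(PARAMETER_NAMES) - len(config.fixed)) + (1 if tc_free else 0)
    if series.n_points <= n_free:
        raise ValueError(
            f"series has {series.n_points} points but the fit has {n_free} "
            "free parameters; need more points than free parameters"
        )

    pars = lmfit.Parameters()
    for name in PARAMETER_NAMES:
        pars.add(
            name,
            value=getattr(init, name),
            vary=name not in config.fixed,
            min=_BOUNDS[name],
        )
    if tc_free:
        pars.add("crit_age", value=critical_age(init), min=0.0)

    ages, rates = series.ages, series.rates

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return _model_rates(ages, p, init.exponent, tc_free) - rates

    minimizer = lmfit.Minimizer(residual, pars)
    out = minimizer.minimize(
        method="leastsq",
        max_nfev=config.max_iterations * (n_free + 1),
        xtol=config.tolerance,
        ftol=config.tolerance,
    )

    fitted = TBMParameters(
        exponent=init.exponent,
        **{name: out.params[name].value for name in PARAMETER_NAMES},
    )
    std_errors: dict[str, Optional[float]] = {}
    for name in PARAMETER_NAMES:
        if name in config.fixed:
            std_errors[name] = None
        else:
            std_errors[name] = (
                float(out.params[name].stderr)
                if out.params[name].stderr is not None
                else None
            )
    if any(
        std_errors[name] is None
        for name in PARAMETER_NAMES
        if name not in config.fixed
    ):
        warnings.warn(
            "singular covariance at convergence; standard errors reported absent",
            RuntimeWarning,
            stacklevel=2,
        )

    covar = out.covar.copy() if out.covar is not None else None
    var_names = tuple(out.var_names)

    if tc_free:
        t_c = float(out.params["crit_age"].value)
        tc_err = (
            float(out.params["crit_age"].stderr)
            if out.params["crit_age"].stderr is not None
            else None
        )
        tc_source = "free"
    else:
        t_c = critical_age(fitted)
        tc_err = _derived_tc_stderr(fitted, var_names, covar)
        tc_source = "derived"

    expected = _model_rates(ages, out.params, init.exponent, tc_free)
    dof = series.n_points - out.nvarys
    chi2o = chi_square_origin(rates, expected, out.nvarys)
    n_excl = int(np.sum(expected <= EXPECTED_RATE_FLOOR))
    try:
        chi2c = chi_square_conventional(rates, expected)
    except ValueError:
        chi2c = None
    pval = p_value(chi2c, dof) if (chi2c is not None and dof >= 1) else None

    return FitResult(
        params=fitted,
        std_errors=std_errors,
        covariance=covar,
        var_names=var_names,
        critical_age=t_c,
        critical_age_stderr=tc_err,
        critical_age_source=tc_source,
        chi2_origin=chi2o,
        chi2_conventional=chi2c,
        dof=dof,
        p_value=pval,
        n_points=series.n_points,
        n_excluded=n_excl,
        iterations=int(out.nfev),
        converged=bool(out.success),
        fixed=config.fixed,
        label=series.label,
    )


def select_exponent(series: AgeRateSeries, config: FitConfig) -> FitResult:
    """Fit once per odd exponent candidate and keep the best.

    The published selection criterion is multi-objective (standard errors,
    chi-square, band widths); its only scalar member is the chi-square, so
    the fit with the smallest conventional chi-square wins, ties broken
    toward the smaller (more parsimonious) exponent.
    """
    results: dict[int, FitResult] = {}
    failures: dict[int, str] = {}
    for n in sorted(config.exponent_candidates):
        try:
            cfg_n = replace(config, initial=config.initial.replace(exponent=int(n)))
            res = fit_tbm(series, cfg_n)
            if res.chi2_conventional is None:
                raise FitError("conventional chi-square undefined")
            results[int(n)] = res
        except Exception as exc:  # aggregate per-candidate diagnostics
            failures[int(n)] = f"{type(exc).__name__}: {exc}"
    if not results:
        detail = "; ".join(f"n={n}: {msg}" for n, msg in failures.items())
        raise FitError(f"every exponent candidate failed ({detail})")
    best_n = min(results, key=lambda n: (results[n].chi2_conventional, n))
    return results[best_n]
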