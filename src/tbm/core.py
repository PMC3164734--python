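"""Closed-form evaluation of the Threshold Bias Model (TBM).

The TBM describes age-specific suicide rates as a piecewise distribution:
zero at and below a critical age ``t_c`` and, above it, the product of a
*threshold-bias* factor (self-destructive impulsivity) and a *consciousness*
factor (planning capacity).  The building blocks are

* the average drive function ``D(t) = d0 - [a (t - t_m)]**n`` — a decreasing,
  odd-symmetric function of age with its inflection point at the middle age
  ``t_m``, positive in youth ("life drives" dominate), approximately ``d0``
  near ``t_m``, and negative in old age ("death drives" dominate);
* the consciousness function ``C(t)``, the solution of the growth law
  ``dC/dt = C * D(t)`` anchored so that ``C(t_m) = K`` (the apex constant):
  ``C(t) = K * exp(d0*(t-t_m) - [a*(t-t_m)]**(n+1) / ((n+1)*a))``;
* the threshold-bias factor ``B(t) = theta + [a (t - t_m)]**n``, the excess of
  the drive's deviation over the threshold ``theta``; its root defines the
  critical age ``t_c = t_m - theta**(1/n) / a``.

The rate is ``S(t) = B(t) * C(t)`` for ``t > t_c`` and ``0`` otherwise, so
that ``S(t_m) = theta * K`` exactly.  When ``theta -> 0``, ``d0 -> 0`` and
``t_m -> 0`` the rate is proportional to a Weibull density of shape ``n + 1``.

All evaluation functions are vectorised over age.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "TBMParameters",
    "ParameterEstimate",
    "InvalidParameterError",
    "PARAMETER_NAMES",
    "average_drive",
    "consciousness",
    "log_consciousness",
    "threshold_bias",
    "critical_age",
    "evaluate_rate",
]

#: Fitted-parameter names, in the conventional reporting order
#: (apex constant K, threshold theta, maturation rate a, middle age t_m,
#: quiescent drive d0).  The exponent n is fixed, not fitted.
PARAMETER_NAMES = (
    "apex_constant",
    "threshold",
    "maturation_rate",
    "middle_age",
    "quiescent_drive",
)


class InvalidParameterError(ValueError):
    """Raised when a TBM parameter set violates the model's constraints."""


@dataclass(frozen=True)
class TBMParameters:
    """The six TBM parameters plus the fixed odd maturational exponent.

    Parameters
    ----------
    apex_constant : float
        Rate-scale constant ``K`` (> 0), the cohort's average apex of mental
        skills; arises as the integration constant of the consciousness
        growth law.
    threshold : float
        Threshold parameter ``theta`` (>= 0, dimensionless as reported); the
        shift from the average drive required to trigger suicidal behaviour,
        an indicator of average suicidal impulsivity.
    maturation_rate : float
        Maturational constant ``a`` (> 0), units 1/years.
    middle_age : float
        Middle age ``t_m`` (>= 0), years; inflection point of the drive
        function.
    quiescent_drive : float
        Quiescent drive constant ``d0``, units 1/years; the drive function's
        value at the middle age.  May be zero or slightly negative.
    exponent : int
        Odd maturational exponent ``n`` >= 1 (fixed during fitting; 9 by
        default, 7–15 recommended).
    """

    apex_constant: float
    threshold: float
    maturation_rate: float
    middle_age: float
    quiescent_drive: float
    exponent: int = 9

    def __post_init__(self) -> None:
        n = self.exponent
        if not (isinstance(n, (int, np.integer)) and n >= 1 and n % 2 == 1):
            raise InvalidParameterError(
                f"exponent must be an odd integer >= 1, got {n!r}"
            )
        if not self.apex_constant > 0:
            raise InvalidParameterError("apex_constant must be > 0")
        if not self.maturation_rate > 0:
            raise InvalidParameterError("maturation_rate must be > 0")
        if self.middle_age < 0:
            raise InvalidParameterError("middle_age must be >= 0")
        if self.threshold < 0:
            # theta < 0 leaves the threshold-crossing equation without a
            # root below the middle age.
            raise InvalidParameterError(
                "threshold must be >= 0 (no real critical age otherwise)"
            )

    def replace(self, **changes: Union[float, int]) -> "TBMParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        """Fitted parameters as an ordered name -> value mapping."""
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


@dataclass(frozen=True)
class ParameterEstimate:
    """A parameter set together with reported standard errors.

    ``critical_age`` holds the *reported* critical age (a freely fitted
    quantity in published parameter tables), which need not coincide with the
    closed-form root of the threshold-crossing equation; use
    :func:`critical_age` for the derived value.  ``fixed`` names parameters
    held constant (they carry no standard error).
    """

    params: TBMParameters
    std_errors: Mapping[str, Union[float, None]] = field(default_factory=dict)
    critical_age: Union[float, None] = None
    critical_age_stderr: Union[float, None] = None
    fixed: frozenset = frozenset()

    def stderr(self, name: str) -> Union[float, None]:
        return self.std_errors.get(name)


def _check_params(params: TBMParameters) -> TBMParameters:
    if not isinstance(params, TBMParameters):
        raise TypeError(f"expected TBMParameters, got {type(params).__name__}")
    return params


def average_drive(age, params: TBMParameters):
    """Average drive ``D(age) = d0 - [a (age - t_m)]**n``.

    ``D`` fuses "life drives" and "death drives": strictly decreasing,
    odd-symmetric about ``(t_m, d0)`` with an inflection point at ``t_m``
    (for exponent >= 3), diverging to ``+inf``/``-inf`` as age decreases/
    increases without bound.
    """
    _check_params(params)
    t = np.asarray(age, dtype=float)
    u = params.maturation_rate * (t - params.middle_age)
    out = params.quiescent_drive - u ** params.exponent
    return out if out.ndim else float(out)


def log_consciousness(age, params: TBMParameters):
    """``log(C(age) / K)``: the antiderivative of the drive, zero at ``t_m``.

    Useful when ``C`` itself underflows (the even-power decay is fierce far
    from the middle age).
    """
    _check_params(params)
    t = np.asarray(age, dtype=float)
    a, n = params.maturation_rate, params.exponent
    x = t - params.middle_age
    u = a * x
    out = params.quiescent_drive * x - u ** (n + 1) / ((n + 1) * a)
    return out if out.ndim else float(out)


def consciousness(age, params: TBMParameters):
    """Consciousness level ``C(age)``, solution of ``dC/dt = C * D(t)``.

    The integration constant is fixed at the middle age, ``C(t_m) = K``,
    which makes the rate at the middle age equal the product of the
    threshold and the apex constant.  ``C`` is positive for all finite ages
    and decays towards zero in the limit of very advanced ages (returned as
    an exact floating-point 0 once the exponent underflows).
    """
    lc = np.asarray(log_consciousness(age, params))
    with np.errstate(over="ignore", under="ignore"):
        out = params.apex_constant * np.exp(lc)
    return out if out.ndim else float(out)


def threshold_bias(age, params: TBMParameters):
    """Threshold-bias factor ``B(age) = theta + [a (age - t_m)]**n``.

    Represents self-destructive impulsivity: the excess of the drive's
    deviation from its quiescent value over the threshold ``theta``.
    ``B`` crosses zero at the critical age and increases with age beyond it.
    """
    _check_params(params)
    t = np.asarray(age, dtype=float)
    u = params.maturation_rate * (t - params.middle_age)
    out = params.threshold + u ** params.exponent
    return out if out.ndim else float(out)


def critical_age(params: TBMParameters) -> float:
    """Critical age ``t_c = t_m - theta**(1/n) / a``.

    The root of the threshold-crossing equation ``B(t_c) = 0``: the age
    below which the modelled rate is exactly zero.  Always real and at or
    below the middle age for ``theta >= 0`` (equal exactly when the
    threshold vanishes).
    """
    _check_params(params)
    th, a, n = params.threshold, params.maturation_rate, params.exponent
    return params.middle_age - th ** (1.0 / n) / a


def evaluate_rate(age, params: TBMParameters):
    """TBM rate ``S(age)`` in deaths per 100,000 per year.

    Piecewise: ``0`` for ``age <= t_c`` and ``B(age) * C(age)`` above the
    critical age.  Vectorised; ages must be non-negative.
    """
    _check_params(params)
    t = np.asarray(age, dtype=float)
    if np.any(t < 0):
        raise ValueError("ages must be >= 0")
    tc = critical_age(params)
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        raw = threshold_bias(t, params) * consciousness(t, params)
    raw = np.asarray(raw)
    # inf * 0 far beyond the old-age peak: the exponential decay wins.
    raw = np.where(np.isnan(raw), 0.0, raw)
    out = np.where(t > tc, raw, 0.0)
    return out if out.ndim else float(out)
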