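"""Reading rate tables and writing fit reports and curve exports.

Rate tables are delimited text (comma for ``.csv``, tab for ``.tsv``) with a
header row naming either ``age`` or ``age_low``/``age_high`` plus ``rate``
and an optional ``population`` column.  Lines starting with ``#`` are
comments; ``# key: value`` comments carry metadata (``label``, ``year``,
``units``).  Fit reports are JSON documents with schema tag
``tbm-report/1``; numeric fields round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import PARAMETER_NAMES, TBMParameters
from .fitting import FitResult
from .forecasting import BandCurve
from .series import AgeRateSeries

__all__ = [
    "RateTableError",
    "read_rate_table",
    "write_rate_table",
    "write_fit_report",
    "read_fit_report",
    "write_curve_csv",
    "REPORT_SCHEMA",
]

REPORT_SCHEMA = "tbm-report/1"


class RateTableError(ValueError):
    """A malformed rate table; the message names the offending line."""


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_rate_table(path: Union[str, Path]) -> AgeRateSeries:
    """Parse a delimited rate table into a validated series.

    Interval columns (``age_low``/``age_high``) produce an interval-typed
    series; malformed rows raise :class:`RateTableError` naming the line.
    """
    path = Path(path)
    sep = _delimiter(path)
    meta: dict[str, str] = {}
    header: Optional[list[str]] = None
    rows: list[tuple[int, list[str]]] = []  # (1-based line number, cells)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip().lower()] = value.strip()
                continue
            cells = [c.strip() for c in line.split(sep)]
            if header is None:
                header = [c.lower() for c in cells]
            else:
                rows.append((lineno, cells))
    if header is None or not rows:
        raise RateTableError(f"{path}: no header or data rows found")

    interval = "age_low" in header and "age_high" in header
    required = (["age_low", "age_high"] if interval else ["age"]) + ["rate"]
    for col in required:
        if col not in header:
            raise RateTableError(f"{path}: missing required column {col!r}")
    idx = {name: header.index(name) for name in header}

    def cell(lineno: int, cells: list[str], col: str) -> float:
        try:
            return float(cells[idx[col]])
        except (IndexError, ValueError):
            raise RateTableError(
                f"{path}:{lineno}: cannot parse column {col!r}"
            ) from None

    lows, highs, ages, rates, pops = [], [], [], [], []
    has_pop = "population" in header
    for lineno, cells in rows:
        if interval:
            lo = cell(lineno, cells, "age_low")
            hi = cell(lineno, cells, "age_high")
            if hi <= lo:
                raise RateTableError(f"{path}:{lineno}: age_high must exceed age_low")
            lows.append(lo)
            highs.append(hi)
            age = 0.5 * (lo + hi)
        else:
            age = cell(lineno, cells, "age")
        r = cell(lineno, cells, "rate")
        if r < 0:
            raise RateTableError(f"{path}:{lineno}: negative rate {r}")
        if ages and age <= ages[-1]:
            raise RateTableError(
                f"{path}:{lineno}: ages must be strictly increasing"
            )
        ages.append(age)
        rates.append(r)
        if has_pop:
            pops.append(cell(lineno, cells, "population"))

    label = meta.get("label", "")
    kwargs = dict(
        population=np.asarray(pops) if has_pop else None,
        label=label,
    )
    if interval:
        return AgeRateSeries.from_intervals(lows, highs, rates, **kwargs)
    return AgeRateSeries(ages=np.asarray(ages), rates=np.asarray(rates), **kwargs)


def write_rate_table(
    series: AgeRateSeries, path: Union[str, Path], metadata: Optional[dict] = None
) -> None:
    """Write a series as a delimited rate table (format of read_rate_table)."""
    path = Path(path)
    sep = _delimiter(path)
    frame = series.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        if series.label:
            fh.write(f"# label: {series.label}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep=sep, index=False)


def _result_to_dict(result: FitResult, year: Optional[int] = None) -> dict:
    doc = {
        "schema": REPORT_SCHEMA,
        "label": result.label,
        "parameters": result.params.as_dict(),
        "exponent": result.params.exponent,
        "std_errors": dict(result.std_errors),
        "fixed": sorted(result.fixed),
        "var_names": list(result.var_names),
        "covariance": (
            np.asarray(result.covariance).tolist()
            if result.covariance is not None
            else None
        ),
        "critical_age": result.critical_age,
        "critical_age_stderr": result.critical_age_stderr,
        "critical_age_source": result.critical_age_source,
        "chi2_origin": result.chi2_origin,
        "chi2_conventional": result.chi2_conventional,
        "dof": result.dof,
        "p_value": result.p_value,
        "n_points": result.n_points,
        "n_excluded": result.n_excluded,
        "iterations": result.iterations,
        "converged": result.converged,
    }
    if year is not None:
        doc["year"] = int(year)
    return doc


def write_fit_report(
    result: FitResult, path: Union[str, Path], year: Optional[int] = None
) -> None:
    """Serialise a fit result as a versioned JSON report."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_result_to_dict(result, year), fh, indent=2)
        fh.write("\n")


def read_fit_report(path: Union[str, Path]) -> tuple[FitResult, Optional[int]]:
    """Load a JSON fit report; returns the result and the year tag (if any)."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema") != REPORT_SCHEMA:
        raise ValueError(f"{path}: unsupported report schema {doc.get('schema')!r}")
    params = TBMParameters(exponent=int(doc["exponent"]), **doc["parameters"])
    result = FitResult(
        params=params,
        std_errors={k: doc["std_errors"].get(k) for k in PARAMETER_NAMES},
        covariance=(
            np.asarray(doc["covariance"]) if doc["covariance"] is not None else None
        ),
        var_names=tuple(doc["var_names"]),
        critical_age=doc["critical_age"],
        critical_age_stderr=doc["critical_age_stderr"],
        critical_age_source=doc["critical_age_source"],
        chi2_origin=doc["chi2_origin"],
        chi2_conventional=doc["chi2_conventional"],
        dof=doc["dof"],
        p_value=doc["p_value"],
        n_points=doc["n_points"],
        n_excluded=doc["n_excluded"],
        iterations=doc["iterations"],
        converged=doc["converged"],
        fixed=frozenset(doc["fixed"]),
        label=doc.get("label", ""),
    )
    return result, doc.get("year")


def write_curve_csv(
    curve: BandCurve,
    path: Union[str, Path],
    observed: Optional[AgeRateSeries] = None,
) -> None:
    """Export a banded curve as CSV (age, observed, fitted, lower, upper)."""
    data = {"age": curve.ages}
    if observed is not None:
        obs = np.full_like(curve.ages, np.nan)
        common, ia, ib = np.intersect1d(
            curve.ages, observed.ages, return_indices=True
        )
        obs[ia] = observed.rates[ib]
        data["observed"] = obs
    data.update(fitted=curve.central, lower=curve.lower, upper=curve.upper)
    pd.DataFrame(data).to_csv(path, index=False)
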