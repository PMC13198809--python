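"""Precision and trend-assessment statistics for longitudinal monitoring.

For each parameter/sex/site stratum this module computes the descriptive
row of a monitoring table: mean mu, SD sigma, coefficient of variation
sigma/mu, the short-term precision error PE_st (root-mean-square percent
CV over same-day repeat scans), the median relative change per annum of
the fitted normative curve, and the short-term trend assessment interval

    TAI_st = 1.8 * PE_st / |median annual change|   [years],

the follow-up time after which the expected age-related change exceeds the
measurement precision margin.  A parameter with zero trend has an infinite
TAI and is flagged "not assessable".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_data import ParticipantRecord, Sex, Site
from .reference_curves import ReferenceCurve, evaluate_curve

__all__ = [
    "PrecisionSummary",
    "TREND_ASSESSMENT_FACTOR",
    "DEFAULT_AGE_GRID",
    "cohort_mu_sigma",
    "precision_error_st",
    "median_annual_change",
    "trend_assessment_interval",
    "summarize_stratum",
]

#: Margin by which an expected change must exceed the short-term precision
#: error before it is considered detectable (monitoring convention; verified
#: to reproduce the published TAI columns from the PE and rate columns).
TREND_ASSESSMENT_FACTOR = 1.8

#: Integer evaluation ages for the older-branch relative slope.
DEFAULT_AGE_GRID: tuple[float, ...] = tuple(float(a) for a in range(38, 93))


@dataclass
class PrecisionSummary:
    """One monitoring-table row for a parameter/sex/site stratum."""

    parameter: str
    sex: Sex
    site: Site
    mu: float
    sigma: float
    cv: float
    pe_st: float | None = None  # percent
    annual_change: float | None = None  # percent per year, signed
    tai_st: float | None = None  # years; math.inf = not assessable

    @property
    def assessable(self) -> bool:
        return self.tai_st is not None and math.isfinite(self.tai_st)

    def as_row(self) -> dict[str, object]:
        """Serializable row; rounding (3 dp) happens only here."""
        rnd = lambda v: None if v is None else round(v, 3)
        return {
            "parameter": self.parameter,
            "sex": self.sex.value,
            "site": self.site.value,
            "mu": rnd(self.mu),
            "sigma": rnd(self.sigma),
            "cv": rnd(self.cv),
            "pe_st": rnd(self.pe_st),
            "annual_change": rnd(self.annual_change),
            "tai_st": None
            if self.tai_st is None or not math.isfinite(self.tai_st)
            else round(self.tai_st, 3),
            "not_assessable": self.tai_st is not None and not math.isfinite(self.tai_st),
        }


def cohort_mu_sigma(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean, SD (n-1 denominator) and coefficient of variation sigma/mu."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 values, got {arr.size}")
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=1))
    if mu == 0.0:
        raise ValueError("mean is zero; CV undefined")
    return mu, sigma, sigma / mu


def precision_error_st(repeat_groups: Iterable[Sequence[float]]) -> float:
    """Short-term precision error: RMS of per-participant percent CVs.

    ``repeat_groups`` holds one list of same-day repeat measurements per
    participant (baseline + repeats, >= 2 values each).
    """
    cvs = []
    for i, group in enumerate(repeat_groups):
        arr = np.asarray(group, dtype=float)
        if arr.size < 2:
            raise ValueError(f"participant group {i} has {arr.size} scan(s); need >= 2")
        cvs.append(arr.std(ddof=1) / arr.mean())
    if not cvs:
        raise ValueError("no repeat groups supplied")
    return 100.0 * float(np.sqrt(np.mean(np.square(cvs))))


def median_annual_change(
    curve: ReferenceCurve, age_grid: Sequence[float] = DEFAULT_AGE_GRID
) -> float:
    """Median over the age grid of the relative slope 100*y'(x)/y(x) [%/yr].

    y'(x) = b + 2c*x = 2c(x - t*) on the quadratic branch.  The curve must
    stay positive over the grid.
    """
    grid = np.asarray(age_grid, dtype=float)
    y = np.array([evaluate_curve(curve, a) for a in grid])
    if np.any(y <= 0):
        raise ValueError("curve is non-positive on the evaluation grid")
    slopes = np.where(
        grid <= curve.threshold, 0.0, 2.0 * curve.c * (grid - curve.threshold)
    )
    return float(np.median(100.0 * slopes / y))


def trend_assessment_interval(pe_st: float, annual_change: float) -> float:
    """TAI_st = 1.8 * PE_st / |annual change| in years (inf when no trend)."""
    if pe_st < 0:
        raise ValueError("pe_st must be >= 0")
    if annual_change == 0.0:
        return math.inf
    return TREND_ASSESSMENT_FACTOR * pe_st / abs(annual_change)


def summarize_stratum(
    records: Iterable[ParticipantRecord],
    parameter: str,
    sex: Sex | str,
    site: Site | str,
    curve: ReferenceCurve | None = None,
    pe_st: float | None = None,
    age_grid: Sequence[float] = DEFAULT_AGE_GRID,
) -> PrecisionSummary:
    """Assemble one monitoring-table row.

    mu/sigma/cv come from all baseline values of the stratum.  PE_st is
    computed from same-day repeats present in ``records`` or supplied as an
    imported constant via ``pe_st`` (published repeatability studies);
    explicit ``pe_st`` wins.  The trend columns need a fitted ``curve``.
    """
    sex, site = Sex(sex), Site(site)
    mine = [r for r in records if r.sex == sex and r.site == site and parameter in r.measurements]
    baseline = [r.measurements[parameter] for r in mine if r.repeat_index == 0]
    mu, sigma, cv = cohort_mu_sigma(baseline)

    if pe_st is None:
        groups: dict[str, list[float]] = {}
        for r in mine:
            groups.setdefault(r.participant_id, []).append(r.measurements[parameter])
        repeat_groups = [g for g in groups.values() if len(g) >= 2]
        if repeat_groups:
            pe_st = precision_error_st(repeat_groups)

    annual = median_annual_change(curve, age_grid) if curve is not None else None
    tai = (
        trend_assessment_interval(pe_st, annual)
        if pe_st is not None and annual is not None
        else None
    )
    return PrecisionSummary(parameter, sex, site, mu, sigma, cv, pe_st, annual, tai)


def summary_table(summaries: Iterable[PrecisionSummary]) -> pd.DataFrame:
    """Monitoring table (one row per summary), rounded for serialization."""
    return pd.DataFrame([s.as_row() for s in summaries])
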