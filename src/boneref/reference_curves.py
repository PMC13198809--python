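"""Constrained piecewise normative model, T/Z-scores and reference bands.

The age trend of each parameter is modelled as a plateau up to a threshold
age t* (default 37 yr) followed by a quadratic decline:

    y(x) = ybar                      for x <= t*
    y(x) = a + b*x + c*x**2          for x >  t*

with continuity and zero slope at t*:

    b + 2*c*t* = 0
    a + b*t* + c*t***2 = ybar

These constraints eliminate a and b, so the old-group fit reduces to a
one-parameter linear least squares y = ybar + c*(x - t*)**2 with the
closed-form solution

    c = sum_i (y_i - ybar) * (x_i - t*)**2 / sum_i (x_i - t*)**4 ,

where ybar and sigma_young are the mean and SD of the young group alone.

T-scores compare a value to the young reference, (X - ybar)/sigma_young;
Z-scores compare to the age-specific expected value, (X - y(age))/sigma_young.
The dispersion is the constant young-cohort SD at all ages (no age-resolved
variance is modelled).  Scores are classified into traffic-light bands:
green [-1, 2], yellow [-2.5, -1), red [-3.5, -2.5) SD, half-open on the
upper side within the negative range so the bands partition the axis.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_data import AGE_THRESHOLD, ParticipantRecord, Sex, Site, baseline_values

__all__ = [
    "ReferenceCurve",
    "ReferenceBandSpec",
    "TScoreProfile",
    "CurveStore",
    "FitError",
    "fit_reference_curve",
    "evaluate_curve",
    "t_score",
    "z_score",
    "classify_band",
    "curve_band_table",
]

_CONSTRAINT_RTOL = 1e-10


class FitError(ValueError):
    """Raised when a reference fit is impossible (too few data, degenerate design)."""


@dataclass
class ReferenceCurve:
    """Fitted piecewise constant+quadratic normative curve for one parameter."""

    parameter: str
    sex: Sex
    site: Site
    threshold: float
    baseline_mean: float
    baseline_sd: float
    a: float
    b: float
    c: float
    age_validity: tuple[float, float] = (20.0, 92.0)
    n_young: int = 0
    n_old: int = 0

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.site = Site(self.site)
        tol = _CONSTRAINT_RTOL * max(1.0, abs(self.baseline_mean))
        slope = self.b + 2.0 * self.c * self.threshold
        cont = self.a + self.b * self.threshold + self.c * self.threshold**2 - self.baseline_mean
        if abs(slope) > tol:
            raise ValueError(f"zero-slope constraint violated: |b + 2*c*t*| = {abs(slope):.3e}")
        if abs(cont) > tol:
            raise ValueError(f"continuity constraint violated: residual = {abs(cont):.3e}")

    @classmethod
    def from_curvature(
        cls,
        parameter: str,
        sex: Sex | str,
        site: Site | str,
        baseline_mean: float,
        baseline_sd: float,
        c: float,
        threshold: float = AGE_THRESHOLD,
        **kwargs,
    ) -> "ReferenceCurve":
        """Build a curve from (ybar, sigma, c) with a, b set by the constraints."""
        b = -2.0 * c * threshold
        a = baseline_mean - b * threshold - c * threshold**2
        return cls(
            parameter=parameter,
            sex=Sex(sex),
            site=Site(site),
            threshold=threshold,
            baseline_mean=baseline_mean,
            baseline_sd=baseline_sd,
            a=a,
            b=b,
            c=c,
            **kwargs,
        )

    # Convenience wrappers -------------------------------------------------
    def __call__(self, age: float) -> float:
        return evaluate_curve(self, age)

    def annual_relative_slope(self, age: float) -> float:
        """100 * y'(age)/y(age) [%/yr]; zero on the plateau."""
        if age <= self.threshold:
            return 0.0
        return 100.0 * 2.0 * self.c * (age - self.threshold) / evaluate_curve(self, age)


@dataclass(frozen=True)
class ReferenceBandSpec:
    """Traffic-light score bands in SD units (green/yellow/red)."""

    green: tuple[float, float] = (-1.0, 2.0)
    yellow: tuple[float, float] = (-2.5, -1.0)
    red: tuple[float, float] = (-3.5, -2.5)

    def __post_init__(self) -> None:
        if not (self.red[0] < self.red[1] <= self.yellow[0] < self.yellow[1] <= self.green[0] < self.green[1]):
            raise ValueError("bands must be ordered red < yellow < green and disjoint")


@dataclass
class TScoreProfile:
    """Six-parameter T-score vector for one age/participant."""

    age: float
    sex: Sex
    site: Site
    scores: dict[str, float] = field(default_factory=dict)
    bands: dict[str, str] = field(default_factory=dict)
    label: str = ""


def fit_reference_curve(
    records: Iterable[ParticipantRecord],
    parameter: str,
    sex: Sex | str,
    site: Site | str,
    threshold: float = AGE_THRESHOLD,
) -> ReferenceCurve:
    """Fit the constrained plateau+quadratic model for one parameter/sex/site.

    Uses baseline scans only.  The young-group mean and SD (n-1 denominator)
    are estimated first and held fixed; the curvature c is then the
    closed-form least-squares solution on the old group.
    """
    sex, site = Sex(sex), Site(site)
    pairs = [
        (age, value)
        for age, value in baseline_values(
            (r for r in records if r.sex == sex and r.site == site), parameter
        )
    ]
    young = [(x, y) for x, y in pairs if x <= threshold]
    old = [(x, y) for x, y in pairs if x > threshold]
    if len(young) < 2:
        raise FitError(f"need >= 2 young records for {parameter}, got {len(young)}")
    if len(old) < 3:
        raise FitError(f"need >= 3 old records for {parameter}, got {len(old)}")

    yv = np.array([y for _, y in young])
    ybar = float(yv.mean())
    sigma = float(yv.std(ddof=1))

    x_old = np.array([x for x, _ in old])
    y_old = np.array([y for _, y in old])
    d2 = (x_old - threshold) ** 2
    denom = float(np.sum(d2**2))
    if denom == 0.0:
        raise FitError("degenerate design: all old-group ages equal the threshold")
    c = float(np.sum((y_old - ybar) * d2) / denom)

    return ReferenceCurve.from_curvature(
        parameter,
        sex,
        site,
        baseline_mean=ybar,
        baseline_sd=sigma,
        c=c,
        threshold=threshold,
        n_young=len(young),
        n_old=len(old),
    )


def evaluate_curve(curve: ReferenceCurve, age: float) -> float:
    """Expected parameter value at ``age``: plateau then quadratic."""
    lo, hi = curve.age_validity
    if not lo <= age <= hi:
        warnings.warn(
            f"age {age} outside validity range [{lo}, {hi}]; extrapolating",
            stacklevel=2,
        )
    if age <= curve.threshold:
        return curve.baseline_mean
    return curve.a + curve.b * age + curve.c * age**2


def t_score(value: float, curve: ReferenceCurve) -> float:
    """(X - ybar)/sigma_young — deviation from the young-adult reference."""
    if not curve.baseline_sd > 0:
        raise ValueError("baseline SD must be > 0 for T-scores")
    return (value - curve.baseline_mean) / curve.baseline_sd


def z_score(value: float, curve: ReferenceCurve, age: float) -> float:
    """(X - y(age))/sigma_young — deviation from the age-specific expectation."""
    if not curve.baseline_sd > 0:
        raise ValueError("baseline SD must be > 0 for Z-scores")
    return (value - evaluate_curve(curve, age)) / curve.baseline_sd


def classify_band(score: float, bands: ReferenceBandSpec = ReferenceBandSpec()) -> str:
    """Classify an SD score into green/yellow/red or out-of-range.

    The negative-side bands are half-open above (e.g. yellow is [-2.5, -1))
    so every score lands in exactly one class; the green band is closed.
    """
    if math.isnan(score):
        raise ValueError("cannot classify NaN score")
    if bands.green[0] <= score <= bands.green[1]:
        return "green"
    if bands.yellow[0] <= score < bands.yellow[1]:
        return "yellow"
    if bands.red[0] <= score < bands.red[1]:
        return "red"
    return "below_range" if score < bands.red[0] else "above_range"


def curve_band_table(
    curve: ReferenceCurve,
    bands: ReferenceBandSpec = ReferenceBandSpec(),
    age_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Mean trajectory and SD-offset band edges per age, for plotting.

    Edge offsets are the band boundaries (-3.5, -2.5, -1, 2 SD by default);
    each edge column holds ``y(age) + k * sigma_young``.
    """
    if age_grid is None:
        age_grid = np.arange(curve.age_validity[0], curve.age_validity[1] + 1.0)
    offsets = sorted({bands.red[0], bands.red[1], bands.yellow[1], bands.green[1]})
    rows = []
    for age in age_grid:
        mean = evaluate_curve(curve, float(age))
        row = {"age": float(age), "mean": mean}
        for k in offsets:
            row[f"sd{k:+g}"] = mean + k * curve.baseline_sd
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Curve store (JSON persistence keyed by parameter/sex/site)
# ---------------------------------------------------------------------------


class CurveStore:
    """In-memory collection of reference curves with JSON round-trip."""

    def __init__(self, curves: Iterable[ReferenceCurve] = ()):
        self._curves: dict[tuple[str, str, str], ReferenceCurve] = {}
        for c in curves:
            self.add(c)

    def add(self, curve: ReferenceCurve) -> None:
        self._curves[(curve.parameter, curve.sex.value, curve.site.value)] = curve

    def get(self, parameter: str, sex: Sex | str, site: Site | str) -> ReferenceCurve:
        key = (parameter, Sex(sex).value, Site(site).value)
        if key not in self._curves:
            raise KeyError(f"no reference curve for {key}")
        return self._curves[key]

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        parameter, sex, site = key
        return (parameter, Sex(sex).value, Site(site).value) in self._curves

    def __len__(self) -> int:
        return len(self._curves)

    def __iter__(self):
        return iter(self._curves.values())

    def save(self, path: str | Path) -> None:
        payload = []
        for c in self._curves.values():
            d = asdict(c)
            d["sex"] = c.sex.value
            d["site"] = c.site.value
            d["age_validity"] = list(c.age_validity)
            payload.append(d)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "CurveStore":
        with open(path) as fh:
            payload = json.load(fh)
        curves = []
        for d in payload:
            d["age_validity"] = tuple(d["age_validity"])
            curves.append(ReferenceCurve(**d))
        return cls(curves)
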