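"""Synthetic cohort generator for the multi-stack HRpQCT reference analysis.

No individual-level data are distributable, so downstream stages are
exercised on synthetic cohorts that reproduce the *statistical structure*
the analysis assumes: sex/site strata (144 F, 237 M by default), ages on
[20, 92] with the empty 38-40 yr window, a plateau up to 37 yr followed by
a quadratic decline whose curvature is solved from a target median annual
%-change, homoscedastic Gaussian measurement noise with the published
per-parameter SDs, and same-day repeat scans with multiplicative noise at
the published precision error for a precision subgroup.

Parameters are generated independently (no cross-parameter copula); each
parameter draws from its own RNG stream split off the master seed, so
adding a parameter never perturbs the values of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from . import normative_tables
from .cohort_data import AGE_THRESHOLD, ParticipantRecord, Sex, Site
from .reference_curves import ReferenceCurve

__all__ = [
    "ParameterTrend",
    "SyntheticConfig",
    "ConfigError",
    "solve_curvature",
    "generate_cohort",
    "default_config",
    "load_config",
]

#: Age by which the relative slope of the default trends equals the target
#: annual change: the median of the integer evaluation grid 38..92 yr.
RATE_EVAL_AGE = 65.0

_RATIO_PARAMS = ("Tb.BV/TV", "Ct.Po", "Rel.Ct.Th")
_CLIP_EPS = 1e-6


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


def solve_curvature(
    target_annual_change: float,
    ybar: float,
    eval_age: float = RATE_EVAL_AGE,
    threshold: float = AGE_THRESHOLD,
    age_max: float = 92.0,
) -> float:
    """Curvature c whose relative slope at ``eval_age`` hits the target rate.

    The quadratic branch is y(x) = ybar + c*(x - t*)^2, so the relative
    slope in %/yr is 100 * 2c(x - t*) / y(x); solving for c at x = eval_age
    gives  c = (r/100) * ybar / (2d - (r/100) d^2)  with d = eval_age - t*.
    Raises :class:`ConfigError` if the resulting curve is non-positive
    anywhere on [t*, age_max].
    """
    if not ybar > 0:
        raise ConfigError("ybar must be > 0")
    if not eval_age > threshold:
        raise ConfigError("eval_age must exceed the threshold")
    r = target_annual_change / 100.0
    d = eval_age - threshold
    denom = 2.0 * d - r * d * d
    if denom == 0.0:
        raise ConfigError("target rate puts the curve pole at eval_age")
    c = r * ybar / denom
    dmax = age_max - threshold
    if ybar + c * dmax * dmax <= 0.0:
        raise ConfigError(
            f"target rate {target_annual_change} %/yr drives the curve "
            f"non-positive before age {age_max}"
        )
    return c


@dataclass(frozen=True)
class ParameterTrend:
    """Generative age-trend settings for one parameter/sex/site.

    young_mean / young_sd: plateau level and SD up to the threshold age;
    annual_change: target median relative change [%/yr] on the older branch
    (converted to a curvature via :func:`solve_curvature`); noise_sd:
    additive Gaussian measurement noise SD (defaults to young_sd);
    repeat_cv: same-day repeat coefficient of variation in percent.
    """

    young_mean: float
    young_sd: float
    annual_change: float = 0.0
    noise_sd: float | None = None
    repeat_cv: float = 0.0

    def __post_init__(self) -> None:
        if not self.young_mean > 0:
            raise ConfigError("young_mean must be > 0")
        if self.young_sd < 0 or (self.noise_sd is not None and self.noise_sd < 0):
            raise ConfigError("SDs must be >= 0")
        if self.repeat_cv < 0:
            raise ConfigError("repeat_cv must be >= 0")

    @property
    def effective_noise_sd(self) -> float:
        return self.young_sd if self.noise_sd is None else self.noise_sd

    def curvature(self, threshold: float = AGE_THRESHOLD, age_max: float = 92.0) -> float:
        return solve_curvature(
            self.annual_change, self.young_mean, RATE_EVAL_AGE, threshold, age_max
        )

    def mean_at(self, age: float, threshold: float = AGE_THRESHOLD) -> float:
        if age <= threshold:
            return self.young_mean
        c = self.curvature(threshold)
        return self.young_mean + c * (age - threshold) ** 2

    def true_curve(
        self, parameter: str, sex: Sex | str, site: Site | str, threshold: float = AGE_THRESHOLD
    ) -> ReferenceCurve:
        """The noise-free generating curve, as a ReferenceCurve."""
        return ReferenceCurve.from_curvature(
            parameter,
            sex,
            site,
            baseline_mean=self.young_mean,
            baseline_sd=self.young_sd,
            c=self.curvature(threshold),
            threshold=threshold,
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration.

    ``trends`` maps (sex, site, parameter-name) to a :class:`ParameterTrend`.
    Defaults mirror the reference study's structure: 144 women and 237 men
    aged 20-92 with no ages in (37, 41); young-group fractions 54/144 (F)
    and 60/237 (M); precision subgroups of 19 (F) and 20 (M) participants
    with one same-day repeat per site.
    """

    seed: int
    n_female: int = 144
    n_male: int = 237
    age_range: tuple[float, float] = (20.0, 92.0)
    age_gap: tuple[float, float] = (37.0, 41.0)
    young_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"F": 54.0 / 144.0, "M": 60.0 / 237.0}
    )
    n_repeat: Mapping[str, int] = field(default_factory=lambda: {"F": 19, "M": 20})
    threshold: float = AGE_THRESHOLD
    trends: Mapping[tuple[str, str, str], ParameterTrend] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_female < 0 or self.n_male < 0:
            raise ConfigError("participant counts must be >= 0")
        lo, hi = self.age_range
        if lo >= hi:
            raise ConfigError(f"degenerate age range [{lo}, {hi}]")
        g0, g1 = self.age_gap
        if not (lo <= g0 < g1 <= hi):
            raise ConfigError("age gap must lie inside the age range")


def default_config(seed: int, parameters: Iterable[str] | None = None, **overrides) -> SyntheticConfig:
    """Configuration with trends taken from the published descriptive table.

    For every radius/tibia row (or the subset ``parameters``), the plateau
    mean/SD are the published mu/sigma, the target annual change and the
    repeat CV are the published rate and PE_st.
    """
    df = normative_tables.descriptive_statistics()
    trends: dict[tuple[str, str, str], ParameterTrend] = {}
    for row in df.itertuples(index=False):
        if row.site not in ("radius", "tibia"):
            continue
        if parameters is not None and row.parameter not in parameters:
            continue
        try:
            trend = ParameterTrend(
                young_mean=row.mu,
                young_sd=row.sigma,
                annual_change=row.annual_change,
                repeat_cv=row.pe_st,
            )
            trend.curvature()  # reject rates that break positivity early
        except ConfigError:
            continue
        trends[(row.sex, row.site, row.parameter)] = trend
    return SyntheticConfig(seed=seed, trends=trends, **overrides)


def _stream(seed: int, *tags: str) -> np.random.Generator:
    """Independent, deterministic RNG stream keyed by (seed, tags)."""
    key = zlib.crc32("|".join(tags).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def generate_cohort(config: SyntheticConfig) -> list[ParticipantRecord]:
    """Draw a deterministic synthetic cohort from ``config``.

    Each participant gets one baseline record per site carrying every
    configured parameter for their sex/site.  The first ``n_repeat``
    participants of each sex form the precision subgroup: they get a
    same-day repeat record, and *every* scan of such a pair carries its own
    multiplicative error ``value * (1 + eps)``, ``eps ~ N(0, repeat_cv/100)``
    — each acquisition is noisy, which is what makes the RMS-CV precision
    error an unbiased estimate of the configured per-scan CV.  Generated
    values are clipped to their physical domain (densities > 0, ratios in
    [0, 1]) so every record satisfies the data-model invariants.
    """
    lo, hi = config.age_range
    g0, g1 = config.age_gap
    counts = {"F": config.n_female, "M": config.n_male}
    sites = sorted({site for (_, site, _) in config.trends}) or ["radius", "tibia"]

    records: list[ParticipantRecord] = []
    for sex in ("F", "M"):
        n = counts[sex]
        if n == 0:
            continue
        rng_age = _stream(config.seed, "ages", sex)
        young = rng_age.random(n) < float(config.young_fraction.get(sex, 0.5))
        ages = np.where(
            young,
            rng_age.uniform(lo, min(g0, config.threshold), n),
            rng_age.uniform(g1, hi, n),
        )
        n_rep = min(int(config.n_repeat.get(sex, 0)), n)

        # value matrix per (site, parameter): baseline draws + repeat factors
        values: dict[tuple[str, str], np.ndarray] = {}
        repeats: dict[tuple[str, str], np.ndarray] = {}
        for (s, site, name), trend in config.trends.items():
            if s != sex:
                continue
            rng = _stream(config.seed, "param", sex, site, name)
            mean = np.array([trend.mean_at(a, config.threshold) for a in ages])
            vals = mean + rng.normal(0.0, trend.effective_noise_sd, n)
            vals = _clip_domain(name, vals)
            if n_rep:
                rng_rep = _stream(config.seed, "repeat", sex, site, name)
                eps = rng_rep.normal(0.0, trend.repeat_cv / 100.0, (n_rep, 2))
                repeats[(site, name)] = _clip_domain(
                    name, vals[:n_rep] * (1.0 + eps[:, 1])
                )
                vals = vals.copy()
                vals[:n_rep] = _clip_domain(name, vals[:n_rep] * (1.0 + eps[:, 0]))
            values[(site, name)] = vals

        for i in range(n):
            pid = f"{sex}{i + 1:04d}"
            for site in sites:
                meas = {
                    name: float(arr[i]) for (s2, name), arr in values.items() if s2 == site
                }
                if not meas:
                    continue
                records.append(
                    ParticipantRecord(pid, sex, float(ages[i]), site, 0, meas)
                )
                if i < n_rep:
                    rep = {
                        name: float(arr[i])
                        for (s2, name), arr in repeats.items()
                        if s2 == site
                    }
                    records.append(
                        ParticipantRecord(pid, sex, float(ages[i]), site, 1, rep)
                    )
    return records


def _clip_domain(name: str, vals: np.ndarray) -> np.ndarray:
    if name in _RATIO_PARAMS:
        return np.clip(vals, _CLIP_EPS, 1.0 - _CLIP_EPS)
    return np.clip(vals, _CLIP_EPS, None)


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a YAML/JSON generator configuration.

    Layout: scalar fields at top level; ``trends`` is a list of mappings
    with keys sex, site, parameter plus the ParameterTrend fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    trends = {}
    for entry in raw.pop("trends", []):
        key = (entry.pop("sex"), entry.pop("site"), entry.pop("parameter"))
        trends[key] = ParameterTrend(**entry)
    for tup_key in ("age_range", "age_gap"):
        if tup_key in raw:
            raw[tup_key] = tuple(raw[tup_key])
    return SyntheticConfig(trends=trends, **raw)
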