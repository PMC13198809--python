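"""Six-parameter bone-health radar profiles.

A radar profile condenses distal bone health into T-scores of six
size-independent parameters (Tot.vBMD, Ct.vBMD, Rel.Ct.Th, Tb.BV/TV,
Tb.DA, apparent yield stress), either for the cohort-mean trajectory at a
set of evaluation ages relative to the young baseline (default 50, 63, 76
and 89 yr vs 37 yr), or for an individual participant.  The radial axis is
the T-score in SD units, clipped for *display only* to [-3.5, 2].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_data import ParticipantRecord, Sex, Site
from .derived_parameters import (
    FabricTensor,
    GeometrySection,
    MechanicalResult,
    apparent_yield_stress,
    degree_of_anisotropy,
    rel_ct_th,
)
from .normative_tables import SIX_PARAMETERS
from .reference_curves import (
    CurveStore,
    ReferenceBandSpec,
    TScoreProfile,
    classify_band,
    evaluate_curve,
    t_score,
)

__all__ = [
    "RadarSpec",
    "cohort_radar_profile",
    "participant_radar_profile",
    "render_report",
    "profiles_to_frame",
]

_DISPLAY_CLIP = (-3.5, 2.0)


@dataclass(frozen=True)
class RadarSpec:
    """Ages and spoke order for the cohort radar report."""

    baseline_age: float = 37.0
    eval_ages: tuple[float, ...] = (50.0, 63.0, 76.0, 89.0)
    parameters: tuple[str, ...] = SIX_PARAMETERS

    def __post_init__(self) -> None:
        ages = self.eval_ages
        if any(a <= self.baseline_age for a in ages) or list(ages) != sorted(set(ages)):
            raise ValueError("eval_ages must be strictly increasing and > baseline_age")


def cohort_radar_profile(
    curves: CurveStore,
    spec: RadarSpec,
    sex: Sex | str,
    site: Site | str,
    include_baseline: bool = True,
) -> list[TScoreProfile]:
    """T-score profiles of the fitted mean trajectory at each evaluation age.

    Per parameter the score at age x is (y(x) - ybar)/sigma_young, i.e. the
    expected T-score of an average individual of that age; the baseline
    profile is identically zero.
    """
    sex, site = Sex(sex), Site(site)
    missing = [p for p in spec.parameters if (p, sex.value, site.value) not in curves]
    if missing:
        raise KeyError(f"missing reference curve(s) for: {', '.join(missing)}")
    ages = ((spec.baseline_age,) if include_baseline else ()) + spec.eval_ages
    profiles = []
    for age in ages:
        scores = {}
        for p in spec.parameters:
            curve = curves.get(p, sex, site)
            scores[p] = t_score(evaluate_curve(curve, age), curve)
        profiles.append(
            TScoreProfile(age=age, sex=sex, site=site, scores=scores, label=f"{age:g} yr")
        )
    return profiles


def participant_radar_profile(
    record: ParticipantRecord,
    curves: CurveStore,
    bands: ReferenceBandSpec = ReferenceBandSpec(),
    parameters: Sequence[str] = SIX_PARAMETERS,
    strict: bool = False,
) -> TScoreProfile:
    """Individual T-score profile with band classification per spoke.

    Rel.Ct.Th, app_sigma_y and Tb.DA are derived on the fly from Ct.Th /
    Tot.Ar / F_y / fabric eigenvalues (m1, m2, m3) when the ready-made
    column is absent.  Missing parameters leave explicit gaps (NaN) unless
    ``strict`` is set, in which case they raise.
    """
    meas = dict(record.measurements)
    if "Rel.Ct.Th" not in meas and {"Ct.Th", "Tot.Ar"}.issubset(meas):
        meas["Rel.Ct.Th"] = rel_ct_th(GeometrySection(meas["Tot.Ar"], meas["Ct.Th"]))
    if "app_sigma_y" not in meas and {"F_y", "Tot.Ar"}.issubset(meas):
        meas["app_sigma_y"] = apparent_yield_stress(
            MechanicalResult(f_y=meas["F_y"]), GeometrySection(meas["Tot.Ar"])
        )
    if "Tb.DA" not in meas and {"m1", "m2", "m3"}.issubset(meas):
        meas["Tb.DA"] = degree_of_anisotropy(
            FabricTensor(meas["m1"], meas["m2"], meas["m3"])
        )

    scores: dict[str, float] = {}
    band_map: dict[str, str] = {}
    for p in parameters:
        if p not in meas:
            if strict:
                raise KeyError(f"participant {record.participant_id} lacks parameter {p}")
            scores[p] = float("nan")
            band_map[p] = "missing"
            continue
        curve = curves.get(p, record.sex, record.site)
        s = t_score(meas[p], curve)
        scores[p] = s
        band_map[p] = classify_band(s, bands)
    return TScoreProfile(
        age=record.age,
        sex=record.sex,
        site=record.site,
        scores=scores,
        bands=band_map,
        label=record.participant_id,
    )


def profiles_to_frame(profiles: Iterable[TScoreProfile]) -> pd.DataFrame:
    """Long-format score table (label, age, sex, site, parameter, score, band)."""
    rows = []
    for p in profiles:
        for name, score in p.scores.items():
            rows.append(
                {
                    "label": p.label,
                    "age": p.age,
                    "sex": p.sex.value,
                    "site": p.site.value,
                    "parameter": name,
                    "t_score": score,
                    "band": p.bands.get(name, ""),
                }
            )
    return pd.DataFrame(rows)


def render_report(
    profiles: Sequence[TScoreProfile],
    out: str | Path,
    format: str | None = None,
) -> Path:
    """Write the radar report as svg/png figure or as lossless json/csv.

    The figure draws one closed polygon per profile over six fixed spokes;
    scores are clipped to the display range [-3.5, 2] in the figure only,
    json/csv always carry the unclipped values.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    out = Path(out)
    fmt = (format or out.suffix.lstrip(".") or "json").lower()
    if fmt == "json":
        payload = [
            {
                "label": p.label,
                "age": p.age,
                "sex": p.sex.value,
                "site": p.site.value,
                "scores": p.scores,
                "bands": p.bands,
            }
            for p in profiles
        ]
        out.write_text(json.dumps(payload, indent=1))
    elif fmt == "csv":
        profiles_to_frame(profiles).to_csv(out, index=False)
    elif fmt in ("svg", "png"):
        _render_figure(profiles, out, fmt)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return out


def _render_figure(profiles: Sequence[TScoreProfile], out: Path, fmt: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = list(profiles[0].scores)
    n = len(params)
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    for p in profiles:
        vals = np.clip([p.scores[k] for k in params], *_DISPLAY_CLIP)
        theta = np.concatenate([angles, angles[:1]])
        r = np.concatenate([vals, vals[:1]])
        ax.plot(theta, r, label=p.label)
        ax.fill(theta, r, alpha=0.08)
    ax.set_xticks(angles)
    ax.set_xticklabels(params)
    ax.set_ylim(*_DISPLAY_CLIP)
    ax.set_title("Bone-health T-score profile")
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    fig.savefig(out, format=fmt, bbox_inches="tight")
    plt.close(fig)
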