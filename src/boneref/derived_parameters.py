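"""Size-invariant and derived skeletal parameters.

Extensive HRpQCT outputs (cortical thickness, total area, yield force)
scale with the size of the imaged section and can mask material-level
change.  The quantities here remove that dependence:

* ``Rel.Ct.Th`` — cortical thickness divided by the equivalent-cylinder
  radius sqrt(Tot.Ar/pi), invariant to uniform scaling of the section;
* mean cylinder diameter ``D = 2*sqrt(Tot.Ar/pi)``;
* apparent yield stress — yield force over mean total area (kN -> N
  conversion applied here, result in N/mm^2 = MPa);
* apparent strain — axial displacement over initial section length;
* trabecular degree of anisotropy ``DA = m3/m1`` from the fabric tensor,
  with a power-law correction between the MSL and MIL fabric estimators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GeometrySection",
    "MechanicalResult",
    "FabricTensor",
    "rel_ct_th",
    "mean_diameter",
    "apparent_yield_stress",
    "apparent_strain",
    "degree_of_anisotropy",
    "msl_to_mil",
    "add_derived_columns",
]


@dataclass(frozen=True)
class GeometrySection:
    """Mean cross-sectional geometry of the scanned section.

    tot_ar: mean total cross-sectional area over all slices [mm^2]
    ct_th:  mean cortical thickness [mm]
    """

    tot_ar: float
    ct_th: float = 0.0

    def __post_init__(self) -> None:
        if not self.tot_ar > 0:
            raise ValueError(f"tot_ar must be > 0, got {self.tot_ar}")
        if self.ct_th < 0:
            raise ValueError("ct_th must be >= 0")


@dataclass(frozen=True)
class MechanicalResult:
    """Structural mechanics outputs of the homogenized FE compression test.

    f_y: estimated yield force [kN]; reaction_force [N]; displacement and
    initial_length [mm] along the loading axis.
    """

    f_y: float = 0.0
    reaction_force: float = 0.0
    displacement: float = 0.0
    initial_length: float = 1.0

    def __post_init__(self) -> None:
        if self.f_y < 0:
            raise ValueError("yield force must be >= 0")
        if not self.initial_length > 0:
            raise ValueError("initial_length must be > 0")


class FabricTensor:
    """Eigenvalues of a positive-definite second-order fabric tensor.

    Eigenvalues are sorted ascending and normalized on construction so that
    ``m1*m2*m3 = 1`` (the degree of anisotropy m3/m1 is scale-free, so the
    normalization convention does not affect it).  ``variant`` records the
    estimator that produced the tensor: mean surface length (MSL) or mean
    intercept length (MIL).
    """

    __slots__ = ("m1", "m2", "m3", "variant")

    def __init__(self, m1: float, m2: float, m3: float, variant: str = "MSL"):
        vals = sorted(float(v) for v in (m1, m2, m3))
        if vals[0] <= 0:
            raise ValueError("fabric eigenvalues must be > 0")
        if variant not in ("MSL", "MIL"):
            raise ValueError("variant must be 'MSL' or 'MIL'")
        norm = (vals[0] * vals[1] * vals[2]) ** (1.0 / 3.0)
        self.m1, self.m2, self.m3 = (v / norm for v in vals)
        self.variant = variant

    @property
    def eigenvalues(self) -> tuple[float, float, float]:
        return (self.m1, self.m2, self.m3)

    @classmethod
    def isotropic(cls, variant: str = "MSL") -> "FabricTensor":
        return cls(1.0, 1.0, 1.0, variant)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FabricTensor(m1={self.m1:.6g}, m2={self.m2:.6g}, "
            f"m3={self.m3:.6g}, variant={self.variant!r})"
        )


def rel_ct_th(g: GeometrySection) -> float:
    """Relative cortical thickness Ct.Th / sqrt(Tot.Ar/pi), dimensionless.

    Invariant under uniform scaling (ct_th -> s*ct_th, tot_ar -> s^2*tot_ar).
    """
    return g.ct_th / math.sqrt(g.tot_ar / math.pi)


def mean_diameter(g: GeometrySection) -> float:
    """Mean cylinder diameter D = 2*sqrt(Tot.Ar/pi) [mm]."""
    return 2.0 * math.sqrt(g.tot_ar / math.pi)


def apparent_yield_stress(m: MechanicalResult, g: GeometrySection) -> float:
    """Apparent yield stress F_y / Tot.Ar [MPa]; F_y converted kN -> N."""
    return m.f_y * 1000.0 / g.tot_ar


def apparent_strain(m: MechanicalResult) -> float:
    """Apparent axial strain: displacement / initial length, dimensionless."""
    return m.displacement / m.initial_length


def degree_of_anisotropy(f: FabricTensor) -> float:
    """Trabecular degree of anisotropy DA = m3/m1 >= 1."""
    return f.m3 / f.m1


def msl_to_mil(da_msl: float, coeff_a: float = 1.0, coeff_b: float = 1.0) -> float:
    """Power-law correction of an MSL-based DA to the MIL convention.

    ``DA_MIL = a * DA_MSL^b``.  The coefficients are calibration values
    (supplementary fit constants, not universal); (a, b) = (1, 1) is the
    identity.  A result below 1 is non-physical for an anisotropy ratio and
    triggers a warning.
    """
    if da_msl < 1.0:
        raise ValueError("da_msl must be >= 1")
    if coeff_a <= 0:
        raise ValueError("coeff_a must be > 0")
    out = coeff_a * da_msl**coeff_b
    if out < 1.0:
        warnings.warn(
            f"MSL->MIL correction produced DA = {out:.4g} < 1 (non-physical)",
            stacklevel=2,
        )
    return out


def add_derived_columns(df: pd.DataFrame, mil_a: float = 1.0, mil_b: float = 1.0) -> pd.DataFrame:
    """Append derived-parameter columns to a cohort table.

    Computes Rel.Ct.Th, the mean diameter D, app_sigma_y and, when fabric
    eigenvalue columns ``m1, m2, m3`` are present, Tb.DA (with MSL->MIL
    correction).  Columns whose inputs are absent are left out; rows with
    missing inputs get NaN.
    """
    out = df.copy()
    if "Tot.Ar" in out:
        out["D"] = 2.0 * (out["Tot.Ar"] / math.pi) ** 0.5
        if "Ct.Th" in out:
            out["Rel.Ct.Th"] = out["Ct.Th"] / (out["Tot.Ar"] / math.pi) ** 0.5
        if "F_y" in out:
            out["app_sigma_y"] = out["F_y"] * 1000.0 / out["Tot.Ar"]
    if {"m1", "m2", "m3"}.issubset(out.columns):
        da = out[["m1", "m2", "m3"]].max(axis=1) / out[["m1", "m2", "m3"]].min(axis=1)
        out["Tb.DA"] = mil_a * da**mil_b
    return out
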