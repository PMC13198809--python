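"""Density- and fabric-based constitutive ingredients for homogenized FE.

Bone at the continuum scale is modelled as an orthotropic elastic solid
whose engineering constants scale with a structural density rho (bound
volume fraction) and with the eigenvalues m1 <= m2 <= m3 of a normalized
fabric tensor:

    E_i   = E0  * rho^k * m_i^(2l)
    G_ij  = mu0 * rho^k * (m_i * m_j)^l
    nu_ij = nu0 * m_i^l / m_j^l      (so that nu_ij/E_i is symmetric)

The compliance matrix is assembled in the fabric principal frame (Voigt
order 11, 22, 33, 23, 13, 12, engineering shear strains) and inverted to a
symmetric positive-definite stiffness.

Yielding is described by a tension-compression-asymmetric superposed
quadric y(s) = sqrt(s:F:s) + f:s - 1, calibrated per axis so that uniaxial
tension sigma0+, uniaxial compression sigma0- and pure shear tau0 lie
exactly on the surface at rho = 1 and isotropic fabric; strengths scale
with the same rho^k, m^l laws as the elastic constants unless overridden.
Values < 0 are elastic, 0 is on the surface, > 0 is outside.

Default constants (experimentally identified):
trabecular E0=10480 MPa, nu0=0.2289, mu0=3350 MPa, k=1.55, l=0.82,
sigma0+=62.01, sigma0-=78.58, tau0=31.83 MPa; cortical E0=15992 MPa,
nu0=0.339, mu0=5846 MPa, k=l=1, sigma0+=71.00, sigma0-=124.20,
tau0=41.30 MPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .derived_parameters import FabricTensor

__all__ = [
    "ElasticConstants",
    "YieldConstants",
    "TRABECULAR_ELASTIC",
    "CORTICAL_ELASTIC",
    "TRABECULAR_YIELD",
    "CORTICAL_YIELD",
    "orthotropic_stiffness",
    "orthotropic_compliance",
    "uniaxial_apparent_modulus",
    "quadric_yield_value",
    "engineering_constants",
]


@dataclass(frozen=True)
class ElasticConstants:
    """Base orthotropic elastic constants and scaling exponents."""

    e0: float  # MPa
    nu0: float
    mu0: float  # MPa
    k: float  # density exponent
    l: float  # fabric exponent

    def __post_init__(self) -> None:
        if self.e0 <= 0 or self.mu0 <= 0:
            raise ValueError("moduli must be > 0")
        if not 0.0 <= self.nu0 < 0.5:
            raise ValueError("nu0 must be in [0, 0.5)")
        if self.k < 0 or self.l < 0:
            raise ValueError("exponents must be >= 0")


@dataclass(frozen=True)
class YieldConstants:
    """Uniaxial tensile/compressive and shear strengths at rho=1, isotropy."""

    sigma0_plus: float  # MPa
    sigma0_minus: float  # MPa
    tau0: float  # MPa

    def __post_init__(self) -> None:
        if min(self.sigma0_plus, self.sigma0_minus, self.tau0) <= 0:
            raise ValueError("yield strengths must be > 0")


TRABECULAR_ELASTIC = ElasticConstants(e0=10480.0, nu0=0.2289, mu0=3350.0, k=1.55, l=0.82)
CORTICAL_ELASTIC = ElasticConstants(e0=15992.0, nu0=0.339, mu0=5846.0, k=1.0, l=1.0)
TRABECULAR_YIELD = YieldConstants(sigma0_plus=62.01, sigma0_minus=78.58, tau0=31.83)
CORTICAL_YIELD = YieldConstants(sigma0_plus=71.00, sigma0_minus=124.20, tau0=41.30)

# Voigt pair order after the normal components: (2,3), (1,3), (1,2)
_SHEAR_PAIRS = ((1, 2), (0, 2), (0, 1))


def _check_rho(rho: float) -> None:
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1], got {rho}")


def orthotropic_compliance(
    rho: float, fabric: FabricTensor, ec: ElasticConstants
) -> np.ndarray:
    """6x6 compliance in the fabric principal frame (engineering shears)."""
    _check_rho(rho)
    m = np.asarray(fabric.eigenvalues)
    scale = rho**ec.k
    e = ec.e0 * scale * m ** (2.0 * ec.l)
    s = np.zeros((6, 6))
    for i in range(3):
        s[i, i] = 1.0 / e[i]
    for i in range(3):
        for j in range(3):
            if i != j:
                # nu_ij / E_i, symmetric in (i, j) by construction
                s[i, j] = -ec.nu0 / (ec.e0 * scale * m[i] ** ec.l * m[j] ** ec.l)
    for a, (i, j) in enumerate(_SHEAR_PAIRS):
        g = ec.mu0 * scale * (m[i] * m[j]) ** ec.l
        s[3 + a, 3 + a] = 1.0 / g
    return s


def orthotropic_stiffness(
    rho: float, fabric: FabricTensor, ec: ElasticConstants
) -> np.ndarray:
    """Symmetric positive-definite 6x6 stiffness matrix (MPa)."""
    c = np.linalg.inv(orthotropic_compliance(rho, fabric, ec))
    c = 0.5 * (c + c.T)  # remove inversion round-off asymmetry
    if np.any(np.linalg.eigvalsh(c) <= 0):
        raise RuntimeError("stiffness not positive definite (invalid constants?)")
    return c


def uniaxial_apparent_modulus(stiffness: np.ndarray, axis: int) -> float:
    """Engineering Young's modulus along ``axis`` (1, 2 or 3), in MPa."""
    if axis not in (1, 2, 3):
        raise ValueError("axis must be 1, 2 or 3")
    compliance = np.linalg.inv(np.asarray(stiffness, dtype=float))
    return 1.0 / compliance[axis - 1, axis - 1]


def engineering_constants(
    rho: float, fabric: FabricTensor, ec: ElasticConstants
) -> dict[str, float]:
    """Engineering constants recovered from the stiffness (round-trip safe)."""
    s = np.linalg.inv(orthotropic_stiffness(rho, fabric, ec))
    out: dict[str, float] = {}
    for i in range(3):
        out[f"E{i + 1}"] = 1.0 / s[i, i]
    for a, (i, j) in enumerate(_SHEAR_PAIRS):
        out[f"G{i + 1}{j + 1}"] = 1.0 / s[3 + a, 3 + a]
    for i in range(3):
        for j in range(3):
            if i != j:
                out[f"nu{i + 1}{j + 1}"] = -s[i, j] / s[i, i]
    return out


def quadric_yield_value(
    stress: np.ndarray,
    yc: YieldConstants,
    rho: float = 1.0,
    fabric: FabricTensor | None = None,
    fabric_frame: np.ndarray | None = None,
    k: float = 1.0,
    l: float = 1.0,
) -> float:
    """Signed yield-criterion value for a symmetric 3x3 stress tensor [MPa].

    Superposed-quadric form y = sqrt(Q(s)) + L(s) - 1 with per-axis
    coefficients pinned by the calibration cases: uniaxial tension t_i,
    uniaxial compression c_i and pure shear tau_ij all return exactly 0.
    ``k`` and ``l`` scale the strengths as t_i = sigma0+ * rho^k * m_i^(2l)
    etc. (pass the compartment's elastic exponents to share the elasticity
    scaling).  ``fabric_frame`` gives the fabric eigenvector basis as
    columns; stress is rotated into that frame, which makes the criterion
    objective under joint rotation of stress and fabric.
    """
    _check_rho(rho)
    sig = np.asarray(stress, dtype=float)
    if sig.shape != (3, 3) or not np.allclose(sig, sig.T, atol=1e-9 * max(1.0, np.abs(sig).max())):
        raise ValueError("stress must be a symmetric 3x3 tensor")
    if fabric_frame is not None:
        r = np.asarray(fabric_frame, dtype=float)
        sig = r.T @ sig @ r
    m = np.asarray(fabric.eigenvalues) if fabric is not None else np.ones(3)

    scale = rho**k
    t = yc.sigma0_plus * scale * m ** (2.0 * l)
    c = yc.sigma0_minus * scale * m ** (2.0 * l)

    quad = 0.0
    lin = 0.0
    for i in range(3):
        # sqrt(B_i)*t + f_i*t = 1 and sqrt(B_i)*c - f_i*c = 1
        sqrt_b = 0.5 * (1.0 / t[i] + 1.0 / c[i])
        f_i = 0.5 * (1.0 / t[i] - 1.0 / c[i])
        quad += (sqrt_b * sig[i, i]) ** 2
        lin += f_i * sig[i, i]
    for i, j in _SHEAR_PAIRS:
        tau = yc.tau0 * scale * (m[i] * m[j]) ** l
        quad += (sig[i, j] / tau) ** 2
    return float(np.sqrt(quad) + lin - 1.0)
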