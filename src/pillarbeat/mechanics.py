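"""Closed-form cantilever mechanics for elastomeric micropillars.

A vertical PDMS micropillar behaves, for the small lateral loads a beating
cardiomyocyte applies at its tip, as an Euler-Bernoulli cantilever of
circular cross-section.  Its tip stiffness is

    k = 3 E I / L^3,    I = pi D^4 / 64   =>   k = 3 pi E D^4 / (64 L^3)

where ``E`` is the Young's modulus of the elastomer, ``D`` the pillar
diameter and ``L`` its length.  A measured tip deflection ``d`` then maps
linearly to the cell's traction force ``F = k d``.

Units contract (used throughout the package): geometry in micrometres,
modulus in megapascals, stiffness in N/m, deflection in micrometres, force
in micronewtons.  Note the convenient identity 1 um * 1 N/m = 1 uN, so no
numeric factor appears in the force conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PillarGeometry",
    "ElasticMaterial",
    "SpringConstant",
    "spring_constant",
    "force_from_deflection",
    "deflection_from_force",
    "PDMS_MODULUS_RANGE_MPA",
]

#: Typical Young's modulus range for cured PDMS (MPa); values outside this
#: range warn but are accepted, so stiffer elastomers remain usable.
PDMS_MODULUS_RANGE_MPA = (0.5, 4.0)


class InvalidParameterError(ValueError):
    """A physical parameter is non-positive or non-finite."""


@dataclass(frozen=True)
class PillarGeometry:
    """Cylindrical pillar geometry.

    Parameters
    ----------
    diameter_um : float
        Pillar diameter D in micrometres.
    length_um : float
        Pillar length L in micrometres.
    """

    diameter_um: float
    length_um: float

    def __post_init__(self) -> None:
        for name in ("diameter_um", "length_um"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(
                    f"{name} must be finite and positive, got {v!r}"
                )

    @property
    def aspect_ratio(self) -> float:
        """Length-to-diameter ratio L/D."""
        return self.length_um / self.diameter_um

    @property
    def second_moment_m4(self) -> float:
        """Area moment of inertia I = pi D^4 / 64 in m^4."""
        d_m = self.diameter_um * 1e-6
        return math.pi * d_m**4 / 64.0


@dataclass(frozen=True)
class ElasticMaterial:
    """Linear-elastic material characterised by its Young's modulus in MPa."""

    youngs_modulus_mpa: float

    def __post_init__(self) -> None:
        e = self.youngs_modulus_mpa
        if not (np.isfinite(e) and e > 0):
            raise InvalidParameterError(
                f"youngs_modulus_mpa must be finite and positive, got {e!r}"
            )
        lo, hi = PDMS_MODULUS_RANGE_MPA
        if not (lo <= e <= hi):
            warnings.warn(
                f"Young's modulus {e} MPa is outside the typical PDMS range "
                f"{lo}-{hi} MPa; proceeding anyway",
                stacklevel=3,
            )


@dataclass(frozen=True)
class SpringConstant:
    """Cantilever tip stiffness k in N/m."""

    n_per_m: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n_per_m) and self.n_per_m > 0):
            raise InvalidParameterError(
                f"spring constant must be finite and positive, got {self.n_per_m!r}"
            )


def spring_constant(
    geometry: PillarGeometry, material: ElasticMaterial
) -> SpringConstant:
    """Tip stiffness of a circular-section cantilever, k = 3 pi E D^4 / (64 L^3).

    Inputs follow the package units contract (um, MPa); the conversion to SI
    happens internally and the result is returned in N/m.

    Examples
    --------
    >>> k = spring_constant(PillarGeometry(16, 48), ElasticMaterial(0.5))
    >>> round(k.n_per_m, 2)
    0.04
    """
    e_pa = material.youngs_modulus_mpa * 1e6
    d_m = geometry.diameter_um * 1e-6
    l_m = geometry.length_um * 1e-6
    k = 3.0 * math.pi * e_pa * d_m**4 / (64.0 * l_m**3)
    return SpringConstant(k)


def _as_k(k: SpringConstant | float) -> float:
    if isinstance(k, SpringConstant):
        return k.n_per_m
    if not (np.isfinite(k) and k > 0):
        raise InvalidParameterError(f"spring constant must be positive, got {k!r}")
    return float(k)


def force_from_deflection(d_um, k: SpringConstant | float, *, pillar_id=None):
    """Convert tip deflection (um) to traction force (uN) via F = k d.

    ``d_um`` may be a scalar, a vector (componentwise conversion), or any
    array of per-frame deflections.  Non-finite deflections raise, naming
    the pillar if an id is supplied.
    """
    kv = _as_k(k)
    d = np.asarray(d_um, dtype=float)
    if not np.all(np.isfinite(d)):
        ctx = f" for pillar {pillar_id}" if pillar_id is not None else ""
        raise InvalidParameterError(f"non-finite deflection{ctx}: {d_um!r}")
    out = d * kv
    return float(out) if out.ndim == 0 else out


def deflection_from_force(f_un, k: SpringConstant | float):
    """Inverse of :func:`force_from_deflection`: d = F / k, in um.

    Used to cross-check the linearity of the force-displacement relation;
    round-trips with the forward conversion to machine precision.
    """
    kv = _as_k(k)
    f = np.asarray(f_un, dtype=float)
    out = f / kv
    return float(out) if out.ndim == 0 else out
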