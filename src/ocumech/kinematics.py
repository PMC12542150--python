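"""Incompressible principal-stretch kinematics for thin-walled ocular tissue.

The optic nerve sheath is modelled as an incompressible membrane whose
material points deform along three principal directions: circumferential
(theta, around the nerve), longitudinal (z, along the nerve) and radial
(through the thickness).  With the volume ratio J = 1 the radial stretch is
slaved to the in-plane pair, ``lambda_r = 1 / (lambda_theta * lambda_z)``,
and the isochoric stretches coincide with the stretches themselves.

Two fiber families reinforce the sheath in-plane.  Their reference
directions are unit vectors in the (theta, z) plane at angles ``alpha1``
(family 1, circumferential by convention: alpha1 = 0) and ``alpha2``
(family 2, longitudinal: alpha2 = 90) from the local theta-axis, with a
scalar dispersion ``kappa`` in [0, 1/3]: 0 means perfectly aligned fibers,
1/3 an isotropic (fully dispersed) distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PrincipalStretchState",
    "FiberArchitecture",
    "incompressible_state",
    "invariants",
    "green_lagrange_strain",
    "stretch_from_engineering",
    "engineering_from_stretch",
]

_INCOMPRESSIBILITY_TOL = 1e-12


@dataclass(frozen=True)
class PrincipalStretchState:
    """Principal stretches (lambda_theta, lambda_z, lambda_r) with J = 1.

    All three stretches are dimensionless and strictly positive; their
    product must equal one (incompressibility) to within 1e-12.
    """

    lambda_theta: float
    lambda_z: float
    lambda_r: float

    def __post_init__(self) -> None:
        for name in ("lambda_theta", "lambda_z", "lambda_r"):
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        j = self.lambda_theta * self.lambda_z * self.lambda_r
        if abs(j - 1.0) > _INCOMPRESSIBILITY_TOL:
            raise ValueError(
                f"stretches violate incompressibility: "
                f"lambda_theta*lambda_z*lambda_r = {j!r} != 1"
            )

    @property
    def J(self) -> float:
        """Volume ratio; identically 1 for admissible states."""
        return self.lambda_theta * self.lambda_z * self.lambda_r


@dataclass(frozen=True)
class FiberArchitecture:
    """Two in-plane fiber families with a shared dispersion parameter.

    Parameters
    ----------
    alpha1_deg, alpha2_deg
        Angles of fiber families 1 and 2 from the local circumferential
        (theta) axis, in degrees, within [0, 90].  Defaults place family 1
        circumferentially and family 2 longitudinally.
    kappa
        Fiber dispersion, dimensionless, in [0, 1/3].
    """

    alpha1_deg: float = 0.0
    alpha2_deg: float = 90.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha1_deg", "alpha2_deg"):
            angle = getattr(self, name)
            if not 0.0 <= angle <= 90.0:
                raise ValueError(f"{name} must lie in [0, 90] degrees, got {angle}")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise ValueError(f"kappa must lie in [0, 1/3], got {self.kappa}")

    @property
    def m1(self) -> tuple[float, float]:
        """Unit vector of family 1 in the (theta, z) plane."""
        a = math.radians(self.alpha1_deg)
        return (math.cos(a), math.sin(a))

    @property
    def m2(self) -> tuple[float, float]:
        """Unit vector of family 2 in the (theta, z) plane."""
        a = math.radians(self.alpha2_deg)
        return (math.cos(a), math.sin(a))


def incompressible_state(lambda_theta: float, lambda_z: float) -> PrincipalStretchState:
    """Build a J = 1 state from the two in-plane stretches.

    The radial stretch is ``1 / (lambda_theta * lambda_z)``.
    """
    if not lambda_theta > 0.0:
        raise ValueError(f"lambda_theta must be strictly positive, got {lambda_theta}")
    if not lambda_z > 0.0:
        raise ValueError(f"lambda_z must be strictly positive, got {lambda_z}")
    return PrincipalStretchState(lambda_theta, lambda_z, 1.0 / (lambda_theta * lambda_z))


def invariants(
    state: PrincipalStretchState, arch: FiberArchitecture
) -> tuple[float, float, float]:
    """Deviatoric invariants (I1, I4, I6) of the right Cauchy-Green tensor.

    With J = 1 the isochoric stretches equal the stretches, so

        I1 = lt**2 + lz**2 + (lt*lz)**-2
        I4 = lt**2 cos^2(a1) + lz**2 sin^2(a1)   (fiber family 1)
        I6 = lt**2 cos^2(a2) + lz**2 sin^2(a2)   (fiber family 2)

    where the third I1 term is the radial stretch squared.  At the default
    angles (a1 = 0, a2 = 90) these reduce to I4 = lt**2 and I6 = lz**2.
    """
    lt, lz = state.lambda_theta, state.lambda_z
    i1 = lt**2 + lz**2 + (lt * lz) ** -2
    c1, s1 = math.cos(math.radians(arch.alpha1_deg)), math.sin(math.radians(arch.alpha1_deg))
    c2, s2 = math.cos(math.radians(arch.alpha2_deg)), math.sin(math.radians(arch.alpha2_deg))
    i4 = lt**2 * c1**2 + lz**2 * s1**2
    i6 = lt**2 * c2**2 + lz**2 * s2**2
    return i1, i4, i6


def green_lagrange_strain(lam):
    """Green-Lagrange strain E = (lambda**2 - 1) / 2 of a principal stretch.

    Accepts a scalar or array; strictly positive stretches only.
    """
    import numpy as np

    arr = np.asarray(lam, dtype=float)
    if np.any(arr <= 0.0):
        raise ValueError("stretch must be strictly positive")
    out = (arr**2 - 1.0) / 2.0
    return out.item() if np.isscalar(lam) or arr.ndim == 0 else out


def stretch_from_engineering(eps_eng):
    """Stretch lambda = 1 + eps from engineering strain (eps > -1)."""
    import numpy as np

    arr = np.asarray(eps_eng, dtype=float)
    if np.any(arr <= -1.0):
        raise ValueError("engineering strain must exceed -1")
    out = 1.0 + arr
    return out.item() if np.isscalar(eps_eng) or arr.ndim == 0 else out


def engineering_from_stretch(lam):
    """Engineering strain eps = lambda - 1; inverse of stretch_from_engineering."""
    import numpy as np

    arr = np.asarray(lam, dtype=float)
    if np.any(arr <= 0.0):
        raise ValueError("stretch must be strictly positive")
    out = arr - 1.0
    return out.item() if np.isscalar(lam) or arr.ndim == 0 else out
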