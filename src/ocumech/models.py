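"""Hyperelastic strain-energy models for ocular tissues.

Three families cover the tissue palette used in posterior-eye mechanics:

* **Reduced polynomial** (order 1 or 2) for the isotropic tissues — sclera,
  optic nerve, retina, choroid, Bruch's membrane.  Order 1 is the
  neo-Hookean model.
* **One-term Ogden** for the lamina cribrosa.
* **Fiber-reinforced Holzapfel (GOH)** for the anisotropic optic nerve
  sheath: an isotropic neo-Hookean ground matrix plus an exponential term
  for two dispersed fiber families.  Fibers contribute only in tension,
  enforced by a Macaulay bracket on the pseudo-fiber strains.

All computations are strictly incompressible (J = 1); the near-
incompressibility coefficients D are carried as metadata for material-card
export only, where a solver needs them to regularise the volumetric
response.  Stresses and energies are in MPa throughout.

Energies expose vectorised second Piola-Kirchhoff principal stresses
``pk2_stresses(lambda_theta, lambda_z)`` obtained by analytic
differentiation of the condensed energy ``psi_hat(lt, lz)`` in which the
radial stretch has been eliminated by incompressibility (this choice of the
pressure makes the radial stress vanish).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .kinematics import FiberArchitecture, PrincipalStretchState, invariants

__all__ = [
    "ReducedPolynomialParams",
    "OgdenParams",
    "HolzapfelParams",
    "MaterialModel",
    "reduced_polynomial_energy",
    "ogden_energy",
    "goh_pseudo_strains",
    "goh_isochoric_energy",
]

# exp() overflows near 709; arguments beyond this are an unphysical corner
# of parameter space and the public energy op refuses them.
_EXP_OVERFLOW = 700.0
# Clip level for optimisation trials: exp(300) ~ 2e130 keeps downstream
# products and squares finite while still dwarfing any physical stress.
_EXP_CLIP = 300.0


def _macaulay(x):
    """Macaulay bracket <x> = (x + |x|) / 2: tensile part only."""
    return (x + np.abs(x)) / 2.0


def _i1_incompressible(lt, lz):
    return lt**2 + lz**2 + (lt * lz) ** -2


@dataclass(frozen=True)
class ReducedPolynomialParams:
    """Reduced-polynomial strain energy U = sum_i C_i0 (I1 - 3)^i.

    ``C`` holds (C10,) for order 1 (neo-Hookean) or (C10, C20) for order 2.
    ``D`` holds the matching compressibility coefficients in MPa^-1; they do
    not enter the incompressible response and are kept for card export.
    """

    C: tuple[float, ...]
    D: tuple[float, ...] = ()
    name: str = ""

    def __init__(self, C: Sequence[float], D: Sequence[float] = (), name: str = ""):
        object.__setattr__(self, "C", tuple(float(c) for c in C))
        object.__setattr__(self, "D", tuple(float(d) for d in D))
        object.__setattr__(self, "name", name)
        if not 1 <= len(self.C) <= 2:
            raise ValueError(f"reduced polynomial order must be 1 or 2, got {len(self.C)}")
        if not self.C[0] > 0.0:
            raise ValueError(f"C10 must be strictly positive, got {self.C[0]}")
        if any(d < 0.0 for d in self.D):
            raise ValueError("compressibility coefficients D must be non-negative")

    @property
    def order(self) -> int:
        return len(self.C)

    def energy(self, i1) -> float:
        return reduced_polynomial_energy(self, i1)

    def _dU_dI1(self, i1):
        x = i1 - 3.0
        out = self.C[0]
        if self.order == 2:
            out = out + 2.0 * self.C[1] * x
        return out

    def pk2_stresses(self, lt, lz):
        """Principal PK2 stresses (S_theta, S_z) at in-plane stretches."""
        lt = np.asarray(lt, dtype=float)
        lz = np.asarray(lz, dtype=float)
        i1 = _i1_incompressible(lt, lz)
        du = self._dU_dI1(i1)
        # dI1/dlt = 2 lt - 2 lt^-3 lz^-2 ; S_theta = (1/lt) dU/dlt
        s_t = du * (2.0 - 2.0 * lt**-4 * lz**-2)
        s_z = du * (2.0 - 2.0 * lz**-4 * lt**-2)
        return s_t, s_z


@dataclass(frozen=True)
class OgdenParams:
    """One-term Ogden energy U = (2 mu1 / alpha1^2) (sum lambda_i^alpha1 - 3).

    This is the convention used by commercial FE solvers for the N = 1
    Ogden material; alpha1 -> 2 recovers the neo-Hookean model with
    C10 = mu1 / 2.
    """

    mu1: float
    alpha1: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.mu1 > 0.0:
            raise ValueError(f"mu1 must be strictly positive, got {self.mu1}")
        if self.alpha1 == 0.0:
            raise ValueError("alpha1 must be nonzero")

    def energy(self, state: PrincipalStretchState) -> float:
        return ogden_energy(self, state)

    def pk2_stresses(self, lt, lz):
        lt = np.asarray(lt, dtype=float)
        lz = np.asarray(lz, dtype=float)
        mu, a = self.mu1, self.alpha1
        lr_a = (lt * lz) ** -a  # radial stretch to the alpha power
        s_t = (2.0 * mu / a) * (lt ** (a - 2.0) - lr_a * lt**-2)
        s_z = (2.0 * mu / a) * (lz ** (a - 2.0) - lr_a * lz**-2)
        return s_t, s_z


@dataclass(frozen=True)
class HolzapfelParams:
    """Gasser-Ogden-Holzapfel fiber-reinforced energy.

    Psi_iso = C10 (I1 - 3) + (k1 / 2 k2) sum_i [exp(k2 <Ebar_i>^2) - 1]

    with pseudo-fiber strains Ebar_i = kappa (I1 - 3) + (1 - 3 kappa)
    (I4or6 - 1).  ``arch`` houses the fiber angles and dispersion kappa.
    ``D`` (MPa^-1) is the solver near-incompressibility coefficient,
    metadata only.  Optionally a second, distinct pair of fiber moduli
    ``(k1_2, k2_2)`` may be given for family 2 (per-family moduli); by
    default both families share (k1, k2).
    """

    C10: float
    k1: float
    k2: float
    arch: FiberArchitecture = field(default_factory=FiberArchitecture)
    D: float = 0.03
    k1_2: float | None = None
    k2_2: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.C10 > 0.0:
            raise ValueError(f"C10 must be strictly positive, got {self.C10}")
        if self.k1 < 0.0:
            raise ValueError(f"k1 must be non-negative, got {self.k1}")
        if self.k1 > 0.0 and not self.k2 > 0.0:
            raise ValueError("k2 must be strictly positive when k1 > 0")
        if self.D < 0.0:
            raise ValueError(f"D must be non-negative, got {self.D}")
        if (self.k1_2 is None) != (self.k2_2 is None):
            raise ValueError("per-family moduli require both k1_2 and k2_2")

    @property
    def per_family_moduli(self) -> bool:
        return self.k1_2 is not None

    def _family_moduli(self) -> tuple[tuple[float, float], tuple[float, float]]:
        if self.per_family_moduli:
            return (self.k1, self.k2), (self.k1_2, self.k2_2)
        return (self.k1, self.k2), (self.k1, self.k2)

    def energy(self, state: PrincipalStretchState) -> float:
        return goh_isochoric_energy(self, state, self.arch)

    def volumetric_energy(self, J: float) -> float:
        """Psi_vol = (1/D) ((J^2 - 1)/2 - ln J); zero at J = 1."""
        if self.D == 0.0:
            return 0.0
        return (1.0 / self.D) * ((J**2 - 1.0) / 2.0 - np.log(J))

    def pk2_stresses(self, lt, lz, *, clip_exp: bool = False):
        """Principal PK2 stresses (S_theta, S_z), vectorised.

        ``clip_exp`` caps the fiber-term exponent so that extreme parameter
        trials during optimisation produce huge-but-finite stresses instead
        of overflowing.
        """
        lt = np.asarray(lt, dtype=float)
        lz = np.asarray(lz, dtype=float)
        with np.errstate(over="ignore" if clip_exp else "warn"):
            return self._pk2_stresses_impl(lt, lz, clip_exp)

    def _pk2_stresses_impl(self, lt, lz, clip_exp):
        kap = self.arch.kappa
        c1 = np.cos(np.radians(self.arch.alpha1_deg))
        s1 = np.sin(np.radians(self.arch.alpha1_deg))
        c2 = np.cos(np.radians(self.arch.alpha2_deg))
        s2 = np.sin(np.radians(self.arch.alpha2_deg))

        i1 = _i1_incompressible(lt, lz)
        i4 = lt**2 * c1**2 + lz**2 * s1**2
        i6 = lt**2 * c2**2 + lz**2 * s2**2
        di1_t = 2.0 * lt - 2.0 * lt**-3 * lz**-2
        di1_z = 2.0 * lz - 2.0 * lz**-3 * lt**-2

        e1 = _macaulay(kap * (i1 - 3.0) + (1.0 - 3.0 * kap) * (i4 - 1.0))
        e2 = _macaulay(kap * (i1 - 3.0) + (1.0 - 3.0 * kap) * (i6 - 1.0))

        (k1a, k2a), (k1b, k2b) = self._family_moduli()
        arg1 = k2a * e1**2
        arg2 = k2b * e2**2
        if clip_exp:
            arg1 = np.minimum(arg1, _EXP_CLIP)
            arg2 = np.minimum(arg2, _EXP_CLIP)
        f1 = k1a * e1 * np.exp(arg1)
        f2 = k1b * e2 * np.exp(arg2)

        dpsi_t = (
            self.C10 * di1_t
            + f1 * (kap * di1_t + (1.0 - 3.0 * kap) * 2.0 * lt * c1**2)
            + f2 * (kap * di1_t + (1.0 - 3.0 * kap) * 2.0 * lt * c2**2)
        )
        dpsi_z = (
            self.C10 * di1_z
            + f1 * (kap * di1_z + (1.0 - 3.0 * kap) * 2.0 * lz * s1**2)
            + f2 * (kap * di1_z + (1.0 - 3.0 * kap) * 2.0 * lz * s2**2)
        )
        return dpsi_t / lt, dpsi_z / lz


MaterialModel = Union[ReducedPolynomialParams, OgdenParams, HolzapfelParams]


def reduced_polynomial_energy(params: ReducedPolynomialParams, i1) -> float:
    """U = sum_i C_i0 (I1 - 3)^i in MPa; requires I1 >= 3."""
    i1 = float(i1)
    if i1 < 3.0 - 1e-9:
        raise ValueError(f"I1 must be >= 3 for an incompressible state, got {i1}")
    x = max(i1 - 3.0, 0.0)
    return sum(c * x ** (i + 1) for i, c in enumerate(params.C))


def ogden_energy(params: OgdenParams, state: PrincipalStretchState) -> float:
    """One-term Ogden energy in MPa; zero at the reference state."""
    mu, a = params.mu1, params.alpha1
    s = state.lambda_theta**a + state.lambda_z**a + state.lambda_r**a
    return (2.0 * mu / a**2) * (s - 3.0)


def goh_pseudo_strains(
    arch: FiberArchitecture, i1: float, i4: float, i6: float
) -> tuple[float, float]:
    """Raw pseudo-fiber strains (Ebar1, Ebar2) before the Macaulay bracket.

    Ebar_i = kappa (I1 - 3) + (1 - 3 kappa) (I4or6 - 1).  At kappa = 1/3
    both collapse to (I1 - 3)/3 regardless of fiber direction (fully
    dispersed fibers).
    """
    if not 0.0 <= arch.kappa <= 1.0 / 3.0 + 1e-12:
        raise ValueError(f"kappa must lie in [0, 1/3], got {arch.kappa}")
    if i1 < 3.0 - 1e-9:
        raise ValueError(f"I1 must be >= 3, got {i1}")
    if i4 <= 0.0 or i6 <= 0.0:
        raise ValueError("I4 and I6 must be strictly positive")
    kap = arch.kappa
    e1 = kap * (i1 - 3.0) + (1.0 - 3.0 * kap) * (i4 - 1.0)
    e2 = kap * (i1 - 3.0) + (1.0 - 3.0 * kap) * (i6 - 1.0)
    return e1, e2


def goh_isochoric_energy(
    params: HolzapfelParams,
    state: PrincipalStretchState,
    arch: FiberArchitecture | None = None,
) -> float:
    """Isochoric GOH energy Psi_iso in MPa at a principal-stretch state.

    Only the tensile part of each pseudo-fiber strain contributes
    (Macaulay bracket).  Raises OverflowError if the fiber exponent would
    overflow exp().
    """
    arch = params.arch if arch is None else arch
    i1, i4, i6 = invariants(state, arch)
    e1, e2 = goh_pseudo_strains(arch, i1, i4, i6)
    e1, e2 = max(e1, 0.0), max(e2, 0.0)
    iso = params.C10 * (i1 - 3.0)
    for (k1, k2), e in zip(params._family_moduli(), (e1, e2)):
        if k1 == 0.0:
            continue
        arg = k2 * e**2
        if arg > _EXP_OVERFLOW:
            raise OverflowError(
                f"fiber energy exponent k2*E^2 = {arg:.3g} overflows exp() "
                f"(Ebar = {e:.6g}, k2 = {k2:.6g})"
            )
        iso += (k1 / (2.0 * k2)) * (np.exp(arg) - 1.0)
    return float(iso)
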