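"""Analytic film-on-substrate wrinkling estimates for Bruch's membrane.

A stiff thin film bonded to a compliant half-space buckles into sinusoidal
wrinkles once the in-plane compressive strain passes a critical value.
The classical small-strain relations for an incompressible bilayer are

    eps_c    = (1/4) (3 Ebar_s / Ebar_f)^(2/3)
    lambda_w = 2 pi h (Ebar_f / (3 Ebar_s))^(1/3)
    A        = h sqrt(eps / eps_c - 1)        (0 below onset)

with h the film thickness and Ebar the plane-strain moduli.  Applied to
Bruch's membrane (the stiff ~5 um lamina between retina and choroid) this
gives a desk-scale order-of-magnitude check on the wrinkling that full
finite-element simulations of large eye rotations predict at the
retina-Bruch's-choroid interface.  The membrane sits between two soft
layers, so the retina- and choroid-substrate estimates are reported as
brackets rather than committing to a homogenised substrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LayerSpec",
    "WrinkleEstimate",
    "plane_strain_modulus",
    "wrinkle_estimate",
    "BM_THICKNESS_UM",
]

#: Anatomical thickness of Bruch's membrane used throughout, in micrometres.
BM_THICKNESS_UM = 5.0


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the bilayer: a name, a neo-Hookean C10, and (for the
    film) a thickness in micrometres."""

    name: str
    C10: float
    thickness_um: float | None = None

    def __post_init__(self) -> None:
        if not self.C10 > 0.0:
            raise ValueError(f"C10 must be strictly positive, got {self.C10}")
        if self.thickness_um is not None and not self.thickness_um > 0.0:
            raise ValueError(f"thickness must be strictly positive, got {self.thickness_um}")


@dataclass(frozen=True)
class WrinkleEstimate:
    wavelength_um: float
    critical_strain: float
    amplitude_um: float
    film: str = ""
    substrate: str = ""


def plane_strain_modulus(C10: float) -> float:
    """Plane-strain modulus of an incompressible neo-Hookean solid, MPa.

    Small-strain limit: shear modulus mu = 2 C10, Young's modulus
    E = 3 mu, and Ebar = E / (1 - nu^2) with nu = 1/2, i.e. Ebar = 8 C10.
    """
    if not C10 > 0.0:
        raise ValueError(f"C10 must be strictly positive, got {C10}")
    return 8.0 * C10


def wrinkle_estimate(
    film: LayerSpec, substrate: LayerSpec, applied_strain: float = 0.0
) -> WrinkleEstimate:
    """Wrinkle wavelength, critical strain and amplitude for the bilayer.

    Requires a film stiffer than its substrate (the film-dominated
    buckling regime) and a film thickness.  Amplitude is zero at or below
    the critical strain.
    """
    if applied_strain < 0.0:
        raise ValueError(f"applied strain must be non-negative, got {applied_strain}")
    if film.thickness_um is None:
        raise ValueError("film layer needs a thickness")
    e_f = plane_strain_modulus(film.C10)
    e_s = plane_strain_modulus(substrate.C10)
    if e_f <= e_s:
        raise ValueError(
            f"film ({film.name}: {e_f:.4g} MPa) must be stiffer than substrate "
            f"({substrate.name}: {e_s:.4g} MPa) for film-dominated wrinkling"
        )
    h = film.thickness_um
    eps_c = 0.25 * (3.0 * e_s / e_f) ** (2.0 / 3.0)
    wavelength = 2.0 * math.pi * h * (e_f / (3.0 * e_s)) ** (1.0 / 3.0)
    if applied_strain > eps_c:
        amplitude = h * math.sqrt(applied_strain / eps_c - 1.0)
    else:
        amplitude = 0.0
    return WrinkleEstimate(
        wavelength_um=wavelength,
        critical_strain=eps_c,
        amplitude_um=amplitude,
        film=film.name,
        substrate=substrate.name,
    )
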