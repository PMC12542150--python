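"""Uniaxial tensile-test analysis: stress measures and model response.

Strip tensile tests report engineering stress against engineering strain.
Constitutive fitting happens in the reference configuration, so raw curves
are re-expressed as second Piola-Kirchhoff (PK2) stress against
Green-Lagrange strain.  For an incompressible uniaxial state with stretch
``lambda`` along the pull axis the chain is pointwise:

    lambda  = 1 + eps_eng
    E       = (lambda**2 - 1) / 2
    sigma_c = sigma_eng * lambda          (Cauchy)
    S       = sigma_c / lambda**2         (PK2)  = sigma_eng / lambda

Model-predicted curves are generated under uniaxial stress: the in-plane
transverse stretch is solved from the zero-transverse-PK2 condition (the
radial stress already vanishes through the incompressibility substitution),
and the axial PK2 stress is evaluated at the solved state.  For isotropic
materials the solve lands on the classical lambda**(-1/2).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import brentq

from .kinematics import incompressible_state
from .models import HolzapfelParams, MaterialModel

__all__ = [
    "Direction",
    "StrainMeasure",
    "StressMeasure",
    "StressStrainCurve",
    "TensileDataset",
    "cauchy_from_engineering",
    "pk2_uniaxial_from_engineering",
    "engineering_from_pk2_uniaxial",
    "pk2_principal_stresses",
    "uniaxial_response",
    "uniaxial_response_grid",
    "reanalyze_raw_curve",
]


class Direction(str, enum.Enum):
    CIRCUMFERENTIAL = "circumferential"
    LONGITUDINAL = "longitudinal"
    AVERAGED = "averaged"


class StrainMeasure(str, enum.Enum):
    ENGINEERING = "engineering"
    GREEN_LAGRANGE = "green_lagrange"


class StressMeasure(str, enum.Enum):
    ENGINEERING = "engineering"
    CAUCHY = "cauchy"
    PK2 = "pk2"


@dataclass
class StressStrainCurve:
    """A single-direction tensile curve with explicit measure tags.

    ``strain`` must be strictly increasing and start at or above zero;
    ``stress`` is in MPa and must vanish (to 1e-9) at zero strain.
    """

    direction: Direction
    strain_measure: StrainMeasure
    stress_measure: StressMeasure
    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.direction = Direction(self.direction)
        self.strain_measure = StrainMeasure(self.strain_measure)
        self.stress_measure = StressMeasure(self.stress_measure)
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.ndim != 1 or self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if self.strain.size and self.strain[0] < 0.0:
            raise ValueError("strain must start at or above zero")
        if np.any(np.diff(self.strain) <= 0.0):
            raise ValueError("strain must be strictly increasing")
        if self.strain.size and self.strain[0] == 0.0 and abs(self.stress[0]) > 1e-9:
            raise ValueError("stress at zero strain must be zero")

    def __len__(self) -> int:
        return self.strain.size


@dataclass
class TensileDataset:
    """Paired circumferential and longitudinal curves in common measures."""

    circumferential: StressStrainCurve
    longitudinal: StressStrainCurve
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c, l = self.circumferential, self.longitudinal
        if (c.strain_measure, c.stress_measure) != (l.strain_measure, l.stress_measure):
            raise ValueError("both curves must share strain and stress measures")

    @property
    def strain_measure(self) -> StrainMeasure:
        return self.circumferential.strain_measure

    @property
    def stress_measure(self) -> StressMeasure:
        return self.circumferential.stress_measure


def cauchy_from_engineering(sigma_eng, lam):
    """Cauchy stress sigma_c = sigma_eng * lambda for uniaxial incompressible loading."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be strictly positive")
    return np.asarray(sigma_eng, dtype=float) * lam


def pk2_uniaxial_from_engineering(sigma_eng, lam):
    """PK2 stress S = sigma_c / lambda**2 = sigma_eng / lambda (diagonal push-forward)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be strictly positive")
    return np.asarray(sigma_eng, dtype=float) / lam


def engineering_from_pk2_uniaxial(s_pk2, lam):
    """Inverse of :func:`pk2_uniaxial_from_engineering`: sigma_eng = S * lambda."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be strictly positive")
    return np.asarray(s_pk2, dtype=float) * lam


def pk2_principal_stresses(model: MaterialModel, state, arch=None) -> tuple[float, float]:
    """(S_theta, S_z) from analytic differentiation of the condensed energy.

    ``arch`` overrides the fiber architecture of a Holzapfel model; it is
    ignored for isotropic models.
    """
    if arch is not None and isinstance(model, HolzapfelParams):
        model = HolzapfelParams(
            model.C10, model.k1, model.k2, arch=arch, D=model.D,
            k1_2=model.k1_2, k2_2=model.k2_2, name=model.name,
        )
    s_t, s_z = model.pk2_stresses(state.lambda_theta, state.lambda_z)
    return float(s_t), float(s_z)


_BRACKET = (0.2, 1.5)
_BRACKET_WIDE = (0.05, 3.0)


def _transverse_stress_fn(model: MaterialModel, lam_axial: float, axis: str):
    """S_transverse as a function of the transverse in-plane stretch."""
    kwargs = {"clip_exp": True} if isinstance(model, HolzapfelParams) else {}

    if axis == "theta":
        def f(l_trans):
            return model.pk2_stresses(lam_axial, l_trans, **kwargs)[1]
    elif axis == "z":
        def f(l_trans):
            return model.pk2_stresses(l_trans, lam_axial, **kwargs)[0]
    else:
        raise ValueError(f"axis must be 'theta' or 'z', got {axis!r}")
    return f


def uniaxial_response(
    model: MaterialModel, lambda_axial: float, axis: str = "theta", arch=None
) -> tuple[float, float]:
    """Axial PK2 stress and transverse stretch under uniaxial stress.

    Solves S_transverse(lambda_trans) = 0 by Brent's method on the bracket
    [0.2, 1.5] (widened once to [0.05, 3.0] before failing), then evaluates
    the axial PK2 stress at the solved state.

    Returns
    -------
    (S_axial, lambda_transverse)
    """
    if lambda_axial < 1.0:
        raise ValueError(f"lambda_axial must be >= 1, got {lambda_axial}")
    if arch is not None and isinstance(model, HolzapfelParams):
        model = HolzapfelParams(
            model.C10, model.k1, model.k2, arch=arch, D=model.D,
            k1_2=model.k1_2, k2_2=model.k2_2, name=model.name,
        )
    f = _transverse_stress_fn(model, float(lambda_axial), axis)
    lo, hi = _BRACKET
    if np.sign(f(lo)) == np.sign(f(hi)):
        lo, hi = _BRACKET_WIDE
        if np.sign(f(lo)) == np.sign(f(hi)):
            raise RuntimeError(
                f"no sign change for transverse stress in [{lo}, {hi}] at "
                f"lambda_axial = {lambda_axial} (f({lo}) = {f(lo):.3g}, "
                f"f({hi}) = {f(hi):.3g})"
            )
    l_trans = brentq(f, lo, hi, xtol=1e-10)
    kwargs = {"clip_exp": True} if isinstance(model, HolzapfelParams) else {}
    if axis == "theta":
        s_axial = model.pk2_stresses(lambda_axial, l_trans, **kwargs)[0]
    else:
        s_axial = model.pk2_stresses(l_trans, lambda_axial, **kwargs)[1]
    return float(s_axial), float(l_trans)


def uniaxial_response_grid(
    model: MaterialModel, lambdas_axial: np.ndarray, axis: str = "theta"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised uniaxial response over a whole stretch grid.

    The transverse solve runs as a fixed-count bracketed bisection on all
    grid points simultaneously (48 halvings of [0.2, 1.5], terminal width
    ~5e-15), which keeps parameter-identification objectives cheap.  Agrees
    with the scalar :func:`uniaxial_response` to solver tolerance.
    """
    lams = np.asarray(lambdas_axial, dtype=float)
    if np.any(lams < 1.0):
        raise ValueError("lambda_axial grid must be >= 1")
    kwargs = {"clip_exp": True} if isinstance(model, HolzapfelParams) else {}

    if axis == "theta":
        def s_trans(l_t):
            return model.pk2_stresses(lams, l_t, **kwargs)[1]
    elif axis == "z":
        def s_trans(l_t):
            return model.pk2_stresses(l_t, lams, **kwargs)[0]
    else:
        raise ValueError(f"axis must be 'theta' or 'z', got {axis!r}")

    lo = np.full_like(lams, _BRACKET[0])
    hi = np.full_like(lams, _BRACKET[1])
    f_lo = s_trans(lo)
    if np.any(np.sign(f_lo) == np.sign(s_trans(hi))):
        lo = np.full_like(lams, _BRACKET_WIDE[0])
        hi = np.full_like(lams, _BRACKET_WIDE[1])
        f_lo = s_trans(lo)
        if np.any(np.sign(f_lo) == np.sign(s_trans(hi))):
            raise RuntimeError("no sign change for transverse stress on widened bracket")
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        f_mid = s_trans(mid)
        same = np.sign(f_mid) == np.sign(f_lo)
        lo = np.where(same, mid, lo)
        f_lo = np.where(same, f_mid, f_lo)
        hi = np.where(same, hi, mid)
    l_trans = 0.5 * (lo + hi)

    if axis == "theta":
        s_axial = model.pk2_stresses(lams, l_trans, **kwargs)[0]
    else:
        s_axial = model.pk2_stresses(l_trans, lams, **kwargs)[1]
    return np.asarray(s_axial, dtype=float), l_trans


def reanalyze_raw_curve(curve: StressStrainCurve) -> StressStrainCurve:
    """Re-express a raw engineering/engineering curve as Green-Lagrange / PK2.

    Pointwise: lambda = 1 + eps, E = (lambda**2 - 1)/2, S = sigma_eng / lambda.
    """
    if curve.strain_measure is not StrainMeasure.ENGINEERING:
        raise ValueError(f"expected engineering strain, got {curve.strain_measure.value}")
    if curve.stress_measure is not StressMeasure.ENGINEERING:
        raise ValueError(f"expected engineering stress, got {curve.stress_measure.value}")
    lam = 1.0 + curve.strain
    return StressStrainCurve(
        direction=curve.direction,
        strain_measure=StrainMeasure.GREEN_LAGRANGE,
        stress_measure=StressMeasure.PK2,
        strain=(lam**2 - 1.0) / 2.0,
        stress=curve.stress / lam,
    )
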