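"""Synthetic uniaxial tensile datasets from a known constitutive model.

The generator emulates the structure of re-analyzed strip-test data for
the optic nerve sheath: paired circumferential and longitudinal uniaxial
curves on a 0-50% engineering-strain grid, expressed in any of the
supported strain/stress measures, with optional seeded Gaussian noise.
Because the generating parameters are known, a generate-then-refit loop
measures parameter recoverability of the identification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import MaterialModel
from .tension import (
    Direction,
    StrainMeasure,
    StressMeasure,
    StressStrainCurve,
    TensileDataset,
    uniaxial_response_grid,
)

__all__ = ["GeneratorSpec", "generate_tensile_dataset", "generate_curve"]

_AXIS_FOR_DIRECTION = {
    Direction.CIRCUMFERENTIAL: "theta",
    Direction.LONGITUDINAL: "z",
}


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic tensile dataset.

    Parameters
    ----------
    model
        Generating constitutive model.
    strain_grid
        Engineering-strain abscissa; default 50 evenly spaced points over
        0-0.5 (the 0-50% range of the tensile protocol).
    noise_sd_fraction
        Standard deviation of additive Gaussian stress noise as a fraction
        of the maximum noiseless stress of each curve; 0 disables noise.
    noise_model
        'additive' (default) or 'multiplicative' (per-point relative).
    seed
        Seed for the noise stream; the same seed reproduces the dataset
        bit for bit.
    directions
        Which curves to generate; both by default.
    strain_measure, stress_measure
        Output measures; defaults are the fitting space (Green-Lagrange
        strain, PK2 stress).
    """

    model: MaterialModel
    strain_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 0.5, 50)
    )
    noise_sd_fraction: float = 0.0
    noise_model: str = "additive"
    seed: int | None = None
    directions: Sequence[Direction] = (
        Direction.CIRCUMFERENTIAL,
        Direction.LONGITUDINAL,
    )
    strain_measure: StrainMeasure = StrainMeasure.GREEN_LAGRANGE
    stress_measure: StressMeasure = StressMeasure.PK2

    def __post_init__(self) -> None:
        self.strain_grid = np.asarray(self.strain_grid, dtype=float)
        if np.any(np.diff(self.strain_grid) <= 0.0):
            raise ValueError("strain grid must be strictly increasing")
        if self.strain_grid[0] < 0.0 or self.strain_grid[-1] > 0.5 + 1e-12:
            raise ValueError("engineering-strain grid must lie within [0, 0.5]")
        if self.noise_sd_fraction < 0.0:
            raise ValueError("noise fraction must be non-negative")
        if self.noise_model not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        self.directions = tuple(Direction(d) for d in self.directions)
        self.strain_measure = StrainMeasure(self.strain_measure)
        self.stress_measure = StressMeasure(self.stress_measure)


def generate_curve(
    spec: GeneratorSpec, direction: Direction, rng: np.random.Generator
) -> StressStrainCurve:
    """One direction's synthetic curve; noise drawn from ``rng``."""
    direction = Direction(direction)
    axis = _AXIS_FOR_DIRECTION[direction]
    eps = spec.strain_grid
    lam = 1.0 + eps
    s_pk2, _ = uniaxial_response_grid(spec.model, lam, axis=axis)

    if spec.stress_measure is StressMeasure.PK2:
        stress = s_pk2
    elif spec.stress_measure is StressMeasure.CAUCHY:
        stress = s_pk2 * lam**2
    else:
        stress = s_pk2 * lam

    if spec.strain_measure is StrainMeasure.GREEN_LAGRANGE:
        strain = (lam**2 - 1.0) / 2.0
    else:
        strain = eps

    stress = stress.copy()
    if spec.noise_sd_fraction > 0.0:
        if spec.noise_model == "additive":
            sd = spec.noise_sd_fraction * np.max(np.abs(stress))
            stress = stress + rng.normal(0.0, sd, size=stress.shape)
        else:
            stress = stress * (1.0 + rng.normal(0.0, spec.noise_sd_fraction, size=stress.shape))
    if strain[0] == 0.0:
        stress[0] = 0.0  # the unloaded specimen carries no stress
    return StressStrainCurve(
        direction=direction,
        strain_measure=spec.strain_measure,
        stress_measure=spec.stress_measure,
        strain=strain,
        stress=stress,
    )


def generate_tensile_dataset(spec: GeneratorSpec) -> TensileDataset:
    """Paired synthetic curves per the spec; metadata records provenance.

    Noise is drawn from a single seeded stream in fixed direction order
    (circumferential first), so identical specs yield identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    curves: dict[Direction, StressStrainCurve] = {}
    for direction in (Direction.CIRCUMFERENTIAL, Direction.LONGITUDINAL):
        if direction in spec.directions:
            curves[direction] = generate_curve(spec, direction, rng)
    if set(curves) != {Direction.CIRCUMFERENTIAL, Direction.LONGITUDINAL}:
        raise ValueError("a TensileDataset needs both directions; "
                         "use generate_curve for a single direction")
    meta = {
        "generator": {
            "model": repr(spec.model),
            "noise_sd_fraction": spec.noise_sd_fraction,
            "noise_model": spec.noise_model,
            "seed": spec.seed,
            "n_points": int(spec.strain_grid.size),
            "strain_range_eng": (float(spec.strain_grid[0]), float(spec.strain_grid[-1])),
        }
    }
    return TensileDataset(
        circumferential=curves[Direction.CIRCUMFERENTIAL],
        longitudinal=curves[Direction.LONGITUDINAL],
        metadata=meta,
    )
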