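"""File formats and unit conversions.

Curve CSV dialect: UTF-8, comma-separated, dot decimal; one metadata line
declaring the measures, then one header line, then rows:

    # direction=circumferential,strain_measure=engineering,stress_measure=engineering
    strain,stress_MPa
    0,0
    0.25,2

Values are written at full precision (shortest round-trippable repr), so a
write/read cycle is bit-identical.  Material cards are deterministic plain
text with parameters in a documented fixed order, parseable back into the
same model.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .kinematics import FiberArchitecture
from .models import HolzapfelParams, MaterialModel, OgdenParams, ReducedPolynomialParams
from .tension import Direction, StrainMeasure, StressMeasure, StressStrainCurve

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "pressure_mmHg_to_kPa",
    "export_material_card",
    "parse_material_card",
]

_MMHG_TO_KPA = 0.1333224


class CurveFormatError(ValueError):
    """Malformed curve CSV; message carries the offending line number."""


def write_curve_csv(curve: StressStrainCurve, path: str | Path) -> None:
    """Write a curve in the package CSV dialect (full float precision)."""
    lines = [
        f"# direction={curve.direction.value},"
        f"strain_measure={curve.strain_measure.value},"
        f"stress_measure={curve.stress_measure.value}",
        "strain,stress_MPa",
    ]
    lines += [f"{float(e)!r},{float(s)!r}" for e, s in zip(curve.strain, curve.stress)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_curve_csv(path: str | Path) -> StressStrainCurve:
    """Read a curve CSV, validating metadata, header and monotonic strain."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# "):
        raise CurveFormatError(f"{path}: line 1: missing '# key=value,...' metadata line")
    meta: dict[str, str] = {}
    for item in lines[0][2:].split(","):
        if "=" not in item:
            raise CurveFormatError(f"{path}: line 1: malformed metadata item {item!r}")
        key, value = item.split("=", 1)
        meta[key.strip()] = value.strip()
    for key in ("direction", "strain_measure", "stress_measure"):
        if key not in meta:
            raise CurveFormatError(f"{path}: line 1: missing metadata field {key!r}")
    try:
        direction = Direction(meta["direction"])
        strain_measure = StrainMeasure(meta["strain_measure"])
        stress_measure = StressMeasure(meta["stress_measure"])
    except ValueError as exc:
        raise CurveFormatError(f"{path}: line 1: {exc}") from None
    if len(lines) < 2 or lines[1].strip() != "strain,stress_MPa":
        raise CurveFormatError(f"{path}: line 2: expected header 'strain,stress_MPa'")
    strain, stress = [], []
    for i, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise CurveFormatError(f"{path}: line {i}: expected two comma-separated values")
        try:
            e, s = float(parts[0]), float(parts[1])
        except ValueError:
            raise CurveFormatError(f"{path}: line {i}: non-numeric value") from None
        if not (np.isfinite(e) and np.isfinite(s)):
            raise CurveFormatError(f"{path}: line {i}: non-finite value")
        if strain and e <= strain[-1]:
            raise CurveFormatError(f"{path}: line {i}: strain not strictly increasing")
        strain.append(e)
        stress.append(s)
    return StressStrainCurve(
        direction=direction,
        strain_measure=strain_measure,
        stress_measure=stress_measure,
        strain=np.array(strain),
        stress=np.array(stress),
    )


def pressure_mmHg_to_kPa(p_mmHg: float, round_decimals: int | None = 1) -> float:
    """Convert mmHg to kPa (1 mmHg = 0.1333224 kPa), half-even rounding.

    ``round_decimals=None`` returns the unrounded value.
    """
    if p_mmHg < 0.0:
        raise ValueError(f"pressure must be non-negative, got {p_mmHg}")
    kpa = p_mmHg * _MMHG_TO_KPA
    if round_decimals is None:
        return kpa
    return float(np.round(kpa, round_decimals))


# Material-card parameter orders (documented, fixed):
#   reduced polynomial / neo-Hookean : C10[, C20], D1[, D2]
#   ogden (one term)                 : mu1, alpha1
#   holzapfel                        : C10, D, k1, k2, kappa  (+ angle line)
def export_material_card(model: MaterialModel, tissue_name: str) -> str:
    """Solver-style plain-text echo of a parameter set."""
    lines = [f"*material, name={tissue_name}"]
    if isinstance(model, ReducedPolynomialParams):
        d = list(model.D) + [0.0] * (model.order - len(model.D))
        header = ", ".join(
            [f"C{i+1}0 (MPa)" for i in range(model.order)]
            + [f"D{i+1} (MPa^-1)" for i in range(model.order)]
        )
        lines += [
            f"*hyperelastic, reduced polynomial, n={model.order}",
            f"** {header}",
            ", ".join(repr(float(v)) for v in (*model.C, *d)),
        ]
    elif isinstance(model, OgdenParams):
        lines += [
            "*hyperelastic, ogden, n=1",
            "** mu1 (MPa), alpha1 (-)",
            f"{float(model.mu1)!r}, {float(model.alpha1)!r}",
        ]
    elif isinstance(model, HolzapfelParams):
        if model.per_family_moduli:
            raise ValueError("per-family fiber moduli have no card form")
        lines += [
            "*anisotropic hyperelastic, holzapfel",
            f"** fiber angles from theta-axis (deg): "
            f"alpha1={float(model.arch.alpha1_deg)!r}, alpha2={float(model.arch.alpha2_deg)!r}",
            "** C10 (MPa), D (MPa^-1), k1 (MPa), k2 (-), kappa (-)",
            ", ".join(
                repr(float(v))
                for v in (model.C10, model.D, model.k1, model.k2, model.arch.kappa)
            ),
        ]
    else:
        raise ValueError(f"cannot export model of type {type(model).__name__}")
    return "\n".join(lines) + "\n"


def parse_material_card(text: str) -> tuple[MaterialModel, str]:
    """Invert :func:`export_material_card`; returns (model, tissue_name)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("*material, name="):
        raise ValueError("card must start with '*material, name=...'")
    name = lines[0].split("=", 1)[1].strip()
    kind = lines[1].strip().lower()
    values = [float(v) for v in lines[-1].split(",")]
    if kind.startswith("*hyperelastic, reduced polynomial"):
        order = int(kind.rsplit("n=", 1)[1])
        if len(values) != 2 * order:
            raise ValueError(f"expected {2 * order} values for order-{order} polynomial")
        return ReducedPolynomialParams(C=values[:order], D=values[order:], name=name), name
    if kind.startswith("*hyperelastic, ogden"):
        if len(values) != 2:
            raise ValueError("expected mu1, alpha1")
        return OgdenParams(mu1=values[0], alpha1=values[1], name=name), name
    if kind.startswith("*anisotropic hyperelastic, holzapfel"):
        if len(values) != 5:
            raise ValueError("expected C10, D, k1, k2, kappa")
        angle_line = next((ln for ln in lines if "fiber angles" in ln), None)
        a1, a2 = 0.0, 90.0
        if angle_line is not None:
            fields = dict(
                item.strip().split("=")
                for item in angle_line.split(":")[-1].split(",")
            )
            a1, a2 = float(fields["alpha1"]), float(fields["alpha2"])
        arch = FiberArchitecture(a1, a2, values[4])
        return (
            HolzapfelParams(C10=values[0], D=values[1], k1=values[2], k2=values[3],
                            arch=arch, name=name),
            name,
        )
    raise ValueError(f"unrecognised card type line: {lines[1]!r}")
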