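"""Tissue material library: named coefficient sets loaded from YAML.

The packaged ``data/materials.yaml`` ships the standard ocular tissue
palette (sclera regions, optic nerve, retina, choroid, Bruch's membrane,
lamina cribrosa, and the optic nerve sheath in both its isotropic and
fiber-reinforced descriptions).  User configs with the same schema can be
loaded from any path.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .kinematics import FiberArchitecture
from .models import HolzapfelParams, MaterialModel, OgdenParams, ReducedPolynomialParams

__all__ = ["load_material", "load_material_config", "tissue_registry"]


def _model_from_entry(name: str, entry: dict[str, Any]) -> MaterialModel:
    try:
        kind = entry["model"]
    except KeyError:
        raise ValueError(f"tissue {name!r}: missing 'model' tag") from None
    if kind == "reduced_polynomial":
        c = [entry["C10"]]
        if "C20" in entry:
            c.append(entry["C20"])
        d = [entry[k] for k in ("D1", "D2") if k in entry]
        return ReducedPolynomialParams(C=c, D=d, name=name)
    if kind == "neo_hookean":
        d = [entry[k] for k in ("D1", "D") if k in entry]
        return ReducedPolynomialParams(C=[entry["C10"]], D=d, name=name)
    if kind == "ogden":
        return OgdenParams(mu1=entry["mu1"], alpha1=entry["alpha1"], name=name)
    if kind == "holzapfel":
        arch = FiberArchitecture(
            alpha1_deg=entry.get("alpha1_deg", 0.0),
            alpha2_deg=entry.get("alpha2_deg", 90.0),
            kappa=entry["kappa"],
        )
        return HolzapfelParams(
            C10=entry["C10"], k1=entry["k1"], k2=entry["k2"],
            arch=arch, D=entry.get("D", 0.03),
            k1_2=entry.get("k1_2"), k2_2=entry.get("k2_2"),
            name=name,
        )
    raise ValueError(f"tissue {name!r}: unknown model tag {kind!r}")


def load_material_config(path: str | Path | None = None) -> dict[str, MaterialModel]:
    """Parse a tissue config file (packaged default when no path given)."""
    if path is None:
        text = resources.files("ocumech").joinpath("data/materials.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "tissues" not in raw:
        raise ValueError("material config must have a top-level 'tissues' mapping")
    return {name: _model_from_entry(name, entry) for name, entry in raw["tissues"].items()}


def tissue_registry() -> dict[str, MaterialModel]:
    """The packaged tissue palette keyed by tissue name."""
    return load_material_config(None)


def load_material(name: str, path: str | Path | None = None) -> MaterialModel:
    """A single named tissue model from a config (packaged default)."""
    registry = load_material_config(path)
    try:
        return registry[name]
    except KeyError:
        known = ", ".join(sorted(registry))
        raise KeyError(f"unknown tissue {name!r}; known tissues: {known}") from None
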