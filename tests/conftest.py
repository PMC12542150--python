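import numpy as np
import pytest

from ocumech.kinematics import FiberArchitecture
from ocumech.models import HolzapfelParams, OgdenParams, ReducedPolynomialParams


@pytest.fixture(scope="session")
def ons_anisotropic() -> HolzapfelParams:
    """Fitted fiber-reinforced sheath model (circumferential + longitudinal families)."""
    return HolzapfelParams(
        C10=0.8, k1=32.2, k2=79.1,
        arch=FiberArchitecture(alpha1_deg=0.0, alpha2_deg=90.0, kappa=0.29),
        D=0.03, name="ons_anisotropic",
    )


@pytest.fixture(scope="session")
def ons_isotropic() -> ReducedPolynomialParams:
    return ReducedPolynomialParams(C=(2.3,), name="ons_isotropic")


@pytest.fixture(scope="session")
def optic_nerve_rp() -> ReducedPolynomialParams:
    return ReducedPolynomialParams(C=(0.23, 8.18), name="optic_nerve")


@pytest.fixture(scope="session")
def lamina_ogden() -> OgdenParams:
    return OgdenParams(mu1=0.36, alpha1=10.4, name="lamina_cribrosa")


@pytest.fixture(scope="session")
def rp_tissues() -> dict[str, ReducedPolynomialParams]:
    """The order-2 reduced-polynomial tissue palette."""
    table = {
        "optic_nerve": (0.23, 8.18),
        "peripapillary_sclera": (0.20, 11.60),
        "anterior_sclera": (2.25, 102.20),
        "equatorial_sclera": (0.87, 91.30),
        "posterior_sclera": (0.80, 32.8),
    }
    return {k: ReducedPolynomialParams(C=v, name=k) for k, v in table.items()}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
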