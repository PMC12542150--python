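"""Independent numerical oracles shared by the test modules."""

from ocumech.kinematics import FiberArchitecture, incompressible_state, invariants
from ocumech.models import (
    OgdenParams,
    ReducedPolynomialParams,
    goh_isochoric_energy,
    ogden_energy,
    reduced_polynomial_energy,
)


def hat_energy(model, lt, lz):
    """Condensed energy Psi_hat(lt, lz) with the radial stretch eliminated."""
    state = incompressible_state(lt, lz)
    if isinstance(model, ReducedPolynomialParams):
        i1, _, _ = invariants(state, FiberArchitecture())
        return reduced_polynomial_energy(model, i1)
    if isinstance(model, OgdenParams):
        return ogden_energy(model, state)
    return goh_isochoric_energy(model, state)


def fd_pk2(model, lt, lz, h=1e-6):
    """Central-difference PK2 stresses: the oracle for analytic stresses."""
    s_t = (hat_energy(model, lt + h, lz) - hat_energy(model, lt - h, lz)) / (2 * h) / lt
    s_z = (hat_energy(model, lt, lz + h) - hat_energy(model, lt, lz - h)) / (2 * h) / lz
    return s_t, s_z
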