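"""Uniaxial stress predictions for the packaged ocular tissue palette.

For each tissue the transverse stretch is solved from the zero
transverse-stress condition and the axial Cauchy stress is reported at
10% and 30% engineering strain.  The spread over four orders of
magnitude — retina softest, anterior sclera stiffest — is what makes the
posterior eye mechanically heterogeneous.
"""

from ocumech import tissue_registry, uniaxial_response

print(f"{'tissue':24s} {'sigma(10%) MPa':>15s} {'sigma(30%) MPa':>15s}")
for name, model in sorted(tissue_registry().items()):
    row = []
    for lam in (1.1, 1.3):
        s_pk2, _ = uniaxial_response(model, lam)
        row.append(s_pk2 * lam**2)  # Cauchy = PK2 * lambda^2 (uniaxial)
    print(f"{name:24s} {row[0]:15.4f} {row[1]:15.4f}")
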