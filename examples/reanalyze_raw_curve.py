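"""Re-express a raw tensile curve in reference-configuration measures.

A strip test reports engineering stress vs engineering strain.  Fitting
happens against second Piola-Kirchhoff stress over Green-Lagrange strain,
so each point is mapped through lambda = 1 + eps, E = (lambda^2 - 1)/2,
S = sigma_eng / lambda.  The printed table shows how the two descriptions
of the same test diverge as strain grows.
"""

import numpy as np

from ocumech import (
    Direction,
    StrainMeasure,
    StressMeasure,
    StressStrainCurve,
    reanalyze_raw_curve,
)

eps = np.array([0.0, 0.1, 0.25, 0.4, 0.5])
sigma = np.array([0.0, 0.08, 0.42, 1.35, 2.40])  # MPa, engineering

raw = StressStrainCurve(
    direction=Direction.CIRCUMFERENTIAL,
    strain_measure=StrainMeasure.ENGINEERING,
    stress_measure=StressMeasure.ENGINEERING,
    strain=eps,
    stress=sigma,
)
ref = reanalyze_raw_curve(raw)

print("eps_eng  sigma_eng   E_GL     S_PK2   (stress in MPa)")
for e, s, eg, sp in zip(raw.strain, raw.stress, ref.strain, ref.stress):
    print(f"{e:7.3f} {s:9.3f} {eg:8.4f} {sp:8.4f}")
print("\nAt 50% engineering strain the Green-Lagrange strain is 0.625 and")
print("the PK2 stress sits a factor 1.5 below the engineering stress.")
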