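# ocumech

Hyperelastic constitutive modelling and inverse parameter identification
for ocular soft tissues, centred on the tensile anisotropy of the optic
nerve sheath (ONS) — the collagen/elastin tube that encases the optic
nerve and carries much of the load the posterior eye sees during large
eye rotations.

The package is for biomechanics researchers who need to (a) re-analyze
uniaxial tensile curves of thin ocular tissues in proper
finite-deformation measures, (b) identify constitutive parameters for
isotropic and fiber-reinforced hyperelastic models from such curves, and
(c) export the resulting material definitions for finite-element solvers.

## Models and methods

All tissues are treated as incompressible and hyperelastic. Three
strain-energy families are implemented with analytic second
Piola–Kirchhoff (PK2) stresses:

* **Reduced polynomial** (isotropic tissues; order 1 = neo-Hookean):
  `U = Σₙ C_n0 (Ī₁ − 3)ⁿ`, n ≤ 2.
* **One-term Ogden** (lamina cribrosa):
  `U = (2μ₁/α₁²)(λ₁^α₁ + λ₂^α₁ + λ₃^α₁ − 3)`.
* **Gasser–Ogden–Holzapfel (GOH)** fiber-reinforced model (anisotropic ONS):
  `Ψ = C₁₀(Ī₁ − 3) + (k₁/2k₂) Σᵢ₌₁,₂ [exp(k₂⟨Ē_i⟩²) − 1]`,
  with pseudo-fiber strains `Ē_i = κ(Ī₁ − 3) + (1 − 3κ)(Ī_{4,6} − 1)` for
  two fiber families (circumferential and longitudinal by default) and
  dispersion κ ∈ [0, 1/3]. The Macaulay bracket ⟨·⟩ keeps compressed
  fibers energy-free.

Raw tensile curves (engineering stress vs engineering strain) are
re-expressed pointwise as PK2 stress over Green–Lagrange strain via
λ = 1 + ε, E = (λ² − 1)/2, σ_cauchy = σ_eng·λ, S = σ_eng/λ. Model curves
are produced under uniaxial stress: the transverse in-plane stretch is
solved from the zero-transverse-PK2 condition. Parameters are identified
by minimising the weighted stress-residual objective

`e² = Σᵢ [w₁(SθE − SθM)ᵢ² + w₂(SzE − SzM)ᵢ²]`

with bounded generalized simulated annealing (seeded restarts) plus a
bounded least-squares polish; isotropic and reduced-polynomial fits use
deterministic bounded least squares. A film-on-compliant-substrate module
estimates the wrinkling wavelength and onset strain of Bruch's membrane,
the stiff ~5 µm lamina between retina and choroid.

## Worked example

`examples/simulate_and_fit_sheath.py` generates noiseless paired
circumferential/longitudinal PK2 curves (50 points per direction over
0–50% engineering strain) from the packaged anisotropic ONS parameter set
and refits them:

```
generated 50 points/direction, PK2 stress up to 42893.0 MPa
recovered C10 = 0.8000 MPa   (generator: 0.8)
recovered k1  = 32.2000 MPa  (generator: 32.2)
recovered k2  = 79.1000      (generator: 79.1)
recovered kappa = 0.2900  (generator: 0.29)
objective e2 = 6.906e-21 MPa^2, R2 = 1.000000 (circ), 1.000000 (long)
```

The four recovered numbers are the ground-matrix modulus (MPa), fiber
modulus (MPa), fiber exponent, and fiber dispersion; matching the
generator to four decimals with a near-zero objective shows the
identification pipeline recovers the parameter set that produced the
data. Other examples cover the raw-curve re-analysis chain
(`reanalyze_raw_curve.py`), the tissue palette's uniaxial responses
(`tissue_stress_curves.py`), and Bruch's-membrane wrinkling estimates
(`bruchs_membrane_wrinkling.py`).

A thin CLI mirrors the library:

```
ocumech simulate --tissue ons_anisotropic --seed 1 --outdir out/
ocumech fit-goh --circumferential out/ons_anisotropic_circumferential.csv \
                --longitudinal out/ons_anisotropic_longitudinal.csv --seed 1
ocumech convert-pressure 40         # -> 5.3 kPa
ocumech export-card --tissue ons_anisotropic
```

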