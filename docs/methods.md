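# Methods

## Kinematics

All desk-scale computations assume strict incompressibility (J = 1). A
material point of a thin-walled specimen is described by its principal
stretches along the circumferential (θ), longitudinal (z) and radial
directions, with the radial stretch slaved to the in-plane pair,
λ_r = (λ_θ λ_z)⁻¹. Under J = 1 the isochoric stretches equal the
stretches, and the deviatoric invariants reduce to

- I₁ = λ_θ² + λ_z² + (λ_θ λ_z)⁻²,
- I₄ = λ_θ² cos²α₁ + λ_z² sin²α₁ (fiber family 1),
- I₆ = λ_θ² cos²α₂ + λ_z² sin²α₂ (fiber family 2),

where α₁, α₂ are the family angles from the local θ-axis. The third term
of I₁ carries the exponent −2 that incompressibility forces (it is the
radial stretch squared). Default angles are α₁ = 0°, α₂ = 90°, i.e. one
circumferential and one longitudinal family, so I₄ = λ_θ² and I₆ = λ_z²;
general angles are configurable. Fiber family 1 is circumferential by
convention throughout.

Near-incompressibility coefficients (D, or D_i for the polynomial
models) do not enter any response computed here; they are carried as
metadata so that exported material cards remain solver-complete.

## Constitutive models

**Reduced polynomial, order ≤ 2** (isotropic tissues):
U = C₁₀(I₁−3) + C₂₀(I₁−3)². Order 1 is the neo-Hookean model.

**One-term Ogden** (lamina cribrosa): U = (2μ₁/α₁²)(Σ λᵢ^α₁ − 3), the
convention used by the major commercial FE solvers for N = 1; α₁ → 2
recovers neo-Hookean with C₁₀ = μ₁/2. The convention is recorded in
exported metadata because coefficient tables alone do not pin it down.

**GOH fiber-reinforced model** (anisotropic ONS):
Ψ_iso = C₁₀(I₁−3) + (k₁/2k₂) Σᵢ₌₁,₂ [exp(k₂⟨Ē_i⟩²) − 1], with
Ē_i = κ(I₁−3) + (1−3κ)(I_{4,6}−1). The Macaulay bracket
⟨x⟩ = (x+|x|)/2 admits only tensile pseudo-fiber strain, the standard
convention for excluding buckled fibers. κ = 0 is perfectly aligned,
κ = 1/3 fully dispersed (the response then loses all angle dependence —
a tested invariant). By default both families share (k₁, k₂), which
makes the uniaxial θ- and z-responses identical at the default angles
(also a tested invariant); an optional per-family pair (k₁₂, k₂₂) is
available, off by default, for direction-distinct curves.

Stresses are second Piola–Kirchhoff, obtained by analytic
differentiation of the condensed energy Ψ̂(λ_θ, λ_z) in which λ_r has
been eliminated; this choice of the indeterminate pressure makes the
radial stress vanish. S_θ = (1/λ_θ)∂Ψ̂/∂λ_θ and symmetrically for S_z. A
central-difference differentiation of the energy (step 1e−6) is kept in
the test suite as an independent oracle and agrees with the analytic
stresses to 1e−6 relative across all families.

## Tensile-test analysis

Raw strip-test curves are engineering stress vs engineering strain.
Re-analysis maps each point through λ = 1+ε, E = (λ²−1)/2 (Green–
Lagrange), σ_c = σ_eng λ (Cauchy), S = σ_c/λ² = σ_eng/λ (PK2, uniaxial).
Model-predicted curves are generated under uniaxial stress: the
transverse in-plane stretch solves S_transverse = 0. Whether the
original experiments measured transverse deformation optically or
assumed it is not documented; the zero-transverse-stress solve is the
standard strip-test reading and is the modelling choice made here. For
isotropic materials it lands on λ_trans = λ^(−1/2) to 1e−8 (tested).

The scalar solver is Brent's method on λ_trans ∈ [0.2, 1.5] (bracket
widened once to [0.05, 3.0] before failing), tolerance 1e−10. The
fitting path uses a vectorised fixed-count bisection over the whole
strain grid (48 halvings, terminal width ≈ 5e−15) so that one objective
evaluation costs two vectorised solves; the two solvers agree to solver
tolerance (tested).

## Parameter identification

The anisotropic fit minimises
e² = Σᵢ [w₁(SθE−SθM)ᵢ² + w₂(SzE−SzM)ᵢ²] in PK2/Green–Lagrange space,
with equal unit weights by default. Optimiser: generalized simulated
annealing (scipy's dual annealing, default visiting/acceptance schedule,
no internal local search) over (C₁₀, k₁, k₂, κ) within bounds
C₁₀ ∈ (0, 10] MPa, k₁ ∈ (0, 10³] MPa, k₂ ∈ (0, 500], κ ∈ [0, 1/3];
5 restarts by default, each started from a seeded draw (uniform for C₁₀
and κ, log-uniform for the scale parameters k₁, k₂) and followed by a
bounded trust-region least-squares polish of the residual vector. The
polish is derivative-based rather than derivative-free: with a smooth
residual and an exponentially narrow valley in (k₁, k₂), the
trust-region step follows the valley to machine precision where pattern
searches stall. Restarts tie-break on lowest e², then lowest k₁
(parsimony). All randomness derives from one integer seed; a fixed seed
reproduces the result bit for bit (tested).

During annealing, trial parameters can push the fiber exponent k₂⟨Ē⟩²
past the range of exp(). Inside the fitting path the exponent is capped
at 300, so infeasible corners return astronomically large but finite
stresses, and the scalar objective is capped at 1e100; the optimum is
never near these caps for any dataset with tissue-scale stresses. The
public energy evaluator instead raises an overflow error, since a user
evaluating a single state should be told the state is outside the
model's range.

The isotropic variant interpolates the longitudinal curve onto the
circumferential grid (overlap only), averages pointwise, and fits the
single neo-Hookean C₁₀. Because the uniaxial PK2 response is exactly
linear in C₁₀, the bounded least-squares solution is computed as a
projection onto the unit response — deterministic and exact. The
reduced-polynomial refit restricts the curve to a stated engineering-
strain window (default 0–0.5) and runs bounded trust-region least
squares on (C₁₀, C₂₀) from a fixed initial guess (0.1, 1.0) against the
model's engineering-stress prediction.

R² is reported per direction as 1 − SS_res/SS_tot on the ordinate of the
fit space (PK2 stress for the anisotropic/isotropic fits, engineering
stress for the raw-curve polynomial refits), with a pooled value as
metadata.

## Synthetic data

The generator emulates re-analyzed strip-test data for the sheath:
paired circumferential/longitudinal curves on a 50-point engineering-
strain grid over 0–50% — the strain range and sampling density of the
tensile protocol the tissue coefficients derive from — expressed by
default in the fitting measures (Green–Lagrange/PK2). Noise, when
requested, is additive Gaussian with standard deviation a stated
fraction of each curve's maximum stress, drawn from a single seeded
stream in fixed direction order; a multiplicative option exists but is
off by default. The stress at zero strain is pinned to zero. The
generator does not emulate preconditioning, hysteresis, clamping
artifacts, or specimen-to-specimen biological variability — so passing
recovery tests demonstrate that the identification pipeline is sound and
unbiased at the study's data scale, not that it would resolve parameter
scatter across real donor tissue.

Two honest consequences of the shared-moduli model are worth noting.
First, with shared (k₁, k₂, κ) and the default angles the circumferential
and longitudinal synthetic curves are identical, so the anisotropic
recovery exercise is effectively a four-parameter fit to one distinct
curve — it still has a unique, exactly recoverable optimum (tested).
Direction-distinct data require the per-family option. Second, the
exponential fiber term evaluated at the fitted sheath coefficients grows
to ~4×10⁴ MPa of PK2 stress at 50% engineering strain — far above any
physiological stress; the fit is dominated by the upper strain range,
and the recovery loop is self-consistent rather than a claim about the
model's physicality there.

## Wrinkling surrogate

Bruch's membrane (thickness 5 µm, the anatomical value used throughout)
is a stiff lamina between the much softer retina and choroid, and
full finite-element simulations of large eye rotations predict it
wrinkles. As a desk-scale sanity check the package applies the classical
stiff-film-on-compliant-half-space relations, ε_c = ¼(3Ē_s/Ē_f)^{2/3},
λ_w = 2πh(Ē_f/3Ē_s)^{1/3}, A = h√(ε/ε_c − 1), with plane-strain moduli
Ē = 8C₁₀ (incompressible small-strain limit, ν = 1/2 for consistency
with the constitutive stack). No analytic treatment of the true
retina–membrane–choroid trilayer is attempted; instead both single-
substrate estimates are reported as brackets. They straddle the ~10² µm
wavelength scale (choroid ≈ 67 µm, retina ≈ 184 µm), and the choroid-
substrate onset strain (≈ 5.5%) lies inside the 5–9% onset band reported
from the simulations — asserted in tests only as factor-of-two,
order-of-magnitude agreement, which is all a single-substrate surrogate
for an emergent finite-element result can support.

## Numerical choices and limitations

- Tolerances: transverse solve 1e−10 (scalar) / ~5e−15 (vectorised);
  polish xtol=ftol=gtol=1e−15; stress–energy consistency oracle 1e−6
  relative.
- Degenerate inputs rejected with named errors: non-positive stretches,
  κ outside [0, 1/3], non-monotone strain grids, constant observed
  vectors in R², non-overlapping strain ranges in curve averaging,
  underdetermined polynomial fits.
- Parameter-recovery properties are asserted for generating parameters
  whose peak PK2 stress at 50% strain stays below 200 MPa; beyond that
  the exponential term produces synthetic "tissues" with astronomic
  stresses that describe nothing physical (the fits also become
  numerically brutal for no scientific gain).
- Problem sizes: 50 points/direction for recovery runs, 20 seeds for
  noisy-refit statistics, 1000 random states for the stress–energy
  consistency sweep, 5 seeded draws for the cross-draw recovery
  property.
- Out of scope: viscoelasticity, poroelasticity, compressible response,
  damage, preconditioning, shear/biaxial protocols, full 3-D deformation
  states, and any finite-element field computation; the wrinkling module
  is a surrogate estimator, not a buckling simulation.
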