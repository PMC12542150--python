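# Constitutive coefficients for ocular tissues, fitted to uniaxial tensile
# data over 0-50% engineering strain.  Units: C10/C20/mu1/k1 in MPa,
# D/D1 in MPa^-1, k2/alpha1/kappa dimensionless.
tissues:
  optic_nerve:
    model: reduced_polynomial
    C10: 0.23
    C20: 8.18
  peripapillary_sclera:
    model: reduced_polynomial
    C10: 0.20
    C20: 11.60
  anterior_sclera:
    model: reduced_polynomial
    C10: 2.25
    C20: 102.20
  equatorial_sclera:
    model: reduced_polynomial
    C10: 0.87
    C20: 91.30
  posterior_sclera:
    model: reduced_polynomial
    C10: 0.80
    C20: 32.8
  bruchs_membrane:
    model: neo_hookean
    C10: 1.82
    D1: 0.022
  choroid:
    model: neo_hookean
    C10: 0.063
    D1: 0.64
  retina:
    model: neo_hookean
    C10: 0.003
    D1: 15.5
  lamina_cribrosa:
    model: ogden
    mu1: 0.36
    alpha1: 10.4
  ons_anisotropic:
    model: holzapfel
    C10: 0.8
    k1: 32.2
    k2: 79.1
    kappa: 0.29
    D: 0.03
    alpha1_deg: 0.0
    alpha2_deg: 90.0
  ons_isotropic:
    model: neo_hookean
    C10: 2.3
    D1: 0.03
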