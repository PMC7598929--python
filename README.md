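# equigr

Mechanobiologically equilibrated constrained-mixture growth and remodeling
(G&R) of the murine thoracic aorta, with an axisymmetric membrane
finite-element solver for "numerical knockout" experiments: localized or
uniform losses of elastic fiber integrity, collagen cross-linking, collagen
turnover balance, smooth-muscle contractility, and mechanosensing or
mechanoregulation of matrix, alone and combined with hypertension and aging.

Thoracic aortic aneurysms arise from many co-existing risk factors — genetic
lesions of matrix or smooth-muscle function, elevated blood pressure,
age-related elastin loss — that are hard to isolate experimentally.  This
package is for vascular-mechanics researchers who want to study each factor
in isolation and in combination in silico: each "knockout" is a prescribed
change of one constitutive parameter, and the model predicts the evolved
geometry, composition, stored energy, and material stiffness of the vessel.

## Model

The wall is a constrained mixture of elastin-dominated matrix (e), smooth
muscle (m) and four collagen fiber families (c; axial, circumferential, two
symmetric diagonals at angle α from the axis).  Elastin is not produced in
maturity and deforms elastically from its deposition-stretch-prestressed
state, with a neo-Hookean energy Ŵᵉ = (cᵉ/2)(tr(FᵉᵀFᵉ) − 3), Fᵉ = F Gᵉ.
Collagen and passive muscle are Fung-exponential fibers,
Ŵ = c₁/(4c₂)(exp[c₂(λ²−1)²] − 1), continually removed and re-deposited at
their deposition stretches Gᶜ, Gᵐ; smooth muscle adds a shear-regulated
active stress T(Δτ_w)(1 − ((λ_M−1)/(λ_M−λ₀))²) e_θ⊗e_θ.

In the rate-independent, *mechanobiologically equilibrated* limit, mass
production balances removal at every point.  Equilibrium requires the
stimulus balance

    Δσ = (K_τw/K_σ) Δτ_w,   Δσ = ((1−δ)σ_v − σ_o)/σ_o,
                            Δτ_w = (1−ξ)τ_w/τ_wo − 1,

with σ_v = tr(σ)/3 the mean intramural stress, τ_w/τ_wo = Q_h a_o³/(Q_o a³)
the Poiseuille wall-shear ratio, and δ, ξ ∈ [0,1] intramural / endothelial
sensing-dysfunction fractions.  Cauchy stress and stored energy follow rules
of mixtures over evolved mass fractions; muscle mass tracks collagen as
ρ_m = ρ_c^η; diagonal collagen reorients by tan α = (λ_θ/λ_z) tan α₀.
Lesions are prescribed Gaussian-like axial profiles
ϑ(z) = ϑ_end + (ϑ_central − ϑ_end) exp(−|(z−l/2)/z_od|^ν) of any controlled
parameter.  Mechanical and mechanobiological equilibrium are solved
*monolithically* (nodal positions plus collagen density at every Gauss
point) with quasi-static continuation in the insult magnitude; loss of a
solution past a critical insult is a mechanobiological static instability.

## Worked example

```sh
python examples/severe_elastin_lesion.py
```

```
scenario: elastin_integrity:severe (converged=True)
  max local diameter increase :  162.2 %
  lesion length (FWHM)        :   3.75 mm
  central stored energy       :   46.9 kPa (-30.7 % vs healthy)
  central circ. stiffness     :   3180 kPa (2.23-fold)
```

A severe (~62%) localized loss of elastic fiber integrity grows an
axisymmetric aneurysm: the local diameter increase far exceeds the 50%
clinical aneurysm definition, elastic energy storage drops about 30% below
the healthy W_o ≈ 68 kPa, and circumferential material stiffness roughly
doubles from its healthy c_θθθθ ≈ 1.4 MPa — the hallmark aneurysmal
phenotype.  Other entry points: `examples/baseline_setpoints.py` (derived
homeostatic pressure and setpoints), `examples/risk_factor_combinations.py`
(insults ± hypertension ± aging), `examples/instability_scan.py` (critical
mechanosensing loss), `examples/equibiaxial_test.py` (virtual biaxial tests
of the remodeled wall), or the `equigr` command line
(`equigr baseline | run | sweep | catalog`).

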