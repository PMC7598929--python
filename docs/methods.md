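# Methods

## The equilibrated constrained mixture

The aortic wall is modeled as a constrained mixture: elastin-dominated
matrix, smooth muscle, and four collagen fiber families deform together with
the tissue but each has its own stress-free natural configuration and
turnover.  In the rate-independent limit adopted here, every simulated state
is *mechanobiologically equilibrated* — mass production exactly balances
removal, and the stimulus balance Δσ = (K_τw/K_σ)Δτ_w holds pointwise — so
the computation resembles an elastic solve: no deposition history is
tracked and no removal-rate constants appear anywhere in the API.  This is
appropriate when remodeling is fast compared with the driving insult
(fully quasi-static G&R); transient trajectories between equilibria are out
of scope.

Key consequences of equilibration used throughout:

* collagen and smooth-muscle fibers always carry the stress of their
  deposition stretches (G_c = 1.25, G_m = 1.20): their Cauchy stress
  contribution per unit constituent volume is constant, and growth absorbs
  further deformation;
* elastin (not produced in maturity) deforms elastically from the original
  homeostatic configuration through F Gᵉ, so dilatation and wall thickening
  stretch it circumferentially and radially;
* stored energy and Cauchy stress are rules of mixtures over evolved mass
  fractions φ_α = φ_oα ρ_α / J, with the volume ratio fixed by mass–volume
  consistency J = Σ φ_oα ρ_α (constant true density);
* the equilibrated active muscle stretch is 1, so active stress is
  φ_m T(Δτ_w)(1 − ((λ_M−1)/(λ_M−λ₀))²) circumferentially.

The mean Cauchy stress σ_v = tr(σ)/3 is the intramural stimulus; the wall
shear ratio is evaluated pointwise from the local stretches as
τ_w/τ_wo = Q_ratio λ_θ⁻³ (Poiseuille at constant flow, with the luminal
radius scaling with the circumferential stretch of the membrane).  Muscle
mass tracks collagen as ρ_m = ρ_c^η.  Diagonal collagen reorients with the
in-plane stretch ratio, tan α = (λ_θ/λ_z) tan α₀, measured from the axial
direction so circumferential dilatation rotates fibers toward
circumferential.

## Membrane reduction and the derived homeostatic pressure

The reference implementation of this class of models uses a 3-D mesh one
quadratic element thick; all reported fields are through-thickness
homogenized.  This package therefore reduces the wall to an axisymmetric
*membrane* on the mid-surface R_o = a_o + h_o/2, with thickness
h = J h_o/(λ_θ λ_z) and the Lagrange multiplier fixed by the mid-wall radial
condition σ_rr = −P/2.  The homeostatic pressure P_o is **derived**, not
prescribed: it is the unique pressure under which the published baseline
state (mass fractions 0.34/0.33/0.33, deposition stretches, moduli) is an
exact fixed point of both residuals, P_o = (σ̂_θθ − σ̂_rr)/(R_o/h_o + 1/2)
= 15.861 kPa ≈ 119 mmHg — a plausible mouse systolic pressure.  The
corresponding setpoints are σ_o = 168.44 kPa, W_o = 67.73 kPa and
c_θθθθ,o = 1423 kPa.

The circumferential material stiffness is the θθθθ component of the spatial
elasticity tensor linearized about the loaded state at frozen composition
(small-on-large): 2σ̂_θθ^passive plus fiber second-derivative terms
projected by the fourth power of the current direction cosines.  The active
stress is excluded from the linearization by default (including it gives
1504 kPa at baseline, clearly off the healthy anchor; the toggle
`stiffness_includes_active` is exposed).  A finite-difference oracle checks
the analytic expression on random admissible states.

Known fidelity gaps of the membrane reduction, in exchange for second-scale
solves: no bending stiffness at lesion shoulders, pressure applied on the
mid-surface, and a single in-plane stress state through the thickness.
Quantities from boundary-value simulations are therefore scale-faithful
rather than digit-faithful (see "Fidelity limits" below).

## Solvers

**Uniform (0-D).**  A cylinder with fixed ends (λ_z = 1) has two unknowns,
(λ_θ, ρ_c), and two residuals (membrane force balance σ_θθ h = P λ_θ R_o;
stimulus balance).  They are solved *simultaneously* by a damped Newton
iteration in (λ_θ, log ρ_c): eliminating ρ_c first is ill-posed wherever
∂g/∂ρ_c crosses zero (which happens on lesion shoulders and under uniform
elastin loss with shear sensing active), while the coupled Jacobian stays
regular there.  An optional force-controlled axial mode replaces λ_z = 1 by
the closed-end balance σ_zz h = P r/2.

**Axisymmetric membrane FEM.**  Quadratic 1-D elements (default 20 along
the 15 mm segment, 3-point Gauss), unknown meridian positions (r, z) with
axial displacement fixed at both ends and radial motion free.  For the same
ill-posedness reason, the global unknown vector also carries log ρ_c at
every Gauss point and the stimulus residuals join the system (monolithic
coupling).  The residual combines membrane stress resultants with the
follower pressure on the deformed mid-surface; the consistent tangent —
including wall-shear, reorientation, density and follower-load coupling —
is assembled by element-wise finite differencing (9 extra residual
evaluations), verified against a global central-difference oracle to 1e-4.
A standalone internal-variable update (local density solve at fixed
deformation, warm-started Newton in log ρ_c) is retained for verification
and point-wise analysis.

**Continuation.**  Insult parameters, pressure elevation and aging ramp
linearly over 10 quasi-static increments (mirroring the reference
protocol), with step halving on failure down to 1/32 of the base increment
and re-growth after success.  The end-region regularization profile — the
shear-to-intramural gain ratio decaying from its baseline 0.35 at the ends
to 0 in the lesion, because wall shear stress is sensed only in insult-free
segments — is applied in full from the first step: the baseline state is an
exact equilibrium under it, whereas ramping it with the insult drives the
path through a spurious fold (partial damage with partial shear sensing).
Exhausting the step halvings returns the last equilibrated state flagged
`converged=False`: the signature of a mechanobiological static instability,
confirmed by the collapse of the smallest singular value of the monolithic
tangent.  No arc-length following is attempted.

Everything is deterministic; no solver consumes random numbers.

## Scenario conventions

* Severity grades (central values of the lesion profile): elastin modulus
  −32% / 34.1 kPa; collagen c₁ᶜ −9% / 181 kPa; T_max −60% / 0; δ 0.075 /
  0.185; G_c −0.4% / 1.235; turnover ratio η 1.05 (its mild and severe
  grades coincide with the published severe value; the alternative reading
  of "5 to 12.5% increments" can be run via a custom severity).
* Hypertension = 1.5× pressure; aging = uniform 30% elastin-modulus loss,
  composing multiplicatively with localized elastin damage (both are
  reductions of the same modulus).
* Elastic-fiber-integrity scenarios run without vessel-level tone
  (T_max = 0, with P_o re-derived), reflecting the association of elastic
  fiber loss with reduced vasoconstrictive capability; with tone included
  the equilibrated membrane loses existence early in the elastin
  continuation.  `ScenarioSpec.T_max_baseline` overrides this (e.g. 50 kPa
  for the protective-tone study).
* Lesion profiles default to ν_z = 5, z_od = 3 mm on the 15 mm segment;
  the asymmetric (axial × circumferential) profile is generated but not
  solved (the membrane is axisymmetric by construction).
* A localized η elevation alone leaves the baseline exactly homeostatic
  (η only couples *evolved* densities), so its catalog entries pair it with
  the systemic risk factors.

## Virtual equibiaxial tests

A converged material point is frozen in composition, unloaded passively to
its traction-free configuration (plane stress, isochoric in-plane root
find), then stretched equibiaxially; fiber stretches compose the deposition
stretch with the superimposed line stretch of each (reoriented) family.
This mimics ex vivo biaxial testing of the remodeled tissue.

## Fidelity limits

What passing tests do and do not show: the package reproduces the healthy
anchors exactly as printed (W_o, c_θθθθ,o to within 0.4%), the severe
elastin lesion's central energy loss (−30.7% vs ≈−30%) and stiffening
(2.23- vs ≈2-fold), the ≈170% maximal catalog dilatation (162% over fully
converged cases), and every qualitative ordering asserted (severity
monotonicity, risk-factor exacerbation, uniform-remodeling of systemic
factors, co-localization of property changes with dilatation).  The
membrane reduction shifts the critical mechanosensing fraction upward —
δ_crit = 0.225 here versus 0.185 for the 3-D reference, whose value is
operationally its solver's Newton failure point — and it makes central
stored energy *rise* in mechanosensing lesions (intact elastin stretched
over a thinner wall), where the 3-D model reports decreases; for non-elastin
insults only orderings are asserted.  The synthetic inputs are idealized:
an initially straight, uniform cylinder without curvature, pulse pressure,
fluid–solid coupling, bending, or animal-to-animal variability, so passing
tests validate the G&R feedback logic, not organ-scale hemodynamics.
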