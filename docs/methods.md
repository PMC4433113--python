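# Methods

## Model

`nanopnp` solves the coupled Poisson–Nernst–Planck (PNP) equations for a
binary electrolyte around a single nanopore in a dielectric membrane, in
axisymmetric cylindrical coordinates (r, z):

- Poisson: ∇·(ε∇V) = −F Σᵢ zᵢcᵢ, solved over the **whole** domain, liquid
  and membrane alike.
- Nernst–Planck flux: jᵢ = −Dᵢ(∇cᵢ + cᵢ zᵢ e/(k_BT) ∇V).
- Continuity: ∂cᵢ/∂t = −∇·jᵢ.

The domain is a cylinder of radius 250 nm: two 250 nm-deep reservoirs
separated by a Si₃N₄ membrane (default 20 nm thick) pierced by a
cylindrical or conical pore (default 10 nm small diameter; 20° full cone
angle gives a 17 nm large opening). Boundary conditions: Dirichlet voltage
and bulk concentration at the far reservoir ends; zero normal electric
field and zero ion flux on the outer cylinder; zero ion flux at every
solid surface. Fixed surface charge σ_S at the water/nitride interface
enters the Poisson weak form as a natural interface source. Deliberately,
**no** Neumann condition V⊥ = σ_S/ε is imposed at the pore wall: because
the membrane interior is part of the electrostatic solve, ions outside the
pore on the membrane faces can take part in screening the pore-wall
charge, and equipotential lines need not be perpendicular to the wall.

The symmetry axis r = 0 needs no explicit boundary condition: every weak
integral carries the revolution weight 2πr, which vanishes there.

## Discretization

**Mesh.** A mapped structured grid: graded axial lines (finest at the
membrane faces) and graded radial lines, with one radial grid line
following the pore-wall line r = w(z), so the liquid/membrane interface
lies exactly on mesh edges for cylinders and cones alike. Quads are split
into triangles for the finite-element Poisson solve. Element size grows
geometrically (default ratio 1.3, coarse profile 1.45) from
`min_element_size` at charged surfaces toward the far boundaries, so
several cells resolve the ~3 nm Debye layer. Far from the pore the cells
are strongly anisotropic (thin in z at the faces, wide in r), which suits
the layered structure of the double layer; the triangle quality floor is
correspondingly low (≈5×10⁻³ inradius/circumradius) and is asserted, not
optimized.

**Poisson.** Piecewise-linear (P1) triangles; stiffness and load integrals
use the exact linear-in-r quadrature (2π·r̄·A for the stiffness weight,
A(2rₐ+r_b+r_c)/12 for the load). The matrix depends only on mesh and
permittivities, so it is factorized once (sparse LU) and reused for every
solve; each Poisson step is a load-vector rebuild plus back-substitution.

**Transport.** Concentrations are piecewise constant. The finite-volume
cells are the structured **quads** (each the union of its two triangles):
on the tensor-product mesh the cell-center connections are normal to the
shared faces, which the consistency of a two-point flux demands. (With
triangle cells the centroid connections of the right-triangle pairs are
skewed relative to the faces, and the two-point flux under-estimates the
conductance by the skew cosine — verified against the uniform Ohmic column,
where the quad scheme reproduces σEA to 10⁻¹⁰ relative.) Facet areas are
exact surfaces of revolution of the shared edges; the drift potential
difference is the nodal voltage averaged to the two cell centers. The face
flux uses Scharfetter–Gummel exponential fitting,
Q = (D·A/d)·[c₁B(δ) − c₂B(−δ)] with B(x) = x/(eˣ−1) and
δ = z e ΔV/(k_B T): exact for the 1D two-point problem, central-diffusion
at δ = 0, and identically zero at Boltzmann concentration ratios, so the
discrete equilibrium carries no spurious currents.

## Time integration

Two time steps are used. The Poisson step δt_P is a fraction f_P = 1/40 of
the RC time constant τ = R·C ≈ 1.1×10⁻⁸ s of the solution column
(R ≈ 17 MΩ) in series with the membrane capacitance (C ≈ 0.65 fF); τ is
recomputed analytically for the realized geometry rather than hard-coded,
so non-default geometries get the right Poisson cadence. Between Poisson
solves the concentrations advance explicitly with the transport step
δt_NP = min(f_NP·Δx²_min/D_max, 0.95/max|M_ii|), where f_NP = 1/5,
Δx_min is the shortest realized cell-center distance and M is the
assembled SG operator. The second bound is the forward-Euler positivity
limit (the SG operator has nonnegative off-diagonals), so concentrations
can never go negative; it binds only where drift dominates near charged
walls at high bias. The inner steps exactly tile δt_P.

Transients are run for 20 RC constants (0.2 μs) after a voltage step; by
then the membrane capacitor is charged and the total ionic current is
z-uniform, while the individual species currents are not — the signature
that true steady state is still far away.

## Steady-state acceleration

The chargeless (common) mode, jc = (j_K + j_Cl)/2, relaxes by co-diffusion
with D_int = 2·D_K·D_Cl/(D_K+D_Cl) and would need ~(250 nm)²/D_int ≈ 30 μs
to equilibrate the reservoirs — far beyond any affordable transient. The
accelerated loop is:

1. time-simulate 20 τ at the applied bias;
2. with the field frozen, solve the steady transport equation
   ∇·jᵢ = 0 per species (a linear solve with the same SG coefficients);
3. form the per-cell average of the two species' changes relative to the
   end of the time simulation and add it to **both** species. For the
   1:−1 pair this common-mode shift adds no space charge, so the Poisson
   solution is exactly unchanged, while the slow co-diffusion profile
   jumps straight to its steady shape;
4. repeat until, for every species, the current through every axial plane
   is uniform within 0.5% of the total current (or, at zero bias, 0.5% of
   the current estimated at 0.1 V from the pore plus access resistances,
   R_pore = 4L_m/(σπd²) with the mean diameter for cones and
   R_access = 1/(σd)).

A scalar (volume-averaged) shift was tried first and stalls: it captures
only the global average of the common mode, and the spatial profile still
relaxes at the co-diffusion rate. The per-cell common-mode shift converges
geometrically, typically in 5–25 outer iterations. The axial planes are
the interior node z-levels of the mesh; planes crossed by no liquid facet
(inside a pore-less slab fixture) are dropped.

Zero-bias equilibrium (the double layer build-up) uses the same loop
starting from uniform bulk concentrations; every bias point of a sweep
starts from that shared equilibrium state, not from the previous bias.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| T | 298.15 | K | room temperature |
| εr water / membrane | 78.4 / 7.5 | — | water at 25 °C; 7.5 reproduces C = 0.65 fF for the 20 nm membrane over the 250 nm domain |
| D(K⁺), D(Cl⁻) | 1.95×10⁻⁹, 2.03×10⁻⁹ | m²/s | infinite-dilution values |
| c_bulk | 10 (100 for the thin-membrane scenario) | mol/m³ | upper limit of the continuum description at this pore size |
| σ_S | −50 (−100 thin membrane) | mC/m² | typical nitride surface charge |
| f_P, f_NP | 1/40, 1/5 | — | Poisson / transport step fractions |
| n_RC | 20 | — | transient length per segment, τ units |
| uniformity tolerance | 0.5% | — | stopping rule of the outer loop |
| min element / growth | 0.5 nm / 1.3 (coarse: 1 nm / 1.45) | | several cells per Debye length |

Mesh profiles: `coarse` (~1.4 k triangles, ~550 transport cells) runs a
bias point in ~10–60 s and is what the test suite and the acceptance
script use; `default` and `fine` are provided for convergence studies.
The documented results (2% transient/steady gap, 4% polarization decrease,
3 mC/m² induced charge) are stable between the coarse and default
profiles.

## What the scenarios do and do not emulate

The scenario presets are clean model systems: perfectly cylindrical or
conical pores, piecewise-uniform fixed surface charge, ideal 1:1
electrolyte, no fluid flow. Passing tests therefore demonstrates the
electrodiffusion mechanism — ion concentration polarization producing
limiting conductances and rectification, and voltage-induced polarization
charges producing overlimiting behaviour — not quantitative agreement with
any measured pore, whose geometry and charge are generally unknown (the
overlay tool deliberately reports raw simulated/measured ratios without
rescaling). Not modelled: electro-osmosis and microvortices
(Navier–Stokes), activity corrections above ~10 mM, ion discreteness
(< 20 ions occupy the pore at 10 mM), amplifier/electrode transients, and
pore fabrication.

## Numerical choices and edge cases

- Sparse direct factorization for both Poisson and the per-species steady
  transport solves; at desk scale (≲10⁴ unknowns) this beats iterative
  methods and is bitwise deterministic.
- The asymmetric charge configuration is the left membrane face plus the
  left half of the pore wall (edge midpoints at z < L_m/2); the exact
  extent in the source system is not recoverable, and the choice is the
  one that reproduces the described polarity behaviour.
- The polarization-charge observable is σ_pol = −ε₀εr_m·E⊥ inside the
  membrane at the interface: the induced displacement the double layer
  must screen in addition to σ_S. (The *contact* displacement jump minus
  σ_S vanishes identically by Gauss's law and carries no information.)
  Reported single numbers average over the outer half of the face radius,
  far from the pore.
- After the common-mode shift, concentrations are clipped at zero (the
  shift can be negative inside strongly depleted pores) and the
  bulk-pinned cell layer is re-pinned; both touch the field only at the
  10⁻¹⁵ level in practice.
- Dirichlet concentration cells are the single cell layer touching the
  reservoir far ends.
- Chord conductance G = I/V is NaN at V = 0; differential conductance g
  uses central differences on the sweep grid (one-sided at the ends);
  rectification ratios pair each positive bias with its exact negative.

## Known limitations

- The uniformly charged **cone** rectifies only marginally at these
  parameters (|ΔG/G| ≈ 1–3% for ±0.125…0.75 V), and in this
  implementation the negative branch is very slightly favored
  (G(+V)/G(−V) ≈ 0.98 at ±0.25 V, stable from the coarse to the fine
  mesh, with an uncharged-cone baseline ratio of 1.002). The balance
  between tip-side access depletion and in-pore enrichment is evidently
  delicate at a 20 nm-long, weakly charged cone; the pore-wall-only cone,
  where the mechanism predicts strong *opposite* rectification, comes out
  clearly (ratio ≈ 0.69).
- Two-point fluxes are slightly skewed on the tilted cells inside conical
  pores (wall angle ≤ 10°); the uncharged-cone I–V is antisymmetric to
  0.2%, bounding the effect.
- The explicit transport step makes very fine meshes expensive
  (δt_NP ∝ Δx²); the fine profile exists for convergence checks, not
  production sweeps.
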