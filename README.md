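# nanopnp

Axisymmetric time-dependent and steady-state **Poisson–Nernst–Planck**
simulations of ion currents through solid-state nanopores.

Solid-state nanopores — nanometre holes in thin Si₃N₄ membranes immersed in
electrolyte — show a family of puzzling current–voltage behaviours: ion
current rectification (G(+V) ≠ G(−V)), limiting conductances
(g = ∂I/∂V flattening with bias), and overlimiting conductances (g rising
again at large bias). `nanopnp` is a continuum electrodiffusion simulator
for these systems, aimed at nanofluidics and biosensing researchers who
want a mechanistic, parameter-explicit model rather than a fit.

The model couples, on an axisymmetric (r, z) domain containing both the
electrolyte reservoirs and the dielectric membrane,

```
∇·(ε∇V)  = −F Σᵢ zᵢcᵢ                    (Poisson)
jᵢ        = −Dᵢ(∇cᵢ + cᵢ zᵢe/(k_BT) ∇V)   (Nernst–Planck)
∂cᵢ/∂t    = −∇·jᵢ                         (continuity)
```

with fixed surface charge σ_S at the water/nitride interface, Dirichlet
voltage and concentration only at the far reservoir ends, and **no**
V⊥ = σ_S/ε wall condition — the membrane interior is part of the
electrostatic solve, so ions on the membrane faces help screen the
pore-wall charge. Transients use a dual time step (Poisson every
δt_P = τ_RC/40, explicit Scharfetter–Gummel transport steps in between);
steady states use an accelerated loop that alternates time simulation with
frozen-field steady transport solves and a charge-neutral common-mode
concentration shift, stopping when every species' current is uniform
through all axial planes to 0.5% of the total. See `docs/methods.md` for
the full account.

## Worked example

The built-in scenarios reproduce the canonical system: a 10 nm pore in a
20 nm membrane, 10 mM KCl, σ_S = −50 mC/m² in several configurations.
Check the analytic anchors first:

```
$ nanopnp validate --scenario uncharged_cyl
quantity                                value  units
debye_length                      3.04012e-09  m
conductivity                         0.149464  S/m
solution_resistance               1.70374e+07  Ohm
membrane_capacitance              6.51943e-16  F
rc_time_constant                  1.11074e-08  s
pore_plus_access_resistance        2.3728e+09  Ohm
ion_spacing                       4.36254e-09  m
intermediate_diffusion             1.9892e-09  m^2/s
codiffusion_time                  3.14197e-05  s
```

The Debye length (3 nm) is comparable to the pore radius; the membrane
capacitance (0.65 fF) and solution resistance give the τ ≈ 10 ns cadence
of the transient integrator; co-diffusion across the 250 nm reservoirs
would take ~30 μs, which is why the steady state needs the accelerated
solver rather than brute-force time stepping.

Now solve the uniformly charged pore at 0.25 V (equilibrium double-layer
build-up, 0.2 μs transient, then the accelerated steady state):

```
$ nanopnp --log-level WARNING run --scenario a_uniform --bias 0.25 --mesh-profile coarse
I(20 tau)  = 5.8725e-10 A
I(steady)  = 5.6594e-10 A
  I_K   = 5.4582e-10 A
  I_Cl  = 2.0118e-11 A
```

Three things to read off: the pore is nearly perfectly cation-selective
(I_Cl is 4% of the total — Cl⁻ is depleted from the negatively charged
pore); the steady current is ~4% *below* the current 0.2 μs after the
voltage step, because ion concentration polarization — salt depletion on
the V_L side, enrichment on the V_R side — raises the net resistance; and
the two currents bracket what an experiment would see on intermediate
time scales.

Full I–V sweeps, with chord/differential conductances and rectification
ratios written to CSV plus plots:

```
nanopnp sweep --scenario c_asymmetric --out out/casym
nanopnp sweep --scenario overlimiting_thin --out out/thin --overlay measured_iv.csv
```

The asymmetric configuration rectifies (ratio ≈ 10 at ±0.5 V on the
coarse profile); the thin-membrane scenario shows the overlimiting upturn
produced by voltage-induced polarization charges. `--overlay` compares a
measured I–V table (columns `V,I`) against the simulation as a raw ratio
table, with no rescaling.

The library API mirrors the CLI: `preset(name)` → `PNPSimulation` →
`initialize_equilibrium` / `run_time_simulation` / `steady_state_solve`,
with observables (plane currents, electrochemical potentials, polarization
charges, I–V curves) in `nanopnp.observables`.

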