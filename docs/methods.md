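# Methods

## Solvation model

The solvation free energy of a rigid solute in an equilibrium solvent is
written as a coupling ("charging") integral. A parameter λ switches the
solute–solvent interaction u_αγ(r) from zero (λ = 0) to full strength
(λ = 1); integrating the λ-derivative of the interaction against the
solute–solvent distribution function g_γ(r; λ) gives G_solv, and because
∂u/∂λ is a sum of atomic terms, the split into per-atom contributions G_α
is exact: Σ_α G_α = G_solv holds identically, for any distribution
provider and any coupling path. Grouping atoms by residue yields the
per-residue profiles that the mutation analytics difference between
wild type and mutant.

Per-atom (and hence per-residue) values are **path-dependent** in general;
only the total is path-invariant. The package fixes a default path and
records it in all outputs, so profiles are comparable across runs.

### Coupling path and quadrature

The default path has two stages: λ₁ switches on the short-range
(Lennard-Jones) term with Coulomb off, then λ₂ scales Coulomb linearly
with LJ fully on. Coulomb-last keeps the integrand smooth: the repulsive
core is complete before any charge appears, so the distribution function
suppresses the region where the Coulomb derivative is singular. Each
stage uses Gauss–Legendre quadrature with 8 nodes by default.

The LJ stage uses a Beutler-style soft core,

u(r; λ₁) = λ₁ · 4ε [D⁻² − D⁻¹],  D = a(1 − λ₁) + (r/σ)⁶,  a = 0.5,

which reduces to plain LJ at λ₁ = 1 and keeps ∂u/∂λ bounded inside the
core. A hard radius floor was considered instead and rejected: the
λ-integrand near λ = 0 is then a spike of width 1/(βu_core) that an
8-node rule integrates poorly (≈1 kcal/mol error on a single atom),
whereas the soft core meets the 0.1% single-atom oracle at 8+8 nodes.

A one-stage "proportional" path (λ scales LJ and Coulomb together) is
provided for path-independence checks. It scales plain LJ linearly rather
than soft-core: with a softened core and partial Coulomb, attraction can
collapse the Boltzmann factor; with the full core present at every λ > 0
the integrand stays bounded.

Mixing is Lorentz–Berthelot; the Coulomb constant is fixed at
332.0636 kcal·Å/(mol·e²). Boltzmann factors are clamped at exp(600) as a
pure overflow guard (never active on well-posed systems).

### Solute parameterisation

Solute atoms get per-element LJ parameters from a small generic table
(C 3.40/0.109, N 3.25/0.170, O 2.96/0.210, S 3.56/0.250, H 1.07/0.0157;
σ in Å, ε in kcal/mol) — a deliberate simplification, not a biomolecular
force field. Residue formal charges at neutral pH (Asp/Glu −1, Lys/Arg
+1, His and termini neutral) are placed on the conventional charged-group
atoms: Lys NZ, Arg CZ, Asp OD1/OD2 and Glu OE1/OE2 at half charge each;
when only part of a group is present (single-bead side chains) the charge
is distributed over the atoms that exist. Heavy atoms only.

His is treated as neutral because its side-chain pKa (~6) puts the
neutral species in the majority at neutral pH; with this rule, side-chain
counting alone reproduces whole-molecule net charges because the
zwitterionic termini cancel per chain.

### Distribution providers

**Ideal-dilute (low-density) provider.** g = exp(−β Σ_α u_αγ), for which
the total has the closed form −kT Σ_γ ρ_γ ∫ (e^{−βu_γ} − 1) dV for *any*
path — the validation backend. Validation systems use a weakly coupled
two-site solvent (±0.1 e); with full water charges the unscreened
Boltzmann factor reaches e^100+ in the deep Coulomb wells and the numbers,
while internally consistent, are physically meaningless. Support is a
fine radial grid for single atoms and a regular 3-D grid otherwise.

**3D-RISM/KH provider.** The production backend solves the
three-dimensional Ornstein–Zernike relation (an FFT convolution with the
pure-solvent site–site susceptibility χ(k)) with the Kovalenko–Hirata
closure, g = e^d for d ≤ 0 and g = 1 + d for d > 0, d = −βu + h − c.
KH guarantees g ≥ 0 and admits the closed-form excess chemical potential
μ = kT Σ_γ ρ_γ ∫ [½h²Θ(−h) − c − ½hc] dV, equal to the charging integral
up to grid and quadrature error — the internal consistency check (≤ 2–3%
on the test solutes; measured ≈ 0.02–0.24%).

Long-range electrostatics is Gaussian-split with width η = 1 Å: the
erf-part of the solute potential is carried analytically in reciprocal
space with its k = 0 term removed (a neutralising background), so every
FFT-transformed quantity is short-ranged. Writing c = c_s − βu_long, the
closure argument and output reduce to short-range combinations; the
long-range term appears only inside the reciprocal-space OZ product.
Iteration uses MDIIS (depth 10, damping 0.3) on the short-range direct
correlation; λ nodes warm-start from their predecessor (verified
node-order independent). Default grid: 0.5 Å spacing, 12 Å padding;
halving the spacing moves the single-ion result by 0.15%.

**Solvent susceptibility.** Default input is the analytic dilute
susceptibility χ = ω of the rigid molecule (sinc factors between bonded
sites) — download-free and sufficient for machinery tests. For production
analyses the package *dresses* χ with solvent–solvent correlations from
its 1-D site–site RISM solver (χ = ω + ρh, KH or HNC closure, same
Gaussian split, Picard iteration): with the dilute χ the solvent
over-responds by an order of magnitude (single-ion G_solv ≈ −850/−1300
kcal/mol for ±1 ions, versus −47/−103 with the dressed χ), which buries
every design signal. The dressed form is restricted to one-component
solvents (uniform site densities); the 150 mM NaCl option adds dilute
(undressed) ion sites. The packaged water model is SPC/E-like (O −0.8476,
H +0.4238, OH 1.0 Å, HH 1.633 Å, ρ 0.0334 Å⁻³) with a small LJ core on H
so Coulomb attraction stays integrable.

## Local-environment analytics

* **d_m** — minimum side-chain heavy-atom distance between a residue and
  the mutation site (Cα substitutes for Gly, or when side-chain atoms are
  missing). Always measured on the *wild-type* structure: design recipes
  must be usable from the wild type alone. For insertions, the anchor
  residue stands in as the site.
* **Charge census** — counts of charged residues with 0 < d_m ≤ cutoff
  (default 15 Å); local_net = n_positive − n_negative.
* **Salt bridges** — side-chain N (Lys NZ; Arg NE/NH1/NH2) within 4.0 Å
  of a carboxylate O (Asp OD1/OD2; Glu OE1/OE2); a bridge is "present" in
  an ensemble at ≥ 50% frame occupancy. The literature uses a range of
  criteria; these are the common conventions and both thresholds are
  configurable.
* **Exposure** — Shrake–Rupley SASA (960 points, 1.4 Å probe) normalised
  by Gly-X-Gly reference maxima; candidate sites need relative exposure
  ≥ 0.25.
* **Bulky flag** — side chains with ≥ 8 heavy atoms (Tyr, Trp), chosen so
  the designed charged mutations (Lys 5, Arg 7, Asp/Glu 4–5) are not
  flagged.

## Statistics

dG_solv is estimated from paired independent runs: per-run
dG = mean over mutant frames − mean over wild-type frames; the reported
value is the run average, the standard error is |dG₁ − dG₂|/2 for exactly
two runs (the study convention) and the sample SE otherwise; a single run
reports no SE. Per-run standard deviations of the per-frame dG trace are
exposed as the fluctuation diagnostic: solvation totals are dominated by
fine structural details (a single salt bridge is worth tens of kcal/mol),
so per-frame scatter is large even when the run mean is stable.

## Design ranking

The three factors — total net charge Q, mutation content dQ (and
bulkiness), and local net charge — are combined as

score = −(w_g · Q · dQ + w_l · local_net · dQ) + w_b · bulky,

lower = predicted more favourable, defaults w_g = w_l = 1 and w_b = 100.
This codification is the package's own: the factors are reported raw
alongside the score so users can re-weight, and on benches where local
environments are engineered to dominate, the ranking reproduces the
ordering of the computed dG_solv.

## Synthetic data

Structures are bead models: one backbone CA bead and one side-chain bead
per residue (named NZ/NH1/OD1/OE1/CB per type, so charge placement,
salt-bridge detection and parameterisation work unchanged), on a
Fibonacci sphere or an ideal helix (rise 1.5 Å, 100°/residue), with a
0.05 Å deterministic jitter to break symmetry. Generators are pure
functions of spec + seed, and every engineered premise (e.g. a requested
local net at a site) is re-measured after construction rather than
assumed. Frame ensembles add i.i.d. Gaussian displacements per atom per
frame (frame 0 = input), in independent per-run streams — sufficient to
exercise the averaging and error machinery, but *not* an emulation of
correlated molecular dynamics: passing tests demonstrate correctness of
the bookkeeping and the solvation model's behaviour, not agreement with
explicit-solvent trajectories of real proteins.

Problem sizes in the tests and the acceptance script (10–34-residue
benches, 0.5–0.7 Å grids, 3+3 to 8+8 λ nodes) are chosen so the whole
analysis runs at desk scale in minutes; all orderings asserted have wide
margins at these sizes.

## Known limitations

* The per-element LJ table and integer formal charges are a model
  substitution relative to force-field-parameterised solutes; absolute
  G_solv values are not comparable to explicit-solvent results.
* The crude water model with KH underestimates dielectric screening: the
  solvent-mediated charge–charge coupling measured on ion pairs decays to
  ~zero by 12 Å (a continuum would retain ≈ −33/d kcal/mol·Å). As a
  consequence the *global* design factor is short-ranged here: adding −1
  at a site far from all host charges of a Q = +3 host stays favourable
  (the anion's self-solvation, −103 vs −47 kcal/mol for the cation,
  outweighs the remote global term), whereas the Born picture — which
  places the added charge on the same sphere as Q — predicts a sign flip.
  The directional global effect (dG(+1) below dG(−1) on positive hosts)
  is robust.
* Finite-box effects on net-charged solutes converge slowly (~1/L) under
  the neutralising-background convention; comparisons are made at fixed
  box sizes.
* The ideal-dilute backend is a validation tool only: it has no screening,
  so charged-solute results grow with box size and multipoint effects are
  multiplicative rather than additive. Superposition of mutation effects
  is a property of the screened (3D-RISM) backend.
* No pKa prediction, no protonation optimisation, no conformational
  response to mutation (mutant structures are consumed or bead-built, not
  relaxed).
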