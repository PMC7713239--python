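# solvmut

Residue-wise solvation free-energy decomposition and local-charge analytics
for designing aggregation-resistant charged protein mutations.

## The problem

Introducing charged mutations is a standard route to improving the
solubility and aggregation resistance of biotherapeutic proteins such as
antibodies. Which sign of charge to add, and *where* to add it, can be
argued from solvation thermodynamics: the solvation free energy G_solv of
the whole protein measures its overall affinity for water, and the change
dG_solv = G_solv(mutant) − G_solv(wild type) upon a candidate mutation
predicts whether the mutant is better solvated. Two design factors govern
dG_solv for charged mutations:

* a **global** factor — when the protein net charge Q is positive, adding
  positive charge is solvated more favourably (and vice versa), in line
  with the continuum Born picture where dG ∝ −(2Q·dQ + dQ²);
* a **local** factor — the net charge of the residues within ~15 Å of the
  mutation site modulates the effect strongly: a +1 mutation is more
  favourable where the local net charge is already positive.

`solvmut` implements the machinery needed to compute and dissect these
effects on rigid structures and frame ensembles:

* an **exact per-atom decomposition** of G_solv via the Kirkwood charging
  formula,

  G_solv = Σ_α G_α,  G_α = Σ_γ ρ_γ ∫₀¹ dλ ∫ dV (∂u_αγ/∂λ) g_γ(r; λ),

  where α runs over solute atoms, γ over solvent sites, ρ_γ is the solvent
  site density and g_γ the solute–solvent distribution function at coupling
  λ. Grouping atoms by residue yields the per-residue profile;
* a **3D-RISM solver** with the Kovalenko–Hirata (KH) closure as the
  distribution-function backend (FFT-based Ornstein–Zernike iteration,
  MDIIS acceleration, Gaussian-split long-range electrostatics), plus the
  closed-form KH free-energy functional for cross-validation, an analytic
  rigid-solvent susceptibility and a 1-D site–site RISM solver that dresses
  it with solvent–solvent correlations;
* an **ideal-dilute provider** with a closed-form total, so every piece of
  the charging machinery can be validated against an independent oracle;
* **local-environment analytics**: minimum side-chain heavy-atom distance
  d_m to the mutation site, the signed charge census within a cutoff
  (default 15 Å), salt-bridge formation/breaking between wild-type and
  mutant ensembles, Shrake–Rupley solvent exposure, and bulky-side-chain
  flags;
* **mutation bookkeeping** (substitutions, N-terminal-style charge-triplet
  insertions, dQ accounting, wild-type↔mutant residue correspondence),
  run-paired dG statistics, and a transparent three-factor ranking
  heuristic for candidate mutations;
* a **synthetic-structure generator** producing compact bead proteins with
  engineered local charge environments, matched wild-type/mutant pairs and
  jittered frame ensembles standing in for trajectory snapshots.

## Worked example

Score two candidate +1 mutations on a synthetic host whose two sites have
engineered local nets of +2 and −2, then compute the actual per-residue
dG_solv profiles with the 3D-RISM backend:

```python
from solvmut import water_model
from solvmut.mutation_model import parse_mutation_list
from solvmut.pipeline import ProfileConfig, profile, rank_candidates
from solvmut.rism_backend import solve_1d_rism
from solvmut.synthetic_data import benchmark_suite, make_mutant

benches = benchmark_suite(seed=1)
bench = benches["local_principle"]
host = bench["structure"]            # 32 residues, net charge 0

report = rank_candidates(host, [bench["site_plus"], bench["site_minus"]],
                         ["K"])
for c in report.candidates:
    print(f"#{c.rank} {c.site} ->K  local_net={c.local_net:+d} "
          f"score={c.score:+.0f}")

water = water_model()
chi = solve_1d_rism(water)           # dressed water susceptibility
cfg = ProfileConfig(grid_spacing=0.7, grid_padding=6.0,
                    n_lj_nodes=3, n_coulomb_nodes=3)
for site in (bench["site_plus"], bench["site_minus"]):
    ms = parse_mutation_list(f"A:A{site.seq_number}K")
    res = profile([host], [make_mutant(host, ms)], ms, solvent=water,
                  backend="rism", config=cfg, susceptibility=chi)
    print(f"{ms}: dG_solv = {res.stats.mean:+.1f} kcal/mol")
```

Output:

```
#1 A:1 ->K  local_net=+2 score=-2
#2 A:32 ->K  local_net=-2 score=+2
A:A1K: dG_solv = -119.7 kcal/mol
A:A32K: dG_solv = +4.9 kcal/mol
```

The ranking predicts, and the decomposition confirms, that the same
glutamine→lysine-style +1 mutation is strongly favourable at the site
surrounded by two extra positive charges (−119.7 kcal/mol) and unfavourable
at the site surrounded by two extra negative charges (+4.9 kcal/mol) — the
local design principle. Over 96% of the absolute per-residue change sits
within 15 Å of the mutation site.

A thin CLI exposes the same operations as subcommands
(`solvmut decompose | census | rank | rmsd-check | synth`).

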