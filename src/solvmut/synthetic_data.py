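"""Synthetic structures, mutants and jittered frame ensembles.

The generators produce download-free inputs with the statistical structure
the analysis assumes: compact bead-model proteins with controllable charge
placement (so that local 15 A environments can be designed), matched
wild-type/mutant pairs, and multi-frame ensembles with Gaussian positional
jitter standing in for snapshots taken from equilibrated trajectories at a
fixed time interval, in independent pairs of runs.

Each residue is two beads: a backbone CA bead and one side-chain bead whose
name/element follow the residue type (Lys NZ, Arg NH1, Asp OD1, Glu OE1,
Ala CB), so that charge placement, salt-bridge detection and the solute
parameterisation all work unchanged on synthetic structures.  Every
generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .local_environment import charge_census, min_sidechain_distance
from .mutation_model import InsertionSet, Mutation, MutationSet
from .structure_io import (
    Atom,
    ChargedStructure,
    Residue,
    ResidueKey,
    StructureEnsemble,
    assign_formal_charges,
)

__all__ = [
    "SynthSpec",
    "JitterSpec",
    "LocalTarget",
    "make_structure",
    "make_mutant",
    "make_runs",
    "benchmark_suite",
]

#: Side-chain bead name and element per residue type.
_SIDE_BEAD = {
    "LYS": ("NZ", "N"),
    "ARG": ("NH1", "N"),
    "ASP": ("OD1", "O"),
    "GLU": ("OE1", "O"),
    "ALA": ("CB", "C"),
    "GLN": ("CB", "C"),
    "SER": ("CB", "C"),
    "TYR": ("CB", "C"),
}
_CHARGE_AA = {+1: "LYS", -1: "ASP"}
_SIDE_OFFSET = 3.2  # A, CA -> side bead
_JITTER = 0.05  # A, deterministic symmetry-breaking noise on bead positions


@dataclass(frozen=True)
class LocalTarget:
    """Requested local net charge at a named site: the generator places
    charged residues with 0 < d_m <= cutoff of ``site_position`` until the
    census there equals ``local_net``."""

    site_position: int  # 1-based residue number
    local_net: int
    cutoff: float = 15.0


@dataclass
class SynthSpec:
    """Specification of a synthetic bead protein.

    ``charges`` places +-1 residues explicitly by position; ``local_targets``
    asks for engineered local environments; ``far_charges`` places charges
    at residues farther than cutoff + margin from every named site (to set
    the global net charge without touching local environments).
    """

    n_residues: int
    geometry: str = "sphere"  # or "helix"
    chain_id: str = "A"
    charges: list = field(default_factory=list)  # (position, +-1)
    local_targets: list = field(default_factory=list)
    far_charges: int = 0
    far_margin: float = 4.0
    radius: float | None = None  # sphere radius; default from n_residues
    seed: int = 0


@dataclass
class JitterSpec:
    """Frame-ensemble generator settings: i.i.d. Gaussian positional noise
    of width sigma per atom per frame, ``n_runs`` independent streams."""

    n_frames: int = 10
    sigma: float = 0.1  # A
    n_runs: int = 2
    frame_interval: float = 1.0  # ns, metadata
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _sphere_positions(n: int, radius: float) -> np.ndarray:
    """Fibonacci lattice on a sphere: near-uniform bead placement."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rxy = np.sqrt(np.maximum(1.0 - z ** 2, 0.0))
    return radius * np.stack(
        [rxy * np.cos(phi), rxy * np.sin(phi), z], axis=1)


def _helix_positions(n: int) -> np.ndarray:
    """Ideal helix: rise 1.5 A and 100 degrees per residue, radius 2.3 A."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i],
                    axis=1)


def _build(spec: SynthSpec, aa_types: list[str]) -> ChargedStructure:
    n = spec.n_residues
    if spec.geometry == "sphere":
        radius = spec.radius or float(np.sqrt(n * 6.0 ** 2 / (4 * np.pi)))
        ca = _sphere_positions(n, radius)
        normals = ca / np.linalg.norm(ca, axis=1, keepdims=True)
    elif spec.geometry == "helix":
        ca = _helix_positions(n)
        normals = ca.copy()
        normals[:, 2] = 0.0
        nrm = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = np.where(nrm > 0, normals / np.maximum(nrm, 1e-9),
                           [1.0, 0.0, 0.0])
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    side = ca + _SIDE_OFFSET * normals

    rng = np.random.default_rng([spec.seed, 0x5EED])
    ca = ca + rng.normal(scale=_JITTER, size=ca.shape)
    side = side + rng.normal(scale=_JITTER, size=side.shape)

    residues, atoms, coords = [], [], []
    serial = 1
    for i, aa in enumerate(aa_types):
        residues.append(Residue(chain_id=spec.chain_id, seq_number=i + 1,
                                aa_type=aa))
        atoms.append(Atom(serial=serial, name="CA", element="C",
                          residue_index=i))
        coords.append(ca[i])
        serial += 1
        bead_name, bead_el = _SIDE_BEAD.get(aa, ("CB", "C"))
        atoms.append(Atom(serial=serial, name=bead_name, element=bead_el,
                          residue_index=i))
        coords.append(side[i])
        serial += 1
    ens = StructureEnsemble(atoms=atoms, residues=residues,
                            frames=[np.array(coords)])
    return assign_formal_charges(ens)


def make_structure(spec: SynthSpec) -> ChargedStructure:
    """Build a charged bead structure from a spec (deterministic per seed).

    The requested local environments are verified by measurement after
    construction: the census at each named site must equal its target, and
    infeasible placements raise.
    """
    aa_types = ["ALA"] * spec.n_residues
    for pos, q in spec.charges:
        if not 1 <= pos <= spec.n_residues:
            raise ValueError(f"charge position {pos} outside chain")
        aa_types[pos - 1] = _CHARGE_AA[int(np.sign(q))]

    # geometry pass with explicit charges only, to measure distances
    cs = _build(spec, aa_types)
    site_keys = {t.site_position: ResidueKey(spec.chain_id, t.site_position)
                 for t in spec.local_targets}

    for target in spec.local_targets:
        site = site_keys[target.site_position]
        want = target.local_net
        d_all = {
            r.seq_number: min_sidechain_distance(cs, r.key, site)
            for r in cs.residues
        }
        census = charge_census(cs, site, cutoff=target.cutoff)
        need = want - census.local_net
        sign = int(np.sign(need)) if need else 0
        candidates = [
            num for num, d in d_all.items()
            if 2.0 < d <= target.cutoff - 2.0
            and aa_types[num - 1] == "ALA"
            and num not in site_keys
            and all(
                min_sidechain_distance(
                    cs, ResidueKey(spec.chain_id, num), other
                ) > target.cutoff + spec.far_margin
                for other in site_keys.values() if other != site
            )
        ]
        candidates.sort(key=lambda num: d_all[num])
        if len(candidates) < abs(need):
            raise ValueError(
                f"cannot reach local net {want} at site {site}: only "
                f"{len(candidates)} placeable residues within "
                f"{target.cutoff} A")
        for num in candidates[:abs(need)]:
            aa_types[num - 1] = _CHARGE_AA[sign]

    if spec.far_charges:
        sign = int(np.sign(spec.far_charges))
        far = [
            r.seq_number for r in cs.residues
            if aa_types[r.seq_number - 1] == "ALA"
            and r.seq_number not in site_keys
            and all(
                min_sidechain_distance(cs, r.key, sk) >
                max((t.cutoff for t in spec.local_targets),
                    default=15.0) + spec.far_margin
                for sk in site_keys.values()
            )
        ]
        if len(far) < abs(spec.far_charges):
            raise ValueError(
                f"cannot place {spec.far_charges} far charges: only "
                f"{len(far)} residues beyond the cutoff margin")
        for num in far[:abs(spec.far_charges)]:
            aa_types[num - 1] = _CHARGE_AA[sign]

    out = _build(spec, aa_types)
    for target in spec.local_targets:  # verify the premise by measurement
        got = charge_census(out, site_keys[target.site_position],
                            cutoff=target.cutoff).local_net
        if got != target.local_net:
            raise ValueError(
                f"census at site {target.site_position} is {got}, "
                f"requested {target.local_net}")
    return out


# ---------------------------------------------------------------------------
# Mutants
# ---------------------------------------------------------------------------

def make_mutant(base: ChargedStructure, ms: MutationSet) -> ChargedStructure:
    """Apply a mutation set at bead level: substitutions swap the side bead
    type in place (backbone untouched); insertions extend the chain before
    the anchor along the outward normal, with a clash check."""
    from .constants import ONE_TO_THREE

    residues = [replace(r) for r in base.residues]
    atoms = [replace(a) for a in base.atoms]
    coords = base.coords.copy()

    for m in ms.substitutions:
        idx = base.residue_by_key(m.site_key)
        if residues[idx].one_letter != m.wt_aa:
            raise ValueError(
                f"wild-type mismatch at {m.site_key}: structure has "
                f"{residues[idx].one_letter}, mutation expects {m.wt_aa}")
        new_aa = ONE_TO_THREE[m.mut_aa]
        residues[idx] = replace(residues[idx], aa_type=new_aa)
        bead_name, bead_el = _SIDE_BEAD.get(new_aa, ("CB", "C"))
        for ai in base.residue_atom_indices(idx):
            if atoms[ai].name != "CA":
                atoms[ai] = replace(atoms[ai], name=bead_name,
                                    element=bead_el)

    for ins in ms.insertions:
        anchor_idx = base.residue_by_key(ins.anchor_key)
        anchor_ca = None
        for ai in base.residue_atom_indices(anchor_idx):
            if base.atoms[ai].name == "CA":
                anchor_ca = base.coords[ai]
        if anchor_ca is None:
            raise ValueError(f"anchor {ins.anchor_key} has no CA")
        center = base.coords.mean(axis=0)
        normal = anchor_ca - center
        nrm = np.linalg.norm(normal)
        normal = normal / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
        tangent = np.cross(normal, [0.0, 0.0, 1.0])
        if np.linalg.norm(tangent) < 1e-6:
            tangent = np.cross(normal, [0.0, 1.0, 0.0])
        tangent /= np.linalg.norm(tangent)

        new_coords = []
        for i, (aa1, key) in enumerate(zip(ins.inserted_aas,
                                           ins.inserted_keys())):
            aa = ONE_TO_THREE[aa1]
            ca_pos = (anchor_ca + (5.5 + 1.8 * i) * normal
                      + 2.0 * (i - (len(ins.inserted_aas) - 1) / 2)
                      * tangent)
            bead_name, bead_el = _SIDE_BEAD.get(aa, ("CB", "C"))
            side_pos = ca_pos + _SIDE_OFFSET * normal
            res = Residue(chain_id=key.chain_id, seq_number=key.seq_number,
                          icode=key.icode, aa_type=aa)
            ridx = len(residues)
            residues.append(res)
            atoms.append(Atom(serial=len(atoms) + 1, name="CA",
                              element="C", residue_index=ridx))
            atoms.append(Atom(serial=len(atoms) + 1, name=bead_name,
                              element=bead_el, residue_index=ridx))
            new_coords.extend([ca_pos, side_pos])
        new_coords = np.array(new_coords)
        from scipy.spatial.distance import cdist
        if cdist(new_coords, coords).min() < 1.5:
            raise ValueError(f"insertion {ins} clashes with the host")
        coords = np.vstack([coords, new_coords])

    ens = StructureEnsemble(atoms=atoms, residues=residues, frames=[coords])
    mut = assign_formal_charges(ens, rules=base.charge_rules or None)
    if mut.total_charge - base.total_charge != ms.delta_q:
        raise AssertionError("delta_q bookkeeping violated by generator")
    return mut


# ---------------------------------------------------------------------------
# Frame ensembles
# ---------------------------------------------------------------------------

def make_runs(structure: ChargedStructure, js: JitterSpec
              ) -> list[ChargedStructure]:
    """Independent jittered frame ensembles (one per run).

    Frame 0 is the input structure; subsequent frames add i.i.d. Gaussian
    displacements of width sigma to every atom.  Each run uses a stream
    derived from (seed, run_id), so runs are independent but reproducible.
    """
    if js.sigma > 1.0:
        warnings.warn(
            f"jitter sigma {js.sigma} A is large; frames may fail the "
            "RMSD stability gate", stacklevel=2)
    runs = []
    base = structure.coords
    for run_id in range(js.n_runs):
        rng = np.random.default_rng([js.seed, run_id])
        frames = [base.copy()]
        for _ in range(1, js.n_frames):
            frames.append(base + rng.normal(scale=js.sigma,
                                            size=base.shape))
        ens = replace(structure, frames=frames, run_id=run_id,
                      frame_interval=js.frame_interval)
        runs.append(ens)
    return runs


# ---------------------------------------------------------------------------
# Canonical benches
# ---------------------------------------------------------------------------

def _salt_bridge_fixture(seed: int) -> ChargedStructure:
    """Four-residue fixture with one engineered Lys-Asp bridge: the NZ and
    OD1 beads are placed 3.0 A apart; two neutral residues sit well away."""
    rng = np.random.default_rng([seed, 0xB41D6E])
    residues, atoms, coords = [], [], []
    layout = [
        ("LYS", [0.0, 0.0, 0.0], [3.2, 0.0, 0.0]),
        ("ASP", [9.0, 0.0, 0.0], [6.2, 0.0, 0.0]),  # NZ-OD1 gap 3.0 A
        ("ALA", [0.0, 12.0, 0.0], [3.2, 12.0, 0.0]),
        ("ALA", [0.0, 0.0, 12.0], [3.2, 0.0, 12.0]),
    ]
    serial = 1
    for i, (aa, ca, side) in enumerate(layout):
        residues.append(Residue(chain_id="A", seq_number=i + 1, aa_type=aa))
        bead_name, bead_el = _SIDE_BEAD[aa]
        atoms.append(Atom(serial=serial, name="CA", element="C",
                          residue_index=i))
        coords.append(np.array(ca, dtype=float))
        serial += 1
        atoms.append(Atom(serial=serial, name=bead_name, element=bead_el,
                          residue_index=i))
        coords.append(np.array(side, dtype=float))
        serial += 1
    coords = np.array(coords) + rng.normal(scale=0.01, size=(len(coords), 3))
    ens = StructureEnsemble(atoms=atoms, residues=residues, frames=[coords])
    return assign_formal_charges(ens)

def benchmark_suite(seed: int = 0) -> dict:
    """The canonical synthetic benches used by the acceptance analyses.

    Keys: ``single_ion``, ``ion_pair``, ``mini_protein`` (Q = +3),
    ``local_principle`` (two candidate sites with engineered local nets
    +2 / -2), ``neutral_host`` (Q = 0 with a negative local environment at
    the insertion anchor), ``salt_bridge``.  Entries carry the structure
    plus the site bookkeeping their analyses need; every engineered premise
    is re-measured at generation time.
    """
    single_ion = make_structure(SynthSpec(
        n_residues=1, geometry="helix", charges=[(1, +1)], seed=seed))

    ion_pair = make_structure(SynthSpec(
        n_residues=2, geometry="helix", charges=[(1, +1), (2, -1)],
        seed=seed))

    mini = make_structure(SynthSpec(
        n_residues=10, geometry="sphere", radius=5.5,
        charges=[(1, +1), (4, +1), (8, +1)], seed=seed))
    assert mini.total_charge == +3

    n_local = 32
    local = make_structure(SynthSpec(
        n_residues=n_local, geometry="sphere", radius=9.5,
        local_targets=[LocalTarget(1, +2, 15.0),
                       LocalTarget(n_local, -2, 15.0)],
        seed=seed))
    assert local.total_charge == 0

    # Q = 0 host whose insertion anchor sees a negative local environment:
    # one engineered Asp pair near residue 1, balanced by Lys on the far side
    neutral = make_structure(SynthSpec(
        n_residues=34, geometry="sphere", radius=10.0,
        local_targets=[LocalTarget(1, -2, 15.0)],
        far_charges=+2, seed=seed))
    assert neutral.total_charge == 0

    bridge = _salt_bridge_fixture(seed)

    return {
        "single_ion": {"structure": single_ion},
        "ion_pair": {"structure": ion_pair},
        "mini_protein": {"structure": mini,
                         "remote_site": ResidueKey("A", 6)},
        "local_principle": {
            "structure": local,
            "site_plus": ResidueKey("A", 1),
            "site_minus": ResidueKey("A", n_local),
            "cutoff": 15.0,
        },
        "neutral_host": {"structure": neutral,
                         "anchor": ResidueKey("A", 1)},
        "salt_bridge": {"structure": bridge},
    }
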