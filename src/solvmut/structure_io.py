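"""Protein structures, frame ensembles, formal charges and RMSD.

Structures are held as a single topology (atoms + residues) shared by one or
more coordinate frames, mirroring how snapshots taken from a trajectory share
one set of atoms.  PDB reading/writing is delegated to :mod:`biotite`; all
geometric analytics downstream operate on heavy atoms only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import BACKBONE_ATOMS, DEFAULT_CHARGE_RULES, THREE_TO_ONE

__all__ = [
    "Atom",
    "Residue",
    "StructureEnsemble",
    "ChargedStructure",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "assign_formal_charges",
    "net_charge",
    "kabsch_rmsd",
    "rmsd_trace",
    "RmsdTrace",
]


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


@dataclass(frozen=True)
class ResidueKey:
    """Hashable identifier of a residue: chain, number, insertion code."""

    chain_id: str
    seq_number: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "H:10" or "H:10a"
        return f"{self.chain_id}:{self.seq_number}{self.icode}"


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    aa_type: str  # 3-letter code
    icode: str = ""
    formal_charge: int = 0

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.seq_number, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.aa_type, "X")

    @property
    def is_standard(self) -> bool:
        return self.aa_type in THREE_TO_ONE


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int  # index into StructureEnsemble.residues

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def is_sidechain(self, residue: Residue) -> bool:
        """Heavy atoms beyond the backbone; Gly's CA stands in for its
        side chain."""
        if self.is_hydrogen:
            return False
        if residue.aa_type == "GLY" and self.name == "CA":
            return True
        return self.name not in BACKBONE_ATOMS


@dataclass
class StructureEnsemble:
    """One topology with one or more coordinate frames.

    ``frames[i]`` is an ``(n_atoms, 3)`` float array in Angstrom; all frames
    share atom count and ordering.  ``frame_interval`` is a time label in ns
    carried as metadata only.
    """

    atoms: list[Atom]
    residues: list[Residue]
    frames: list[np.ndarray]
    run_id: int = 0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected ({n}, 3)"
                )
            if not np.all(np.isfinite(f)):
                raise ValueError(f"frame {i} contains non-finite coordinates")
            self.frames[i] = f

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """Coordinates of the first frame (the representative structure)."""
        return self.frames[0]

    @property
    def atom_residue_index(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def sidechain_mask(self) -> np.ndarray:
        return np.array(
            [a.is_sidechain(self.residues[a.residue_index]) for a in self.atoms],
            dtype=bool,
        )

    def ca_mask(self) -> np.ndarray:
        return np.array(
            [a.name == "CA" and not a.is_hydrogen for a in self.atoms], dtype=bool
        )

    def residue_atom_indices(self, res_index: int) -> np.ndarray:
        return np.nonzero(self.atom_residue_index == res_index)[0]

    def residue_by_key(self, key: ResidueKey) -> int:
        for i, r in enumerate(self.residues):
            if r.key == key:
                return i
        raise KeyError(f"no residue {key}")

    def with_frames(self, frames: list[np.ndarray], run_id: int | None = None
                    ) -> "StructureEnsemble":
        return replace(
            self, frames=list(frames),
            run_id=self.run_id if run_id is None else run_id,
        )


@dataclass
class ChargedStructure(StructureEnsemble):
    """A structure ensemble whose residues carry formal charges."""

    charge_rules: dict = field(default_factory=dict)

    @property
    def total_charge(self) -> int:
        return int(sum(r.formal_charge for r in self.residues))

    def residue_charges(self) -> np.ndarray:
        return np.array([r.formal_charge for r in self.residues], dtype=int)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SOL"}


def _validate_pdb_records(path: str) -> None:
    """Cheap scan for malformed coordinate records, reporting line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(
                        f"{path}:{lineno}: unparseable coordinate record: "
                        f"{line.rstrip()!r}"
                    ) from exc


def read_pdb(path: str, include_hetero: bool = False) -> StructureEnsemble:
    """Read a PDB file into a :class:`StructureEnsemble`.

    One frame per MODEL block (a single frame if the file has none).
    Alternate locations are resolved to the highest-occupancy conformer
    (ties resolved alphabetically, i.e. to 'A'); waters and hetero groups
    are excluded unless ``include_hetero``; hydrogens are retained.
    """
    import biotite.structure.io.pdb as pdb

    _validate_pdb_records(str(path))
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(altloc="occupancy")
    except Exception as exc:  # biotite raises a mix of error types
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc

    arr0 = stack[0]
    keep = ~np.isin(arr0.res_name, list(_WATER_NAMES))
    if not include_hetero:
        keep &= ~arr0.hetero
    stack = stack[..., keep]
    arr0 = stack[0]
    if arr0.array_length() == 0:
        raise PDBParseError(f"{path}: no protein atoms found")

    residues: list[Residue] = []
    res_lookup: dict[tuple, int] = {}
    atoms: list[Atom] = []
    for i in range(arr0.array_length()):
        icode = str(arr0.ins_code[i]).strip()
        rk = (str(arr0.chain_id[i]), int(arr0.res_id[i]), icode,
              str(arr0.res_name[i]))
        if rk not in res_lookup:
            res_lookup[rk] = len(residues)
            residues.append(
                Residue(chain_id=rk[0], seq_number=rk[1], icode=rk[2],
                        aa_type=rk[3])
            )
        atoms.append(
            Atom(serial=i + 1, name=str(arr0.atom_name[i]),
                 element=str(arr0.element[i]) or "C",
                 residue_index=res_lookup[rk])
        )

    frames = [np.asarray(stack.coord[m], dtype=float)
              for m in range(stack.stack_depth())]
    return StructureEnsemble(atoms=atoms, residues=residues, frames=frames)


def write_pdb(ensemble: StructureEnsemble, path: str) -> None:
    """Write all frames of an ensemble as MODEL blocks of a PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ensemble.n_atoms
    arr = struc.AtomArray(n)
    for i, atom in enumerate(ensemble.atoms):
        res = ensemble.residues[atom.residue_index]
        arr.chain_id[i] = res.chain_id
        arr.res_id[i] = res.seq_number
        arr.ins_code[i] = res.icode
        arr.res_name[i] = res.aa_type
        arr.atom_name[i] = atom.name
        arr.element[i] = atom.element
        arr.hetero[i] = False
    if ensemble.n_frames == 1:
        arr.coord = ensemble.frames[0]
        obj = arr
    else:
        obj = struc.stack([arr] * ensemble.n_frames)
        obj.coord = np.stack(ensemble.frames)
    f = pdb.PDBFile()
    f.set_structure(obj)
    f.write(str(path))


# ---------------------------------------------------------------------------
# Formal charges
# ---------------------------------------------------------------------------

def assign_formal_charges(
    structure: StructureEnsemble,
    rules: dict[str, int] | None = None,
) -> ChargedStructure:
    """Assign formal charges at neutral pH.

    Asp/Glu are -1, Lys/Arg +1, everything else (including His) 0.  Termini
    contribute nothing: the zwitterionic NH3+/COO- pair cancels per chain.
    Non-standard residues get charge 0 with a warning.
    """
    rules = DEFAULT_CHARGE_RULES if rules is None else rules
    residues = []
    for r in structure.residues:
        if not r.is_standard:
            warnings.warn(
                f"non-standard residue {r.aa_type} at {r.key}: charge 0",
                stacklevel=2,
            )
        residues.append(replace(r, formal_charge=rules.get(r.aa_type, 0)))
    return ChargedStructure(
        atoms=list(structure.atoms),
        residues=residues,
        frames=list(structure.frames),
        run_id=structure.run_id,
        frame_interval=structure.frame_interval,
        charge_rules=dict(rules),
    )


def net_charge(cs: ChargedStructure, chains: set[str] | None = None) -> int:
    """Net formal charge in e, optionally restricted to a set of chains."""
    if chains is not None:
        known = set(cs.chains)
        unknown = set(chains) - known
        if unknown:
            raise KeyError(f"unknown chain id(s): {sorted(unknown)}")
        return int(sum(r.formal_charge for r in cs.residues
                       if r.chain_id in chains))
    return cs.total_charge


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Minimal RMSD between two corresponding point sets after optimal
    rigid superposition (Kabsch)."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"point sets must match: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a0, b0)
    # evaluate the residual explicitly: the rssd reported by align_vectors
    # loses ~8 digits to cancellation when the fit is near-exact
    diff = rot.apply(b0) - a0
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


@dataclass
class RmsdTrace:
    series: np.ndarray  # per-frame RMSD to the reference, A
    max: float
    threshold: float

    @property
    def passes_gate(self) -> bool:
        return self.max <= self.threshold


def rmsd_trace(
    ensemble: StructureEnsemble,
    reference: np.ndarray | None = None,
    selection: np.ndarray | None = None,
    threshold: float = 3.0,
) -> RmsdTrace:
    """C-alpha RMSD of every frame to a reference frame.

    ``selection`` is a boolean atom mask (default: C-alpha atoms); the gate
    flag records whether the maximum stayed within ``threshold`` (the
    conventional stability criterion for equilibrated trajectories).
    """
    mask = ensemble.ca_mask() if selection is None else np.asarray(selection)
    ref = ensemble.frames[0] if reference is None else np.asarray(reference)
    series = np.array(
        [kabsch_rmsd(f[mask], ref[mask]) for f in ensemble.frames]
    )
    return RmsdTrace(series=series, max=float(series.max()),
                     threshold=threshold)
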