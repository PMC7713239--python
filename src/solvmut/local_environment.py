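"""Local-environment analytics around a mutation site.

The quantities here carry the "local" design factor: the minimum side-chain
heavy-atom distance d_m from each residue to the mutation site, the signed
census of charged residues within a cutoff (default 15 A) of the site,
salt-bridge formation/breaking between wild type and mutant, solvent
exposure, and a bulky-side-chain flag.  All distances are measured on the
wild-type structure, because design recipes must be usable from knowledge of
the wild type alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (
    GXG_MAX_SASA,
    SALT_BRIDGE_ACCEPTORS,
    SALT_BRIDGE_DONORS,
    SIDECHAIN_HEAVY_COUNT,
    VDW_DEFAULT,
    VDW_RADII,
)
from .mutation_model import CorrespondenceMap
from .structure_io import ChargedStructure, ResidueKey, StructureEnsemble

__all__ = [
    "NeighborRecord",
    "ChargeCensus",
    "SaltBridge",
    "min_sidechain_distance",
    "neighbor_records",
    "charge_census",
    "detect_salt_bridges",
    "salt_bridge_delta",
    "sasa",
    "relative_exposure",
    "environment_table",
    "bulky_flag",
]


def _charge_class(charge: int) -> str:
    return "positive" if charge > 0 else "negative" if charge < 0 else "neutral"


@dataclass
class NeighborRecord:
    key: ResidueKey
    d_m: float  # A; 0 for the mutation site itself
    charge_class: str


@dataclass
class ChargeCensus:
    cutoff: float
    n_positive: int
    n_negative: int

    @property
    def local_net(self) -> int:
        return self.n_positive - self.n_negative


@dataclass(frozen=True)
class SaltBridge:
    positive: ResidueKey
    negative: ResidueKey
    min_distance: float  # A, closest N-O contact
    occupancy: float = 1.0  # fraction of frames in which the bridge exists

    @property
    def pair(self) -> tuple[ResidueKey, ResidueKey]:
        return (self.positive, self.negative)


# ---------------------------------------------------------------------------
# Distances and census
# ---------------------------------------------------------------------------

def _sidechain_coords(
    cs: ChargedStructure, res_index: int, coords: np.ndarray
) -> np.ndarray:
    """Heavy side-chain atom coordinates of one residue (Gly: CA); falls
    back to CA with a warning when side-chain atoms are missing."""
    res = cs.residues[res_index]
    idx = cs.residue_atom_indices(res_index)
    side = [i for i in idx
            if cs.atoms[i].is_sidechain(res) and not cs.atoms[i].is_hydrogen]
    if not side:
        ca = [i for i in idx if cs.atoms[i].name == "CA"]
        if not ca:
            raise ValueError(f"residue {res.key} has no side-chain or CA atom")
        if res.aa_type != "GLY":
            warnings.warn(
                f"residue {res.key} ({res.aa_type}) lacks side-chain atoms; "
                "using CA", stacklevel=2,
            )
        side = ca
    return coords[side]


def _site_indices(cs: ChargedStructure, site) -> list[int]:
    keys = [site] if isinstance(site, ResidueKey) else list(site)
    return [cs.residue_by_key(k) for k in keys]


def min_sidechain_distance(
    cs: ChargedStructure,
    residue: ResidueKey,
    site,
    frame: np.ndarray | None = None,
) -> float:
    """d_m: minimum side-chain heavy-atom distance from ``residue`` to the
    mutation ``site`` (a residue key or a set of keys; for a multi-residue
    site the minimum over the set is taken).  Zero if the residue is part of
    the site."""
    coords = cs.coords if frame is None else frame
    site_idx = _site_indices(cs, site)
    res_idx = cs.residue_by_key(residue)
    if res_idx in site_idx:
        return 0.0
    a = _sidechain_coords(cs, res_idx, coords)
    best = np.inf
    for si in site_idx:
        b = _sidechain_coords(cs, si, coords)
        best = min(best, float(cdist(a, b).min()))
    return best


def neighbor_records(
    cs: ChargedStructure, site, frame: np.ndarray | None = None
) -> list[NeighborRecord]:
    """d_m and charge class for every residue, relative to the site."""
    return [
        NeighborRecord(
            key=r.key,
            d_m=min_sidechain_distance(cs, r.key, site, frame=frame),
            charge_class=_charge_class(r.formal_charge),
        )
        for r in cs.residues
    ]


def charge_census(
    cs: ChargedStructure,
    site,
    cutoff: float = 15.0,
    frame: np.ndarray | None = None,
) -> ChargeCensus:
    """Signed census of charged residues with 0 < d_m <= cutoff.

    The site itself is excluded; local_net = n_positive - n_negative is the
    local design factor.
    """
    n_pos = n_neg = 0
    for rec, res in zip(neighbor_records(cs, site, frame=frame), cs.residues):
        if rec.d_m <= 0.0 or rec.d_m > cutoff:
            continue
        if res.formal_charge > 0:
            n_pos += 1
        elif res.formal_charge < 0:
            n_neg += 1
    return ChargeCensus(cutoff=cutoff, n_positive=n_pos, n_negative=n_neg)


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

def _group_atom_coords(
    cs: ChargedStructure, res_index: int, names: tuple[str, ...],
    coords: np.ndarray,
) -> np.ndarray:
    idx = [i for i in cs.residue_atom_indices(res_index)
           if cs.atoms[i].name in names]
    return coords[idx]


def detect_salt_bridges(
    cs: ChargedStructure,
    distance_cutoff: float = 4.0,
    frame: np.ndarray | None = None,
) -> list[SaltBridge]:
    """Salt bridges in one frame.

    A bridge exists when any charged-group nitrogen of Lys (NZ) or Arg
    (NE/NH1/NH2) lies within ``distance_cutoff`` of any carboxylate oxygen
    of Asp (OD1/OD2) or Glu (OE1/OE2).  Each residue pair is reported once.
    """
    coords = cs.coords if frame is None else frame
    donors = [(i, SALT_BRIDGE_DONORS[r.aa_type])
              for i, r in enumerate(cs.residues)
              if r.aa_type in SALT_BRIDGE_DONORS]
    acceptors = [(i, SALT_BRIDGE_ACCEPTORS[r.aa_type])
                 for i, r in enumerate(cs.residues)
                 if r.aa_type in SALT_BRIDGE_ACCEPTORS]
    bridges = []
    for di, dnames in donors:
        dpos = _group_atom_coords(cs, di, dnames, coords)
        if dpos.size == 0:
            continue
        for ai, anames in acceptors:
            apos = _group_atom_coords(cs, ai, anames, coords)
            if apos.size == 0:
                continue
            dmin = float(cdist(dpos, apos).min())
            if dmin < distance_cutoff:
                bridges.append(SaltBridge(
                    positive=cs.residues[di].key,
                    negative=cs.residues[ai].key,
                    min_distance=dmin,
                ))
    return bridges


def _bridge_occupancy(
    ens: ChargedStructure, distance_cutoff: float
) -> dict[tuple, SaltBridge]:
    counts: dict[tuple, list] = {}
    for frame in ens.frames:
        for b in detect_salt_bridges(ens, distance_cutoff, frame=frame):
            entry = counts.setdefault(b.pair, [0, np.inf])
            entry[0] += 1
            entry[1] = min(entry[1], b.min_distance)
    return {
        pair: SaltBridge(positive=pair[0], negative=pair[1],
                         min_distance=dmin, occupancy=n / ens.n_frames)
        for pair, (n, dmin) in counts.items()
    }


def salt_bridge_delta(
    wt_ens: ChargedStructure,
    mut_ens: ChargedStructure,
    cmap: CorrespondenceMap,
    site_keys=(),
    occupancy_threshold: float = 0.5,
    distance_cutoff: float = 4.0,
) -> tuple[list[SaltBridge], list[SaltBridge], dict]:
    """Salt bridges formed and broken upon mutation.

    A bridge is "present" in an ensemble when its occupancy is at least
    ``occupancy_threshold``.  Formed = present in mutant only; broken =
    present in wild type only.  ``involves_site`` tags each changed bridge
    with whether one of its residues is a mutation site (wild-type keys for
    broken bridges, inserted/anchor keys for formed ones).
    """
    wt_b = {p: b for p, b in _bridge_occupancy(wt_ens, distance_cutoff).items()
            if b.occupancy >= occupancy_threshold}
    mut_b = {p: b
             for p, b in _bridge_occupancy(mut_ens, distance_cutoff).items()
             if b.occupancy >= occupancy_threshold}

    inv = cmap.inverse  # mutant key -> wt key
    mut_as_wt = {}
    for pair, b in mut_b.items():
        wt_pair = (inv.get(pair[0], pair[0]), inv.get(pair[1], pair[1]))
        mut_as_wt[wt_pair] = b

    formed = [b for p, b in mut_as_wt.items() if p not in wt_b]
    broken = [b for p, b in wt_b.items() if p not in mut_as_wt]

    sites = set(site_keys)
    mutant_sites = sites | set(cmap.mutant_only)
    involves_site = {}
    for b in formed:
        involves_site[b.pair] = bool(
            {b.positive, b.negative,
             inv.get(b.positive, b.positive), inv.get(b.negative, b.negative)}
            & mutant_sites
        )
    for b in broken:
        involves_site[b.pair] = bool({b.positive, b.negative} & sites)
    return formed, broken, involves_site


# ---------------------------------------------------------------------------
# Solvent exposure and bulkiness
# ---------------------------------------------------------------------------

def sasa(
    cs: StructureEnsemble,
    probe: float = 1.4,
    n_points: int = 960,
    frame: np.ndarray | None = None,
) -> dict:
    """Shrake-Rupley solvent-accessible surface area per residue (A^2).

    Heavy atoms only; unknown elements get a default radius with a warning.
    """
    import biotite.structure as struc

    coords = cs.coords if frame is None else frame
    heavy = np.nonzero(cs.heavy_mask)[0]
    n = len(heavy)
    arr = struc.AtomArray(n)
    radii = np.empty(n)
    for j, i in enumerate(heavy):
        atom = cs.atoms[i]
        res = cs.residues[atom.residue_index]
        arr.chain_id[j] = res.chain_id[:4]
        arr.res_id[j] = res.seq_number
        arr.res_name[j] = res.aa_type[:5]
        arr.atom_name[j] = atom.name[:6]
        arr.element[j] = atom.element
        el = atom.element.upper()
        if el not in VDW_RADII:
            warnings.warn(f"unknown element {el!r}: default vdW radius",
                          stacklevel=2)
        radii[j] = VDW_RADII.get(el, VDW_DEFAULT)
    arr.coord = coords[heavy]
    atom_sasa = struc.sasa(arr, probe_radius=probe, point_number=n_points,
                           vdw_radii=radii)
    per_res: dict = {}
    for j, i in enumerate(heavy):
        key = cs.residues[cs.atoms[i].residue_index].key
        per_res[key] = per_res.get(key, 0.0) + float(atom_sasa[j])
    return per_res


def relative_exposure(cs: ChargedStructure, **kwargs) -> dict:
    """Per-residue SASA normalised by Gly-X-Gly reference maxima."""
    areas = sasa(cs, **kwargs)
    out = {}
    for r in cs.residues:
        ref = GXG_MAX_SASA.get(r.one_letter, 200.0)
        out[r.key] = areas.get(r.key, 0.0) / ref
    return out


def environment_table(cs: ChargedStructure, site, cutoff: float = 15.0):
    """Per-residue environment summary around a site as a DataFrame:
    residue key, amino acid, charge class, d_m, SASA and census
    membership.  Suitable for CSV export."""
    import pandas as pd

    areas = sasa(cs)
    rows = []
    for rec, res in zip(neighbor_records(cs, site), cs.residues):
        rows.append({
            "key": str(rec.key),
            "aa": res.one_letter,
            "charge_class": rec.charge_class,
            "d_m": rec.d_m,
            "sasa": areas.get(rec.key, 0.0),
            "in_census": bool(0.0 < rec.d_m <= cutoff
                              and res.formal_charge != 0),
        })
    return pd.DataFrame(rows, columns=["key", "aa", "charge_class", "d_m",
                                       "sasa", "in_census"])


def bulky_flag(mut_aa: str, threshold: int = 8) -> bool:
    """True when the side chain has at least ``threshold`` heavy atoms.

    With the default threshold Tyr (8) and Trp (10) are flagged while the
    designed charged mutations (Lys 5, Arg 7, Asp/Glu 4-5) are not.
    """
    count = SIDECHAIN_HEAVY_COUNT.get(mut_aa.upper())
    if count is None:
        raise ValueError(f"unknown amino-acid code {mut_aa!r}")
    return count >= threshold
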