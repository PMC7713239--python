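"""Physical constants and per-residue/per-element parameter tables.

All energies are in kcal/mol, lengths in Angstrom, charges in units of the
elementary charge e, temperatures in Kelvin.
"""

from __future__ import annotations

#: Boltzmann constant, kcal/(mol K)
K_B = 0.0019872041

#: Coulomb constant k_e = 1/(4 pi eps_0) in kcal A / (mol e^2)
K_E = 332.0636

#: Formal charges of side chains at neutral pH.  Asp/Glu are deprotonated,
#: Lys/Arg protonated; His is treated as neutral (its pKa ~6 puts the
#: dominant species at pH 7 in the neutral form).  Termini are not charged:
#: the zwitterionic NH3+/COO- pair cancels per chain, so side-chain counting
#: alone yields the molecular net charge.
DEFAULT_CHARGE_RULES: dict[str, int] = {
    "ASP": -1,
    "GLU": -1,
    "LYS": +1,
    "ARG": +1,
}

#: 3-letter -> 1-letter amino-acid codes.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Charge of a 1-letter amino-acid code under the default rules.
def aa_charge(one_letter: str, rules: dict[str, int] | None = None) -> int:
    rules = DEFAULT_CHARGE_RULES if rules is None else rules
    return rules.get(ONE_TO_THREE.get(one_letter.upper(), ""), 0)


#: Number of side-chain heavy atoms per amino acid (Gly has none; for
#: geometric fall-backs its CA stands in for the side chain).
SIDECHAIN_HEAVY_COUNT = {
    "A": 1, "R": 7, "N": 4, "D": 4, "C": 2, "Q": 5, "E": 5, "G": 0,
    "H": 6, "I": 4, "L": 4, "K": 5, "M": 4, "F": 7, "P": 3, "S": 2,
    "T": 3, "W": 10, "Y": 8, "V": 3,
}

#: Van der Waals radii (A) for SASA; fallback used for unknown elements.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39,
}
VDW_DEFAULT = 1.70

#: Maximum solvent-accessible surface areas (A^2) of residue X in a
#: Gly-X-Gly tripeptide, used to normalise per-residue SASA into a relative
#: exposure.  Theoretical values of Tien et al. (2013).
GXG_MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Simplified per-element Lennard-Jones parameters (sigma in A, epsilon in
#: kcal/mol) for solute atoms.  This is a generic united table, not a
#: reproduction of any specific biomolecular force field.
ELEMENT_LJ = {
    "C": (3.40, 0.109),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.56, 0.250),
    "P": (3.74, 0.200),
    "H": (1.07, 0.0157),
}
ELEMENT_LJ_DEFAULT = (3.40, 0.109)

#: Atoms that carry the formal charge of a charged residue, with the
#: fraction of the residue charge assigned to each when present.
CHARGED_GROUP_ATOMS = {
    "LYS": {"NZ": 1.0},
    "ARG": {"CZ": 1.0},
    "ASP": {"OD1": 0.5, "OD2": 0.5},
    "GLU": {"OE1": 0.5, "OE2": 0.5},
}

#: Side-chain nitrogens of basic residues and carboxylate oxygens of acidic
#: residues used in salt-bridge detection.
SALT_BRIDGE_DONORS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
SALT_BRIDGE_ACCEPTORS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

#: Backbone heavy-atom names; everything else is side chain (Gly CA counts
#: as side chain for geometric purposes).
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
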