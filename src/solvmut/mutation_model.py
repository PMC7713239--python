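"""Mutation specifications, net-charge increments and wt/mutant residue
correspondence.

A mutation set carries plain substitutions ("E10G") and N-terminal-style
charge insertions (e.g. an RRR or DDD triplet inserted before an anchor
residue).  Its ``delta_q`` is the bookkeeping quantity dQ = Q(mutant) -
Q(wild type) under the neutral-pH charge rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .constants import DEFAULT_CHARGE_RULES, ONE_TO_THREE, aa_charge
from .structure_io import ChargedStructure, ResidueKey

__all__ = [
    "Mutation",
    "InsertionSet",
    "MutationSet",
    "CorrespondenceMap",
    "parse_mutation",
    "parse_mutation_list",
    "delta_q",
    "build_correspondence",
]

_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Mutation:
    """Single-residue substitution, e.g. E10G on chain H."""

    chain_id: str
    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"silent substitution {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in ONE_TO_THREE:
                raise ValueError(f"unknown amino-acid code {aa!r}")

    @property
    def site_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.position)

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class InsertionSet:
    """Residues inserted immediately before ``anchor_position``.

    Inserted residues are numbered with the anchor's number plus insertion
    codes a, b, c ... so downstream numbering stays stable.
    """

    chain_id: str
    anchor_position: int
    inserted_aas: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.inserted_aas:
            raise ValueError("empty insertion")
        for aa in self.inserted_aas:
            if aa not in ONE_TO_THREE:
                raise ValueError(f"unknown amino-acid code {aa!r}")

    @property
    def anchor_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.anchor_position)

    def inserted_keys(self) -> list[ResidueKey]:
        return [
            ResidueKey(self.chain_id, self.anchor_position,
                       chr(ord("a") + i))
            for i in range(len(self.inserted_aas))
        ]

    def __str__(self) -> str:
        return (f"{self.chain_id}:ins{self.anchor_position}"
                f"{''.join(self.inserted_aas)}")


@dataclass
class MutationSet:
    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for m in self.members:
            if isinstance(m, Mutation):
                key = (m.chain_id, m.position)
                if key in seen:
                    raise ValueError(
                        f"two substitutions at chain {m.chain_id} "
                        f"position {m.position}"
                    )
                seen.add(key)

    @property
    def substitutions(self) -> list[Mutation]:
        return [m for m in self.members if isinstance(m, Mutation)]

    @property
    def insertions(self) -> list[InsertionSet]:
        return [m for m in self.members if isinstance(m, InsertionSet)]

    @property
    def delta_q(self) -> int:
        return delta_q(self)

    def site_keys(self) -> list[ResidueKey]:
        """Wild-type residue keys naming the mutation site(s).

        For insertions the anchor residue stands in (the inserted residues
        do not exist in the wild type, and local annotations are measured on
        the wild-type structure)."""
        keys = [m.site_key for m in self.substitutions]
        keys += [ins.anchor_key for ins in self.insertions]
        return keys

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


def parse_mutation(text: str, chain_id: str) -> Mutation:
    """Parse a substitution string like "E10G" for a given chain."""
    m = _MUT_RE.match(text.strip().upper())
    if m is None:
        raise ValueError(f"malformed mutation string {text!r} "
                         "(expected e.g. 'E10G')")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    return Mutation(chain_id=chain_id, position=pos, wt_aa=wt, mut_aa=mut)


def parse_mutation_list(text: str) -> MutationSet:
    """Parse a chain-qualified comma list, e.g. "H:E10G,H:D73N,L:E80Q".

    Insertions are written "H:ins100RRR" (insert R,R,R before H:100).
    """
    members = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        if ":" not in token:
            raise ValueError(f"missing chain qualifier in {token!r}")
        chain, spec = token.split(":", 1)
        spec = spec.strip()
        ins = re.match(r"^ins(\d+)([A-Za-z]+)$", spec)
        if ins:
            members.append(InsertionSet(
                chain_id=chain, anchor_position=int(ins.group(1)),
                inserted_aas=tuple(ins.group(2).upper()),
            ))
        else:
            members.append(parse_mutation(spec, chain))
    return MutationSet(members)


def delta_q(ms: MutationSet, rules: dict[str, int] | None = None) -> int:
    """Net-charge increment dQ of a mutation set in e."""
    rules = DEFAULT_CHARGE_RULES if rules is None else rules
    total = 0
    for m in ms:
        if isinstance(m, Mutation):
            total += aa_charge(m.mut_aa, rules) - aa_charge(m.wt_aa, rules)
        else:
            total += sum(aa_charge(aa, rules) for aa in m.inserted_aas)
    return total


def validate_against_structure(ms: MutationSet, wt: ChargedStructure) -> None:
    """Check that each substitution's wild-type residue matches the
    structure; raises naming the offending position."""
    for m in ms.substitutions:
        idx = wt.residue_by_key(m.site_key)
        found = wt.residues[idx].one_letter
        if found != m.wt_aa:
            raise ValueError(
                f"wild-type mismatch at {m.site_key}: structure has {found}, "
                f"mutation expects {m.wt_aa}"
            )


@dataclass
class CorrespondenceMap:
    """Bijective pairing of wild-type and mutant residue keys, plus the
    unmatched (inserted / deleted) keys of either side."""

    pairs: dict  # wt ResidueKey -> mutant ResidueKey
    mutant_only: list
    wt_only: list

    def __post_init__(self) -> None:
        values = list(self.pairs.values())
        if len(set(values)) != len(values):
            raise ValueError("correspondence is not bijective")

    def mutant_key(self, wt_key: ResidueKey) -> ResidueKey:
        return self.pairs[wt_key]

    @property
    def inverse(self) -> dict:
        return {v: k for k, v in self.pairs.items()}


def build_correspondence(
    wt: ChargedStructure,
    mut: ChargedStructure,
    ms: MutationSet,
) -> CorrespondenceMap:
    """Match residues of a wild-type/mutant pair by (chain, number, icode).

    Substituted positions are matched across differing residue types;
    inserted positions are flagged mutant-only.  Any sequence difference the
    mutation set does not explain raises an error listing the positions.
    """
    wt_map = {r.key: r for r in wt.residues}
    mut_map = {r.key: r for r in mut.residues}
    sub_sites = {m.site_key for m in ms.substitutions}
    expected_inserted = {k for ins in ms.insertions
                         for k in ins.inserted_keys()}

    pairs: dict = {}
    unexplained: list = []
    for key, r in wt_map.items():
        if key in mut_map:
            if mut_map[key].aa_type != r.aa_type and key not in sub_sites:
                unexplained.append(key)
            pairs[key] = key
    mutant_only = [k for k in mut_map if k not in wt_map]
    wt_only = [k for k in wt_map if k not in mut_map]

    stray = [k for k in mutant_only if k not in expected_inserted]
    if unexplained or stray or wt_only:
        raise ValueError(
            "sequence differences not explained by the mutation set: "
            f"changed={sorted(map(str, unexplained))} "
            f"inserted={sorted(map(str, stray))} "
            f"deleted={sorted(map(str, wt_only))}"
        )
    return CorrespondenceMap(pairs=pairs, mutant_only=mutant_only,
                             wt_only=wt_only)
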