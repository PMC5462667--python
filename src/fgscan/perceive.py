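"""Functional-group perception by iterative atom marking and merging.

The perception has no pattern library. Atoms are marked by four structural
rules, marked atoms are merged into connected cores, and each core is
extracted together with its first-shell carbon environment:

1. every heteroatom (anything that is not C or H, halogens included) is
   marked;
2. carbons are marked when they (a) carry a non-aromatic double or triple
   bond to a heteroatom, (b) sit in a non-aromatic carbon–carbon double or
   triple bond, (c) are acetal-type sp3 carbons with two or more O/N/S
   neighbors each having only single bonds, or (d) belong to a
   three-membered oxirane/aziridine/thiirane ring;
3. marked atoms connected by non-aromatic bonds merge into one functional
   group — aromatic ring heteroatoms stay lone single-atom groups unless an
   aliphatic functionality (e.g. an acyl group on a pyrrole nitrogen)
   attaches to them through a non-aromatic bond;
4. unmarked carbons directly bonded to a core are recorded as the group's
   environment, typed aliphatic or aromatic; they are context, not part of
   the group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from rdkit import Chem

from .molio import Molecule

#: Rule tags recorded per marked atom.
TAG_HETEROATOM = "heteroatom"
TAG_C_MULTIBOND_HET = "c_multibond_het"
TAG_C_C_MULTIBOND = "c_c_multibond"
TAG_ACETAL_C = "acetal_c"
TAG_THREE_RING = "three_ring"

ALL_TAGS = frozenset(
    {TAG_HETEROATOM, TAG_C_MULTIBOND_HET, TAG_C_C_MULTIBOND, TAG_ACETAL_C, TAG_THREE_RING}
)

_MULTI = (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
_ONS = (7, 8, 16)


@dataclass(frozen=True)
class MarkSet:
    """Atoms flagged as functional-group members, with the rule(s) that fired."""

    marked: frozenset[int]
    reason_per_atom: Mapping[int, frozenset[str]]

    def tags(self, idx: int) -> frozenset[str]:
        return self.reason_per_atom.get(idx, frozenset())


@dataclass(frozen=True)
class Attachment:
    """One environment carbon bonded to a core atom."""

    core_atom: int
    env_carbon: int
    carbon_type: str  # "aliphatic" | "aromatic"


@dataclass(frozen=True)
class FunctionalGroup:
    """One connected FG core plus its typed first-shell carbon environment."""

    parent: Molecule
    core: frozenset[int]
    attachments: tuple[Attachment, ...]
    is_lone_aromatic_het: bool


def mark_heteroatoms(mol: Molecule) -> set[int]:
    """Indices of all atoms that are neither carbon nor hydrogen."""
    return {
        a.GetIdx() for a in mol.rdmol.GetAtoms() if a.GetAtomicNum() not in (1, 6)
    }


def _is_het(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() not in (1, 6)


def mark_carbons(mol: Molecule) -> set[int]:
    """Carbons marked by the four carbon rules (union of a–d)."""
    rd = mol.rdmol
    marked: set[int] = set()

    # (a) C=X / C#X and (b) C=C / C#C, both restricted to non-aromatic bonds
    for bond in rd.GetBonds():
        if bond.GetIsAromatic() or bond.GetBondType() not in _MULTI:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 6 and _is_het(b):
            marked.add(a.GetIdx())
        if b.GetAtomicNum() == 6 and _is_het(a):
            marked.add(b.GetIdx())
        if a.GetAtomicNum() == 6 and b.GetAtomicNum() == 6:
            marked.add(a.GetIdx())
            marked.add(b.GetIdx())

    # (c) acetal carbons: sp3 (non-aromatic, no multiple bond) with >=2
    # O/N/S neighbors, each of which has only single bonds
    for atom in rd.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if any(b.GetBondType() in _MULTI or b.GetIsAromatic() for b in atom.GetBonds()):
            continue
        n_ons = 0
        for nb in atom.GetNeighbors():
            if nb.GetAtomicNum() in _ONS and all(
                b.GetBondType() == Chem.BondType.SINGLE for b in nb.GetBonds()
            ):
                n_ons += 1
        if n_ons >= 2:
            marked.add(atom.GetIdx())

    # (d) oxirane / aziridine / thiirane ring carbons
    for ring in rd.GetRingInfo().AtomRings():
        if len(ring) != 3:
            continue
        atoms = [rd.GetAtomWithIdx(i) for i in ring]
        het = [a for a in atoms if a.GetAtomicNum() in _ONS]
        carb = [a for a in atoms if a.GetAtomicNum() == 6]
        if len(het) == 1 and len(carb) == 2:
            marked.update(a.GetIdx() for a in carb)

    return marked


def mark_atoms(mol: Molecule) -> MarkSet:
    """Full marking pass: heteroatom rule plus the four carbon rules, tagged."""
    rd = mol.rdmol
    reasons: dict[int, set[str]] = {}

    def add(idx: int, tag: str) -> None:
        reasons.setdefault(idx, set()).add(tag)

    for idx in mark_heteroatoms(mol):
        add(idx, TAG_HETEROATOM)

    for bond in rd.GetBonds():
        if bond.GetIsAromatic() or bond.GetBondType() not in _MULTI:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 6 and _is_het(b):
            add(a.GetIdx(), TAG_C_MULTIBOND_HET)
        if b.GetAtomicNum() == 6 and _is_het(a):
            add(b.GetIdx(), TAG_C_MULTIBOND_HET)
        if a.GetAtomicNum() == 6 and b.GetAtomicNum() == 6:
            add(a.GetIdx(), TAG_C_C_MULTIBOND)
            add(b.GetIdx(), TAG_C_C_MULTIBOND)

    for atom in rd.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if any(b.GetBondType() in _MULTI or b.GetIsAromatic() for b in atom.GetBonds()):
            continue
        n_ons = sum(
            1
            for nb in atom.GetNeighbors()
            if nb.GetAtomicNum() in _ONS
            and all(b.GetBondType() == Chem.BondType.SINGLE for b in nb.GetBonds())
        )
        if n_ons >= 2:
            add(atom.GetIdx(), TAG_ACETAL_C)

    for ring in rd.GetRingInfo().AtomRings():
        if len(ring) != 3:
            continue
        atoms = [rd.GetAtomWithIdx(i) for i in ring]
        if (
            sum(1 for a in atoms if a.GetAtomicNum() in _ONS) == 1
            and sum(1 for a in atoms if a.GetAtomicNum() == 6) == 2
        ):
            for a in atoms:
                add(a.GetIdx(), TAG_THREE_RING)

    return MarkSet(
        frozenset(reasons),
        {idx: frozenset(tags) for idx, tags in reasons.items()},
    )


def merge_marked(mol: Molecule, marks: MarkSet) -> list[frozenset[int]]:
    """Connected components of marked atoms under non-aromatic bonds.

    Aromatic bonds never merge two marked atoms, so aromatic ring
    heteroatoms stay singletons unless an aliphatic functionality reaches
    them through a non-aromatic bond. Components are returned sorted by
    their smallest atom index.
    """
    rd = mol.rdmol
    adj: dict[int, list[int]] = {i: [] for i in marks.marked}
    for bond in rd.GetBonds():
        if bond.GetIsAromatic():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in adj and j in adj:
            adj[i].append(j)
            adj[j].append(i)

    seen: set[int] = set()
    cores: list[frozenset[int]] = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        cores.append(frozenset(comp))
    return cores


def extract_groups(mol: Molecule) -> list[FunctionalGroup]:
    """Mark, merge and extract every functional group of a molecule.

    Attachments list each (core atom, adjacent carbon outside the core)
    pair with the carbon's aromatic/aliphatic type; implicit hydrogens on
    core atoms remain free valences of the group.
    """
    rd = mol.rdmol
    marks = mark_atoms(mol)
    groups: list[FunctionalGroup] = []
    for core in merge_marked(mol, marks):
        attachments: list[Attachment] = []
        for idx in sorted(core):
            for nb in rd.GetAtomWithIdx(idx).GetNeighbors():
                j = nb.GetIdx()
                if j in core or nb.GetAtomicNum() != 6:
                    continue
                ctype = "aromatic" if nb.GetIsAromatic() else "aliphatic"
                attachments.append(Attachment(idx, j, ctype))
        only = next(iter(core)) if len(core) == 1 else None
        lone_arom = (
            only is not None
            and rd.GetAtomWithIdx(only).GetIsAromatic()
            and _is_het(rd.GetAtomWithIdx(only))
        )
        groups.append(
            FunctionalGroup(mol, core, tuple(attachments), lone_arom)
        )
    return groups
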