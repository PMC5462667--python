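"""Reduction of extracted functional groups to generalized canonical forms.

A functional group extracted with its environment may occur in many
variants differing only in what sits at its attachment points (hydrogen,
aliphatic carbon, aromatic carbon). For frequency profiling those variants
are collapsed onto the chemically decisive core by a three-step scheme:

1. environment carbons on core *carbons* are deleted — except substituents
   on a carbonyl carbon, which survive to step 3 (this is what keeps
   aldehydes and ketones apart);
2. free valences on core *heteroatoms* are filled with placeholder R atoms
   (R stands for hydrogen or carbon) — except hydrogens of –OH groups and
   hydrogens on single-heteroatom N or S groups, which stay explicit
   (secondary vs tertiary amines, thiols vs sulfides);
3. the remaining environment carbons (on heteroatoms and on carbonyls)
   become R atoms — except on single-heteroatom N/O/S/halogen groups,
   where the carbon is retained with its aliphatic/aromatic type
   (alcohol vs phenol, amine vs aniline, alkyl vs aryl halide, the ether
   subtypes).

A lone aromatic ring heteroatom generalizes to its bare lowercase symbol.

The canonical string is a pseudo-SMILES: standard SMILES for core atoms,
``R`` for placeholders, bare ``C``/``c`` for retained typed environment
carbons, ``[H]`` for retained hydrogens. Canonicality comes from RDKit's
canonical ranking over a role-encoded graph (roles distinguished by
isotope-tagged dummy atoms), so equal FG graphs always serialize to equal
strings regardless of input atom order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from rdkit import Chem

from .perceive import FunctionalGroup

# node roles
CORE = "core"
ENV_ALIPHATIC = "env_aliphatic"
ENV_AROMATIC = "env_aromatic"
R_ATOM = "r"
HYDROGEN = "h"

_AROMATIC_SYMBOL = {7: "n", 8: "o", 16: "s"}

_BT = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}


@dataclass(frozen=True)
class FGNode:
    kind: str  # CORE / ENV_ALIPHATIC / ENV_AROMATIC / R_ATOM / HYDROGEN
    atomic_num: int = 0  # meaningful for CORE and HYDROGEN nodes
    aromatic: bool = False
    charge: int = 0


@dataclass(frozen=True)
class FGGraph:
    """Role-typed functional-group graph, the input of canonicalization."""

    nodes: tuple[FGNode, ...]
    bonds: tuple[tuple[int, int, str], ...]

    def neighbors(self, i: int) -> list[tuple[int, str]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out


@dataclass(frozen=True)
class GeneralizedFG:
    """The unit of counting: one generalized canonical form."""

    pseudo_smiles: str
    n_core_atoms: int
    n_r_atoms: int
    retains_carbon_types: bool
    is_lone_aromatic_het: bool = False


# ---------------------------------------------------------------------------
# graph construction


def build_full_graph(fg: FunctionalGroup) -> FGGraph:
    """Ungeneralized graph: core atoms, typed environment carbons, explicit
    hydrogens on heteroatoms. Hydrogens on carbons stay implicit."""
    rd = fg.parent.rdmol
    index: dict[int, int] = {}
    nodes: list[FGNode] = []
    bonds: list[tuple[int, int, str]] = []

    for idx in sorted(fg.core):
        atom = rd.GetAtomWithIdx(idx)
        index[idx] = len(nodes)
        nodes.append(
            FGNode(CORE, atom.GetAtomicNum(), atom.GetIsAromatic(), atom.GetFormalCharge())
        )

    for idx in sorted(fg.core):
        atom = rd.GetAtomWithIdx(idx)
        for bond in atom.GetBonds():
            other = bond.GetOtherAtom(atom)
            j = other.GetIdx()
            order = (
                "aromatic"
                if bond.GetBondType() == Chem.BondType.AROMATIC
                else bond.GetBondType().name.lower()
            )
            if j in fg.core:
                if idx < j:
                    bonds.append((index[idx], index[j], order))
            elif other.GetAtomicNum() == 6:
                kind = ENV_AROMATIC if other.GetIsAromatic() else ENV_ALIPHATIC
                k = len(nodes)
                nodes.append(FGNode(kind, 6, other.GetIsAromatic()))
                bonds.append((index[idx], k, order))
            else:
                # non-carbon outside the core (possible only across aromatic
                # bonds into another core); stands in as a placeholder
                k = len(nodes)
                nodes.append(FGNode(R_ATOM))
                bonds.append((index[idx], k, "single"))
        if atom.GetAtomicNum() != 6:
            for _ in range(atom.GetTotalNumHs()):
                k = len(nodes)
                nodes.append(FGNode(HYDROGEN, 1))
                bonds.append((index[idx], k, "single"))

    return FGGraph(tuple(nodes), tuple(bonds))


def _core_info(graph: FGGraph):
    core_idx = [i for i, n in enumerate(graph.nodes) if n.kind == CORE]
    carbonyl: set[int] = set()
    for a, b, order in graph.bonds:
        if order != "double":
            continue
        na, nb = graph.nodes[a], graph.nodes[b]
        if na.kind == CORE and nb.kind == CORE:
            if na.atomic_num == 6 and nb.atomic_num == 8:
                carbonyl.add(a)
            elif nb.atomic_num == 6 and na.atomic_num == 8:
                carbonyl.add(b)
    single_het = len(core_idx) == 1 and graph.nodes[core_idx[0]].atomic_num != 6
    return core_idx, carbonyl, single_het


def generalize_graph(graph: FGGraph) -> FGGraph:
    """Apply the three-step generalization to a role-typed FG graph.

    Idempotent: applying it to its own output is the identity.
    """
    core_idx, carbonyl, single_het = _core_info(graph)

    if single_het and graph.nodes[core_idx[0]].aromatic:
        # lone aromatic ring heteroatom: bare atom, environment dropped
        return FGGraph((graph.nodes[core_idx[0]],), ())

    keep: dict[int, FGNode] = {i: graph.nodes[i] for i in core_idx}
    new_bonds: list[tuple[int, int, str]] = []
    extra: list[tuple[int, FGNode, str]] = []  # (core node, new node, order)

    def only_single_bonds(i: int) -> bool:
        return all(order == "single" for _, order in graph.neighbors(i))

    for a, b, order in graph.bonds:
        na, nb = graph.nodes[a], graph.nodes[b]
        if na.kind == CORE and nb.kind == CORE:
            new_bonds.append((a, b, order))
            continue
        if nb.kind == CORE:  # orient: a = core, b = satellite
            a, b, na, nb = b, a, nb, na
        sat = nb
        if sat.kind == R_ATOM:
            extra.append((a, sat, "single"))
            continue
        if sat.kind == HYDROGEN:
            het = na.atomic_num
            if het == 8 and only_single_bonds(a):
                extra.append((a, sat, "single"))  # –OH kept
            elif single_het and het in (7, 16):
                extra.append((a, sat, "single"))  # simple amine / thiol
            else:
                extra.append((a, FGNode(R_ATOM), "single"))
            continue
        # environment carbon
        if na.atomic_num == 6:
            if a in carbonyl:
                extra.append((a, FGNode(R_ATOM), "single"))
            # else: deleted; the freed valence becomes an implicit hydrogen
        else:
            if single_het:
                extra.append((a, sat, order))  # typed carbon retained
            else:
                extra.append((a, FGNode(R_ATOM), "single"))

    remap = {old: new for new, old in enumerate(sorted(keep))}
    nodes = [graph.nodes[old] for old in sorted(keep)]
    bonds = [(remap[a], remap[b], order) for a, b, order in new_bonds]
    for core_old, node, order in extra:
        bonds.append((remap[core_old], len(nodes), order))
        nodes.append(node)
    return FGGraph(tuple(nodes), tuple(bonds))


# ---------------------------------------------------------------------------
# canonical serialization


def _lone_symbol(node: FGNode) -> str:
    sym = _AROMATIC_SYMBOL.get(node.atomic_num)
    if sym is None:
        sym = "[" + Chem.GetPeriodicTable().GetElementSymbol(node.atomic_num).lower() + "]"
    return sym


def canonical_pseudo_smiles(graph: FGGraph) -> str:
    """Deterministic canonical pseudo-SMILES of a role-typed FG graph."""
    if (
        len(graph.nodes) == 1
        and graph.nodes[0].kind == CORE
        and graph.nodes[0].aromatic
        and graph.nodes[0].atomic_num != 6
    ):
        return _lone_symbol(graph.nodes[0])

    rw = Chem.RWMol()
    for node in graph.nodes:
        if node.kind == CORE:
            atom = Chem.Atom(node.atomic_num)
            atom.SetIsAromatic(node.aromatic)
            atom.SetFormalCharge(node.charge)
            if node.atomic_num != 6:
                # heteroatom valences are fully spelled out by R/H satellites
                atom.SetNoImplicit(True)
        elif node.kind == HYDROGEN:
            atom = Chem.Atom(1)
        else:
            atom = Chem.Atom(0)  # dummy; isotope encodes the role
            atom.SetIsotope(
                {R_ATOM: 1, ENV_ALIPHATIC: 2, ENV_AROMATIC: 3}[node.kind]
            )
            if node.kind == ENV_AROMATIC:
                atom.SetIsAromatic(True)
        rw.AddAtom(atom)
    for a, b, order in graph.bonds:
        rw.AddBond(a, b, _BT[order])
        if order == "aromatic":
            rw.GetBondBetweenAtoms(a, b).SetIsAromatic(True)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    smi = Chem.MolToSmiles(mol)
    return smi.replace("[1*]", "R").replace("[2*]", "C").replace("[3*]", "c")


def render_smarts_ish(pseudo_smiles: str) -> str:
    """Exchange rendering: ``R`` placeholders become ``*`` so downstream
    SMARTS/SMILES tools can parse the string. ``R`` never occurs in any
    element symbol of the dialect, so plain substitution is safe."""
    return pseudo_smiles.replace("R", "*")


# ---------------------------------------------------------------------------
# top-level operations


def generalize(fg: FunctionalGroup) -> GeneralizedFG:
    """Reduce one extracted functional group to its generalized form."""
    if fg.is_lone_aromatic_het:
        rd = fg.parent.rdmol
        atom = rd.GetAtomWithIdx(next(iter(fg.core)))
        node = FGNode(CORE, atom.GetAtomicNum(), True, atom.GetFormalCharge())
        return GeneralizedFG(_lone_symbol(node), 1, 0, False, True)
    g = generalize_graph(build_full_graph(fg))
    pseudo = canonical_pseudo_smiles(g)
    n_core = sum(1 for n in g.nodes if n.kind == CORE)
    n_r = sum(1 for n in g.nodes if n.kind == R_ATOM)
    retained = any(n.kind in (ENV_ALIPHATIC, ENV_AROMATIC) for n in g.nodes)
    return GeneralizedFG(pseudo, n_core, n_r, retained)


def full_form(fg: FunctionalGroup) -> str:
    """Canonical pseudo-SMILES of the ungeneralized, full-environment form."""
    return canonical_pseudo_smiles(build_full_graph(fg))


# ---------------------------------------------------------------------------
# environment-variant combinatorics

#: an attachment point is hydrogen, an aliphatic carbon or an aromatic carbon
ATTACHMENT_VALUES = ("H", "C", "c")


def enumerate_environment_variants(
    n_points: int,
    symmetric_groups: Sequence[Sequence[int]] = (),
    interchangeable_blocks: Sequence[Sequence[int]] = (),
) -> list[tuple[str, ...]]:
    """All distinct environment variants of a generalized core.

    Each of ``n_points`` attachment points takes a value from
    :data:`ATTACHMENT_VALUES`. ``symmetric_groups`` lists groups of point
    indices that are mutually interchangeable (e.g. the two substituents on
    an amide nitrogen); ``interchangeable_blocks`` lists groups of
    *symmetric-group indices* whose blocks swap as wholes (e.g. the two
    NR2 halves of a urea). Returns the sorted canonical representatives of
    the equivalence classes; an empty point set yields one empty variant.
    """
    if n_points == 0:
        return [()]
    groups = [tuple(g) for g in symmetric_groups]
    seen: set[tuple[str, ...]] = set()
    for values in product(ATTACHMENT_VALUES, repeat=n_points):
        v = list(values)
        for g in groups:
            ordered = sorted(v[i] for i in g)
            for i, val in zip(g, ordered):
                v[i] = val
        for block in interchangeable_blocks:
            parts = sorted(tuple(v[i] for i in groups[b]) for b in block)
            for b, part in zip(block, parts):
                for i, val in zip(groups[b], part):
                    v[i] = val
        seen.add(tuple(v))
    return sorted(seen)


def amide_variant_count() -> int:
    """Variants of the amide group: one carbonyl attachment plus two
    interchangeable nitrogen attachments."""
    return len(enumerate_environment_variants(3, symmetric_groups=[(1, 2)]))
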