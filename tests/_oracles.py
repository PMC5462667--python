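"""Independent oracles used by the test suite.

The marking oracle re-states each marking rule as a SMARTS query plus a
naive per-atom scan, with no shared state with the implementation (which
walks bonds procedurally). The variant-count oracle enumerates the full
permutation group and counts orbits by brute force.
"""

from itertools import permutations, product

from rdkit import Chem

# rule 1: any atom that is not carbon and not hydrogen
_HETERO = Chem.MolFromSmarts("[!#6;!#1]")
# rule 2a: carbon with a (non-aromatic) double or triple bond to a heteroatom;
# SMARTS '=' and '#' never match aromatic bonds
_C_MULTI_HET = Chem.MolFromSmarts("[#6;$([#6]=[!#6;!#1]),$([#6]#[!#6;!#1])]")
# rule 2b: carbons of a non-aromatic C=C or C#C
_C_C_MULTI = Chem.MolFromSmarts("[#6;$([#6]=[#6]),$([#6]#[#6])]")
# rule 2c: aliphatic sp3 carbon with two O/N/S neighbors that carry only
# single bonds (no double, triple or aromatic bond)
_ONS_SINGLE = "[$([#8;!a;!$(*=*);!$(*#*)]),$([#7;!a;!$(*=*);!$(*#*)]),$([#16;!a;!$(*=*);!$(*#*)])]"
_ACETAL = Chem.MolFromSmarts(f"[C;!$(C=*);!$(C#*)]({_ONS_SINGLE}){_ONS_SINGLE}")
# rule 2d: carbons of a three-membered ring with exactly one O/N/S
_THREE_RING = Chem.MolFromSmarts("[C;r3]1[C;r3][#8,#7,#16;r3]1")


def oracle_marked_atoms(rdmol: Chem.Mol) -> set[int]:
    """Marked-atom set recomputed rule by rule via SMARTS matching."""
    marked: set[int] = set()
    for (i,) in rdmol.GetSubstructMatches(_HETERO):
        marked.add(i)
    for (i,) in rdmol.GetSubstructMatches(_C_MULTI_HET):
        marked.add(i)
    for (i,) in rdmol.GetSubstructMatches(_C_C_MULTI):
        marked.add(i)
    for match in rdmol.GetSubstructMatches(_ACETAL):
        marked.add(match[0])
    for match in rdmol.GetSubstructMatches(_THREE_RING, uniquify=False):
        marked.add(match[0])
        marked.add(match[1])
    return marked


def _group_permutations(n_points, symmetric_groups, interchangeable_blocks):
    """All permutations of the attachment points generated by the declared
    symmetry, built by closure over the generator set."""
    identity = tuple(range(n_points))
    perms = {identity}
    generators = []
    for group in symmetric_groups:
        group = tuple(group)
        for perm in permutations(group):
            p = list(identity)
            for src, dst in zip(group, perm):
                p[src] = dst
            generators.append(tuple(p))
    for block in interchangeable_blocks:
        blocks = [tuple(symmetric_groups[b]) for b in block]
        for perm in permutations(range(len(blocks))):
            p = list(identity)
            for bi, bj in enumerate(perm):
                for src, dst in zip(blocks[bi], blocks[bj]):
                    p[src] = dst
            generators.append(tuple(p))
    frontier = set(generators)
    while frontier:
        new = set()
        for g in frontier:
            for p in perms | frontier:
                comp = tuple(p[g[i]] for i in range(n_points))
                if comp not in perms and comp not in frontier:
                    new.add(comp)
        perms |= frontier
        frontier = new
    return perms


def oracle_variant_count(n_points, symmetric_groups=(), interchangeable_blocks=()):
    """Orbit count of {H, C, c}^n under the symmetry group, by brute force."""
    perms = _group_permutations(n_points, symmetric_groups, interchangeable_blocks)
    seen = set()
    n_orbits = 0
    for values in product("HCc", repeat=n_points):
        if values in seen:
            continue
        n_orbits += 1
        for p in perms:
            seen.add(tuple(values[p[i]] for i in range(n_points)))
    return n_orbits
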