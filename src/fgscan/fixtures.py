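"""Built-in fixture panel and a deterministic random-molecule generator.

The panel is a set of small, hand-worked molecules whose expected cores,
attachment shells and generalized forms were derived by manual
application of the perception rules; it is stored as annotated
TSV data (``data/panel.tsv``) so it doubles as a worked rule-by-rule
reference. The random generator assembles molecules from a fragment
grammar that spans every marking rule (heteroatoms, multiple bonds,
acetal centers, three-membered heterocycles, aromatic heterocycles) and
guarantees that every output parses and standardizes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from rdkit import Chem

from .molio import Molecule, standardize_smiles


@dataclass(frozen=True)
class CoreExpectation:
    """Hand-derived description of one expected FG core."""

    n_atoms: int
    tags: frozenset[str]
    n_aliphatic: int  # aliphatic environment carbons
    n_aromatic: int  # aromatic environment carbons

    def key(self) -> tuple:
        return (self.n_atoms, tuple(sorted(self.tags)), self.n_aliphatic, self.n_aromatic)


@dataclass(frozen=True)
class FixtureCase:
    name: str
    smiles: str
    expected_cores: tuple[CoreExpectation, ...]
    expected_generalized: tuple[str, ...]
    comment: str

    @property
    def rule_coverage(self) -> frozenset[str]:
        out: set[str] = set()
        for core in self.expected_cores:
            out |= core.tags
        return frozenset(out)


def _parse_cores(field: str) -> tuple[CoreExpectation, ...]:
    if not field:
        return ()
    cores = []
    for part in field.split(";"):
        n, tags, na, nar = part.split("|")
        cores.append(
            CoreExpectation(int(n), frozenset(tags.split("+")), int(na), int(nar))
        )
    return tuple(cores)


def builtin_panel() -> tuple[FixtureCase, ...]:
    """The hand-verified fixture panel (one case per row of the data TSV)."""
    text = (
        resources.files("fgscan").joinpath("data/panel.tsv").read_text(encoding="utf-8")
    )
    cases = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, smiles, cores, gen, comment = line.split("\t")
        expected = tuple(g for g in gen.split(";") if g)
        cases.append(FixtureCase(name, smiles, _parse_cores(cores), expected, comment))
    return tuple(cases)


def panel_smiles_file(path) -> None:
    """Write the panel as a SMILES input file (``SMILES<TAB>name``)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for case in builtin_panel():
            fh.write(f"{case.smiles}\t{case.name}\n")


# ---------------------------------------------------------------------------
# random molecule generator

# linear fragment grammar; ring-bearing units use ring number 1 only and are
# renumbered on assembly
_START = ["C", "CC", "CCC", "C(C)C", "C(=O)", "O", "N", "c1ccccc1", "c1ccncc1", "C=C"]
_CHAIN = [
    "C",
    "CC",
    "C(C)C",
    "O",
    "N",
    "S",
    "C(=O)",
    "C(=O)N",
    "C(=O)O",
    "NC(=O)",
    "C=C",
    "C#C",
    "S(=O)(=O)",
    "c1ccccc1",
    "c1ccncc1",
    "c1ccsc1",
    "c1cc[nH]c1",
    "C1CCCC1",
]
_TERMINAL = [
    "C",
    "Cl",
    "F",
    "Br",
    "I",
    "O",
    "N",
    "S",
    "C#N",
    "C(=O)O",
    "C(N)=O",
    "C=C",
    "S(N)(=O)=O",
    "[N+](=O)[O-]",
    "C1CO1",
    "C1CN1",
    "C1CS1",
    "C(OC)OC",
    "N(C)C",
    "OC",
    "c1ccccc1",
    "c1ccncc1",
]

_RING_DIGITS = "123456789"


def _renumber(unit: str, digit: str) -> str:
    return unit.replace("1", digit)


def random_molecules(n: int, seed: int, max_heavy_atoms: int = 24) -> list[str]:
    """``n`` deterministic random small-molecule SMILES for a fixed seed.

    Candidates are assembled from the fragment grammar and kept only if
    RDKit parses them and standardization succeeds within the heavy-atom
    budget, so every returned SMILES feeds the perception pipeline.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    out: list[str] = []
    while len(out) < n:
        n_units = rng.randint(1, 4)
        parts: list[str] = []
        ring = 0
        for k in range(n_units):
            if k == 0:
                unit = rng.choice(_START)
            elif k == n_units - 1:
                unit = rng.choice(_TERMINAL)
            else:
                unit = rng.choice(_CHAIN)
            if "1" in unit:
                if ring >= len(_RING_DIGITS):
                    break
                unit = _renumber(unit, _RING_DIGITS[ring])
                ring += 1
            parts.append(unit)
        smiles = "".join(parts)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetNumAtoms() > max_heavy_atoms:
            continue
        if not isinstance(standardize_smiles(smiles), Molecule):
            continue
        out.append(Chem.MolToSmiles(mol))
    return out
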