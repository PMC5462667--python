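"""Molecule input, standardization and tabular output.

Molecules enter as SMILES (one per line, optional whitespace-separated
identifier) or SDF (V2000) and are standardized before perception:

* the largest covalent fragment is kept (counterion / salt stripping),
* records whose kept fragment contains any metal or metalloid outside the
  common organic element subset are rejected as ``organometallic``,
* atomic charges are neutralized where chemically possible (charge-parent
  convention: protonate anionic N/O/S, deprotonate protonated amines),
* aromaticity is perceived by RDKit's default model.

The standardized molecule is exposed as an immutable :class:`Molecule`
wrapping the sanitized RDKit mol.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

#: Elements allowed in a standardized molecule. Everything else (alkali and
#: alkaline-earth metals, transition metals, lanthanides, metalloid metals,
#: ...) marks the record as organometallic. Noble gases are tolerated so the
#: check is purely a metal screen.
ORGANIC_ELEMENTS = frozenset(
    {1, 2, 5, 6, 7, 8, 9, 10, 14, 15, 16, 17, 18, 34, 35, 36, 53, 54, 86}
)

_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class RawRecord:
    """One input entry, prior to standardization."""

    identifier: str
    smiles_or_block: str
    source_line: int
    is_sdf: bool = False
    parse_failed: bool = False


@dataclass(frozen=True)
class AtomView:
    element: str
    is_aromatic: bool
    formal_charge: int
    implicit_h: int
    index: int


@dataclass(frozen=True)
class BondView:
    i: int
    j: int
    order: str
    is_aromatic: bool


class Molecule:
    """Immutable standardized molecular graph.

    Thin wrapper around a sanitized RDKit mol; hydrogens stay implicit and
    are never part of the perceived graph.
    """

    __slots__ = ("_rdmol", "_smiles")

    def __init__(self, rdmol: Chem.Mol):
        self._rdmol = rdmol
        self._smiles = Chem.MolToSmiles(rdmol)

    @property
    def rdmol(self) -> Chem.Mol:
        return self._rdmol

    @property
    def atoms(self) -> tuple[AtomView, ...]:
        return tuple(
            AtomView(
                a.GetSymbol(),
                a.GetIsAromatic(),
                a.GetFormalCharge(),
                a.GetTotalNumHs(),
                a.GetIdx(),
            )
            for a in self._rdmol.GetAtoms()
        )

    @property
    def bonds(self) -> tuple[BondView, ...]:
        return tuple(
            BondView(
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                _BOND_ORDER[b.GetBondType()],
                b.GetIsAromatic(),
            )
            for b in self._rdmol.GetBonds()
        )

    def num_atoms(self) -> int:
        return self._rdmol.GetNumAtoms()

    def to_smiles(self) -> str:
        return self._smiles

    def __repr__(self) -> str:  # pragma: no cover
        return f"Molecule({self._smiles!r})"


@dataclass(frozen=True)
class Rejection:
    identifier: str
    reason: str


StandardizeResult = Union[Molecule, Rejection]


# ---------------------------------------------------------------------------
# reading


def _smiles_records(path: Path) -> Iterator[RawRecord]:
    with open(path, "r", encoding="utf-8") as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            n += 1
            parts = line.split(None, 1)
            smiles = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"mol{n}"
            ok = Chem.MolFromSmiles(smiles, sanitize=False) is not None
            yield RawRecord(ident, smiles, lineno, parse_failed=not ok)


def _sdf_records(path: Path) -> Iterator[RawRecord]:
    # line-accurate streaming split on the V2000 "$$$$" delimiter
    with open(path, "r", encoding="utf-8") as fh:
        block: list[str] = []
        start = 1
        n = 0
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "$$$$":
                n += 1
                text = "".join(block)
                name = block[0].strip() if block else ""
                ident = name or f"mol{n}"
                ok = Chem.MolFromMolBlock(text, sanitize=False) is not None
                yield RawRecord(ident, text, start, is_sdf=True, parse_failed=not ok)
                block = []
                start = lineno + 1
            else:
                block.append(line)
        if any(l.strip() for l in block):
            n += 1
            text = "".join(block)
            ident = (block[0].strip() or f"mol{n}") if block else f"mol{n}"
            ok = Chem.MolFromMolBlock(text, sanitize=False) is not None
            yield RawRecord(ident, text, start, is_sdf=True, parse_failed=not ok)


def read_molecules(path: str | Path, format: str = "smiles") -> Iterator[RawRecord]:
    """Stream :class:`RawRecord` entries from a SMILES or SDF file.

    Malformed entries are yielded with ``parse_failed=True`` rather than
    dropped; an empty file yields an empty stream. Identifiers missing from
    the input are auto-generated as ``mol<ordinal>``.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read molecule file: {path}")
    if format not in ("smiles", "sdf"):
        raise ValueError(f"unknown format: {format!r}")
    return _sdf_records(path) if format == "sdf" else _smiles_records(path)


# ---------------------------------------------------------------------------
# standardization


def _parse(record: RawRecord) -> Chem.Mol | None:
    if record.is_sdf:
        return Chem.MolFromMolBlock(record.smiles_or_block, sanitize=True)
    return Chem.MolFromSmiles(record.smiles_or_block, sanitize=True)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]

    def key(f: Chem.Mol) -> tuple:
        heavy = sum(1 for a in f.GetAtoms() if a.GetAtomicNum() > 1)
        # larger first; final lexicographic tie-break on canonical SMILES
        # (reverse-sorted string via negative ordinal trick is overkill —
        # sort twice instead)
        return (heavy, Descriptors.MolWt(f))

    best = sorted(frags, key=lambda f: (-key(f)[0], -key(f)[1], Chem.MolToSmiles(f)))
    return best[0]


def _contains_metal(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() not in ORGANIC_ELEMENTS for a in mol.GetAtoms())


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Charge-parent neutralization, in place on an editable copy.

    Anionic N/O/S gain a proton unless a positively charged neighbor
    compensates the charge internally (nitro, N-oxide, azide stay intact);
    protonated nitrogens with at least one hydrogen lose one. Charges that
    cannot be neutralized without breaking valence are left in place.
    """
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        q = atom.GetFormalCharge()
        if q < 0 and atom.GetAtomicNum() in (7, 8, 16):
            if any(n.GetFormalCharge() > 0 for n in atom.GetNeighbors()):
                continue
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + (-q))
            atom.SetNoImplicit(True)
            atom.SetFormalCharge(0)
        elif q > 0 and atom.GetAtomicNum() == 7 and atom.GetTotalNumHs() >= q:
            atom.SetNumExplicitHs(atom.GetTotalNumHs() - q)
            atom.SetNoImplicit(True)
            atom.SetFormalCharge(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def standardize(record: RawRecord) -> StandardizeResult:
    """Standardize one record or reject it.

    Returns a :class:`Molecule` with the largest fragment kept, charges
    neutralized where possible and default aromaticity perceived, or a
    :class:`Rejection` with reason ``unparseable`` or ``organometallic``.
    """
    if record.parse_failed:
        return Rejection(record.identifier, "unparseable")
    mol = _parse(record)
    if mol is None or mol.GetNumAtoms() == 0:
        return Rejection(record.identifier, "unparseable")
    mol = _largest_fragment(mol)
    if _contains_metal(mol):
        return Rejection(record.identifier, "organometallic")
    try:
        mol = _neutralize(mol)
    except Exception:
        return Rejection(record.identifier, "unparseable")
    return Molecule(mol)


def standardize_smiles(smiles: str, identifier: str = "mol") -> StandardizeResult:
    """Convenience: standardize a single SMILES string."""
    ok = Chem.MolFromSmiles(smiles, sanitize=False) is not None
    return standardize(RawRecord(identifier, smiles, 1, parse_failed=not ok))


# ---------------------------------------------------------------------------
# writing


def write_fg_table(
    rows: Iterable[tuple[str, Sequence[str]]],
    path: str | Path,
) -> None:
    """Write the per-molecule FG table as TSV.

    One row per molecule–FG pair, FG strings in canonical sort order; a
    molecule with zero FGs gets a single row with an empty FG field. Output
    bytes are a pure function of the input.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("molecule_id\tfg_pseudo_smiles\n")
        for ident, fgs in rows:
            if not fgs:
                fh.write(f"{ident}\t\n")
                continue
            for fg in sorted(fgs):
                fh.write(f"{ident}\t{fg}\n")


def write_rejection_log(rejections: Iterable[Rejection], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("molecule_id\treason\n")
        for rej in rejections:
            fh.write(f"{rej.identifier}\t{rej.reason}\n")
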