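"""Input, standardization and table-writing behavior."""

import pytest
from rdkit import Chem

from fgscan import (
    Molecule,
    Rejection,
    read_molecules,
    standardize,
    standardize_smiles,
    write_fg_table,
)
from fgscan.molio import RawRecord, write_rejection_log


def _smiles_of(result):
    assert isinstance(result, Molecule), result
    return result.to_smiles()


class TestReadMolecules:
    def test_smiles_file_with_identifiers(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("CCO\tmol1\nCC=O\tmol2\n")
        records = list(read_molecules(p))
        assert [(r.identifier, r.smiles_or_block) for r in records] == [
            ("mol1", "CCO"),
            ("mol2", "CC=O"),
        ]
        assert not any(r.parse_failed for r in records)

    def test_missing_identifier_autogenerated(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("CCO\n\nCCN\n")
        records = list(read_molecules(p))
        assert [r.identifier for r in records] == ["mol1", "mol2"]
        assert [r.source_line for r in records] == [1, 3]

    def test_malformed_line_flagged_not_dropped(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("not_a_smiles(\tbad\nCCO\tok\n")
        records = list(read_molecules(p))
        assert len(records) == 2
        assert records[0].parse_failed and not records[1].parse_failed
        rej = standardize(records[0])
        assert isinstance(rej, Rejection) and rej.reason == "unparseable"

    def test_empty_file_empty_stream(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("")
        assert list(read_molecules(p)) == []

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_molecules(tmp_path / "nope.smi")

    def test_sdf_roundtrip(self, tmp_path):
        block = Chem.MolToMolBlock(Chem.MolFromSmiles("CC(=O)O"))
        p = tmp_path / "in.sdf"
        p.write_text("acetic\n" + block.split("\n", 1)[1] + "$$$$\n")
        records = list(read_molecules(p, format="sdf"))
        assert len(records) == 1 and not records[0].parse_failed
        assert _smiles_of(standardize(records[0])) == "CC(=O)O"


class TestStandardize:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("CCO", "CCO"),  # identity
            ("CC(=O)[O-].[Na+]", "CC(=O)O"),  # salt strip + neutralize
            ("CC[NH3+].[Cl-]", "CCN"),  # ammonium -> amine
            ("C[N+](C)(C)C", "C[N+](C)(C)C"),  # quaternary N: no H to remove
            ("O=[N+]([O-])c1ccccc1", "O=[N+]([O-])c1ccccc1"),  # nitro intact
            ("CS([O-])(=O)=O", "CS(=O)(=O)O"),  # sulfonate -> acid
        ],
    )
    def test_neutralization_and_salt_stripping(self, smiles, expected):
        assert _smiles_of(standardize_smiles(smiles)) == Chem.CanonSmiles(expected)

    @pytest.mark.parametrize("smiles", ["CC[Pb](CC)(CC)CC", "CC(=O)O[Na]", "c1ccccc1[Mg]Br"])
    def test_organometallic_rejected(self, smiles):
        result = standardize_smiles(smiles)
        assert isinstance(result, Rejection) and result.reason == "organometallic"

    def test_metal_counterion_is_not_organometallic(self):
        # the metal sits in the discarded fragment, the parent is organic
        assert isinstance(standardize_smiles("CC(=O)[O-].[Na+]"), Molecule)

    def test_largest_fragment_tiebreak_by_weight(self):
        # CCO (46.07) vs CCN (45.08): equal heavy atoms, oxygen wins on mass
        for smiles in ("CCO.CCN", "CCN.OCC"):
            assert _smiles_of(standardize_smiles(smiles)) == "CCO"

    def test_idempotent(self, corpus200):
        for smiles in corpus200[:50]:
            once = standardize_smiles(smiles)
            again = standardize_smiles(once.to_smiles())
            assert again.to_smiles() == once.to_smiles()

    def test_roundtrip_through_smiles(self, corpus200):
        for smiles in corpus200[:50]:
            mol = standardize_smiles(smiles)
            assert standardize_smiles(mol.to_smiles()).to_smiles() == mol.to_smiles()

    def test_molecule_views(self):
        mol = standardize_smiles("CC=O")
        assert [a.element for a in mol.atoms] == ["C", "C", "O"]
        orders = sorted(b.order for b in mol.bonds)
        assert orders == ["double", "single"]


class TestWriteFgTable:
    def test_rows_and_empty_case(self, tmp_path):
        p = tmp_path / "out.tsv"
        write_fg_table([("m1", ["RC(=O)N(R)R"]), ("m2", [])], p)
        lines = p.read_text().splitlines()
        assert lines == [
            "molecule_id\tfg_pseudo_smiles",
            "m1\tRC(=O)N(R)R",
            "m2\t",
        ]

    def test_deterministic_bytes(self, tmp_path):
        rows = [("m1", ["b", "a"]), ("m2", ["c"])]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_fg_table(rows, p1)
        write_fg_table(rows, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert "m1\ta" in p1.read_text()  # canonical sort order

    def test_rejection_log(self, tmp_path):
        p = tmp_path / "rej.tsv"
        write_rejection_log([Rejection("m9", "organometallic")], p)
        assert p.read_text().splitlines()[1] == "m9\torganometallic"
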