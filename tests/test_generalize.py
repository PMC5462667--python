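"""Generalization scheme, canonical pseudo-SMILES and variant combinatorics."""

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from fgscan import (
    build_full_graph,
    canonical_pseudo_smiles,
    enumerate_environment_variants,
    extract_groups,
    full_form,
    generalize,
    generalize_graph,
    render_smarts_ish,
    standardize_smiles,
)
from _oracles import oracle_variant_count


def _forms(smiles):
    mol = standardize_smiles(smiles)
    return sorted(g.pseudo_smiles for g in map(generalize, extract_groups(mol)))


NAMED_DISTINCTIONS = [
    ("alcohol/phenol", "CCO", "Oc1ccccc1"),
    ("amine/aniline", "CN", "Nc1ccccc1"),
    ("aldehyde/ketone", "CC=O", "CC(C)=O"),
    ("sec/tert amine", "CNC", "CN(C)C"),
    ("thiol/sulfide", "CS", "CSC"),
    ("alkyl/aryl chloride", "CCCl", "Clc1ccccc1"),
]


class TestGeneralize:
    @pytest.mark.parametrize("name, a, b", NAMED_DISTINCTIONS)
    def test_named_distinctions_map_to_distinct_forms(self, name, a, b):
        fa, fb = _forms(a), _forms(b)
        assert len(fa) == len(fb) == 1
        assert fa != fb, name

    def test_all_amide_substitutions_collapse_to_one_form(self):
        forms = {_forms(s)[0] for s in ("CC(N)=O", "CC(=O)NC", "CC(=O)N(C)C")}
        assert forms == {"RC(=O)N(R)R"}

    def test_lone_aromatic_heteroatom_is_bare_symbol(self):
        for smiles, symbol in [("c1ccncc1", "n"), ("c1ccoc1", "o"), ("c1ccsc1", "s")]:
            (g,) = [generalize(fg) for fg in extract_groups(standardize_smiles(smiles))]
            assert g.pseudo_smiles == symbol and g.is_lone_aromatic_het

    def test_r_count_matches_string(self, panel):
        for case in panel:
            for fg in extract_groups(standardize_smiles(case.smiles)):
                g = generalize(fg)
                assert g.pseudo_smiles.count("R") == g.n_r_atoms, case.name

    def test_idempotent_on_generalized_graphs(self, panel):
        for case in panel:
            for fg in extract_groups(standardize_smiles(case.smiles)):
                if fg.is_lone_aromatic_het:
                    continue
                once = generalize_graph(build_full_graph(fg))
                twice = generalize_graph(once)
                assert canonical_pseudo_smiles(twice) == canonical_pseudo_smiles(once)

    def test_full_forms_refine_generalized_forms(self):
        # the substituted ureas collapse onto one generalized form but keep
        # distinct full-environment forms
        ureas = ["NC(N)=O", "CNC(N)=O", "CNC(=O)NC", "CNC(=O)N(C)C", "CN(C)C(=O)N(C)C", "NC(=O)Nc1ccccc1"]
        gen = {_forms(s)[0] for s in ureas}
        full = set()
        for s in ureas:
            (fg,) = extract_groups(standardize_smiles(s))
            full.add(full_form(fg))
        assert len(gen) == 1
        assert len(full) == len(ureas)


class TestCanonicalization:
    def test_canonical_across_random_atom_orders(self):
        mol = standardize_smiles("CC(=O)Nc1ccc(O)cc1").rdmol
        variants = Chem.MolToRandomSmilesVect(mol, 10, randomSeed=7)
        results = set()
        for smi in variants:
            results.add(tuple(_forms(smi)))
        assert len(results) == 1

    def test_smallest_alcohol_form(self):
        (fg,) = extract_groups(standardize_smiles("CO"))
        assert generalize(fg).pseudo_smiles == "CO[H]"

    def test_acylhydrazone_connectivity(self):
        (fg,) = extract_groups(standardize_smiles("CC(=O)NN=CC"))
        assert generalize(fg).pseudo_smiles == "RC(=O)N(R)N=C"

    def test_smarts_ish_rendering_parses(self):
        for pseudo in ("RC(=O)N(R)R", "CBr", "cO[H]"):
            rendered = render_smarts_ish(pseudo)
            assert "R" not in rendered
            assert Chem.MolFromSmarts(rendered) is not None


class TestVariantEnumeration:
    def test_amide_has_18_variants(self):
        variants = enumerate_environment_variants(3, symmetric_groups=[(1, 2)])
        assert len(variants) == 18

    def test_single_point_has_3_variants(self):
        assert len(enumerate_environment_variants(1)) == 3

    def test_urea_has_21_variants(self):
        variants = enumerate_environment_variants(
            4, symmetric_groups=[(0, 1), (2, 3)], interchangeable_blocks=[(0, 1)]
        )
        assert len(variants) == 21
        assert len(variants) == oracle_variant_count(4, [(0, 1), (2, 3)], [(0, 1)])

    def test_empty_attachment_set(self):
        assert enumerate_environment_variants(0) == [()]

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(data=st.data())
    def test_orbit_counts_match_brute_force(self, data):
        n = data.draw(st.integers(min_value=1, max_value=5))
        points = list(range(n))
        groups = []
        i = 0
        while i < n:
            size = data.draw(st.integers(min_value=1, max_value=n - i))
            if size > 1:
                groups.append(tuple(points[i : i + size]))
            i += size
        blocks = []
        sizes = {}
        for gi, g in enumerate(groups):
            sizes.setdefault(len(g), []).append(gi)
        for same in sizes.values():
            if len(same) > 1 and data.draw(st.booleans()):
                blocks.append(tuple(same))
        got = len(enumerate_environment_variants(n, groups, blocks))
        expected = oracle_variant_count(n, groups, blocks)
        assert got == expected
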