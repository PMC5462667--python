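# fgscan

Automatic functional-group perception for organic molecules — no pattern
library required.

Classical FG detectors match molecules against a hand-curated list of a
few hundred substructures, so anything outside the list is invisible. `fgscan` instead *derives* every functional group from
the molecular graph itself: heteroatoms and activated carbons are marked by
a handful of structural rules, connected marked atoms are merged into
cores, and each core is extracted together with its first-shell carbon
environment. The groups are then reduced to generalized canonical forms —
pseudo-SMILES with `R` placeholder atoms — that serve as counting keys for
profiling compound collections (screening libraries, vendor catalogs,
bioactivity databases). Typical users are medicinal and computational
chemists comparing the functionality content of molecule sets.

## The algorithm

**Perception.** For a standardized molecule (largest fragment kept, charges
neutralized where chemically possible, organometallics rejected):

1. mark every heteroatom (any atom that is not C or H, halogens included);
2. mark carbons that are
   - double/triple-bonded to a heteroatom through a non-aromatic bond
     (carbonyl, imine, nitrile, ...),
   - part of a non-aromatic C=C or C#C,
   - acetal-type sp3 carbons: ≥ 2 neighbors from {O, N, S}, each of which
     has only single bonds (acetals, ketals, aminals, thioacetals),
   - members of a three-membered oxirane/aziridine/thiirane ring;
3. merge marked atoms connected by non-aromatic bonds into one group.
   Aromatic ring heteroatoms are collected as lone single-atom groups —
   they belong to their heterocycle, not to a classical FG — unless an
   aliphatic functionality reaches them through a non-aromatic bond
   (an acyl group on a pyrrole nitrogen merges with it);
4. record the unmarked carbons bonded to each core as its *environment*,
   typed aliphatic (`C`) or aromatic (`c`).

**Generalization.** Environment detail is collapsed onto the chemically
decisive core: environment carbons on core carbons are deleted (except on a
carbonyl carbon, so aldehydes ≠ ketones), free valences on heteroatoms are
filled with `R` atoms (except –OH hydrogens, and hydrogens of simple amines
and thiols, so secondary ≠ tertiary amines and thiols ≠ sulfides), and
remaining environment carbons become `R` — except on single-heteroatom
N/O/S/halogen groups, where the carbon is kept with its type (alcohol
`CO[H]` ≠ phenol `cO[H]`, amine ≠ aniline, alkyl ≠ aryl chloride, the ether
subtypes). The resulting canonical pseudo-SMILES — `RC(=O)N(R)R` for the
amide, `RN(R)C(=O)N(R)R` for the urea, `C=CC(=O)N(R)R` for acrylamide — is
the unit of counting. Counting is per-molecule presence: a molecule holding
two esters counts once for the ester row.

Aromaticity follows RDKit's default perception model; FG assignments on
borderline rings (e.g. oxo-arenes such as 2-pyridone or the caffeine
carbonyls) depend on that model, which is why it is surfaced here rather
than hidden.

## Worked example

```bash
$ cat demo.smi
CC(=O)Nc1ccc(O)cc1	paracetamol
CC(=O)Oc1ccccc1C(=O)O	aspirin
CN1C=NC2=C1C(=O)N(C)C(=O)N2C	caffeine

$ fgfind -i demo.smi -o demo_fgs.tsv
fgfind: read=3 standardized=3 rejected=0
$ cat demo_fgs.tsv
molecule_id	fg_pseudo_smiles
paracetamol	RC(=O)N(R)R
paracetamol	cO[H]
aspirin	RC(=O)O[H]
aspirin	ROC(R)=O
caffeine	Rc(R)=O
caffeine	Rc(R)=O
```

Paracetamol carries an amide (`RC(=O)N(R)R`; the `R`s absorb the methyl
and the ring attachment) and a phenol (`cO[H]` — the aromatic environment
carbon is retained, so it cannot be confused with an alcohol). Aspirin
splits into a carboxylic acid and an ester; caffeine's two carbonyls sit on
aromatic ring carbons and appear as the oxo-arene form `Rc(R)=O`, while its
aromatic ring nitrogens are lone-heteroatom groups that stay out of the
table by default (`--include-aromatic-het` keeps them).

```bash
$ fgstats -i demo_fgs.tsv -o demo_table.tsv
fgstats: molecules=3 unique_fgs=5
$ cat demo_table.tsv
fg	n_molecules	percent
RC(=O)N(R)R	1	33.3333
RC(=O)O[H]	1	33.3333
ROC(R)=O	1	33.3333
Rc(R)=O	1	33.3333
cO[H]	1	33.3333
```

Each group occurs in 1 of the 3 molecules (33.3%); note caffeine's
duplicated carbonyl still counts once. A JSON summary with singleton and
threshold statistics lands next to the table. The same pipeline is one call
in Python:

```python
>>> from fgscan import find_functional_groups
>>> for g in find_functional_groups("CC(=O)Nc1ccc(O)cc1"):
...     print(g.pseudo_smiles, g.n_core_atoms, g.n_r_atoms)
RC(=O)N(R)R 3 3
cO[H] 1 0
```

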