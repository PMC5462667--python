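# Methods

## Scope and model

`fgscan` perceives functional groups (FGs) directly from the molecular
graph instead of matching a curated substructure list. The underlying
model is that nearly all FGs are organized around heteroatoms and a small
set of activated carbons; everything else (plain rings, alkyl skeletons)
is scaffold. A group is therefore *defined* as a connected component of
marked atoms, and the first shell of unmarked carbons around it is kept as
typed context. This makes the method total — every molecule decomposes
into groups without exceptions — at the price that "functional group" is
what the rules say it is, not what any particular chemist might say.

## Standardization (`molio`)

- **Fragment selection.** Only the largest covalent fragment is kept,
  measured by heavy-atom count; ties break by molecular weight, then by
  lexicographic canonical SMILES, so the choice is deterministic under
  atom reordering. Whether equal-size salt partners should instead be
  dropped entirely is a judgment call; keeping one fragment keeps the
  record usable.
- **Organometallic rejection.** Applied to the kept fragment: any element
  outside {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} ∪ noble gases
  rejects the record. Metal *counterions* therefore do not reject a salt;
  metals bonded into the parent fragment do.
- **Neutralization.** Charge-parent convention: anionic N/O/S are
  protonated and protonated nitrogens with an available hydrogen are
  deprotonated. An anion adjacent to a positively charged atom is left
  alone so that internally compensated groups (nitro, N-oxide, azide)
  survive intact — protonating them would strand the cation charge.
  Charges that cannot be removed without breaking valence (quaternary
  ammonium) stay. Standardization is idempotent.
- **Aromaticity.** RDKit's default perception. This is a genuine model
  choice with visible consequences: 2-pyridone-like rings come out
  aromatic, so their carbonyls are perceived as oxo-arene groups
  (`Rc(R)=O`) and their ring NH as a lone aromatic heteroatom. A toolkit
  with a different aromaticity model will shift counts between such
  neighboring categories (e.g. oxo-arene vs lactam); that sensitivity is
  inherent to any FG scheme that distinguishes aromatic from aliphatic
  carbon.

## Perception (`perceive`)

The marking rules and their operationalizations:

| rule | definition used |
| --- | --- |
| heteroatom | atomic number ∉ {1, 6} |
| C multi-bonded to heteroatom | bond type DOUBLE/TRIPLE, not aromatic |
| C=C / C#C carbon | same bond test, both ends carbon |
| acetal carbon | non-aromatic C with no double/triple bond ("sp3" without hybridization perception) and ≥ 2 O/N/S neighbors whose bonds are all single |
| three-membered heterocycle | ring of size 3 with exactly two carbons and one O/N/S; all three atoms tagged |

Merging joins marked atoms across every non-aromatic bond. Aromatic bonds
never merge — this reconciles "merge all connected marked atoms" with the
treatment of aromatic ring heteroatoms as single-atom groups, while still
letting an acyl group on a pyrrole nitrogen pull that nitrogen into a
larger group through the non-aromatic N–C bond. Adjacent ring heteroatoms
(pyridazine) consequently stay two singleton groups.

The environment is strictly first-shell: the unmarked carbons bonded to
core atoms, typed aliphatic/aromatic, never their further neighbors. A
carbon that is itself a marked member of another core (reachable only
across an aromatic bond, e.g. an oxo-arene ring carbon next to a lone
aromatic N) is still recorded as environment with its type; the two cores
remain disjoint.

Alternative, more aggressive definitions of activated carbons (carbons
alpha to a carbonyl or to S=O) are deliberately out of scope: they inflate
the group inventory with large rare groups and are better served by
dedicated reactivity filters.

## Generalization (`generalize`)

Steps, applied to the role-typed FG graph (core atoms / environment
carbons / hydrogens on heteroatoms):

1. environment carbons on core carbons are deleted (the freed valence
   becomes an implicit hydrogen); carbonyl substituents are exempted and
   survive to step 3 — this is exactly what separates `RC=O` (aldehyde)
   from `RC(R)=O` (ketone);
2. hydrogens on core heteroatoms become `R`, except –OH hydrogens (any
   core oxygen with only single bonds) and hydrogens on single-heteroatom
   N/S groups (simple amines, thiols);
3. remaining environment carbons become `R`, except on single-heteroatom
   N/O/S/halogen groups, where the carbon is retained with its
   aliphatic/aromatic type.

The step-3 exception is applied to *all* environment carbons of
single-heteroatom cores, not only singly-substituted N/O ones: this is
what yields separate dialkyl / alkyl-aryl / diaryl ether forms, the
secondary amine subtypes, and alkyl vs aryl halides, which a literal
one-carbon reading could not produce. Thiocarbonyl (C=S) substituents do
not get the carbonyl exemption — "carbonyl" is read as C=O. A lone
aromatic heteroatom generalizes to its bare lowercase symbol (`n`, `o`,
`s`).

A consequence worth spelling out: amide N–H is *not* kept (the amide core
is multi-atom), so primary, secondary and tertiary amides share the single
generalized form `RC(=O)N(R)R`. Amide substitution detail lives in the
full-environment forms (below), not in the generalized key.

**Canonicalization.** The generalized graph is serialized through RDKit's
canonical SMILES over a role-encoded graph: `R` placeholders and retained
environment carbons are isotope-tagged dummy atoms (so roles participate
in canonical ranking), retained hydrogens are explicit atoms, and the
final string maps the dummies to `R`/`C`/`c`. Equal FG graphs therefore
produce byte-equal strings regardless of input atom order. The dialect
renders retained environment carbons as bare `C`/`c`; a `--smarts-ish`
rendering replaces `R` with `*` for downstream tools that must parse the
strings. Note the display dialect does not distinguish a retained
environment carbon from a core carbon token; the counting key is the
canonical string, and the small single-heteroatom forms where retained
carbons occur do not collide with any core-carbon form.

**Full-environment mode** (`--no-generalize` / `--keep-environment`, the
two flags are synonyms) serializes the ungeneralized graph in the same
dialect: typed environment carbons, explicit heteroatom hydrogens. One
generalized urea corresponds to many full forms (unsubstituted, N-methyl,
N,N'-diaryl, ...), which is where substitution-level statistics come from.

**Variant combinatorics.** `enumerate_environment_variants` counts the
distinct environment patterns of a core with `n` attachment points, each
taking H / aliphatic C / aromatic C, deduplicated under declared
symmetries (interchangeable points within a group, and wholesale
interchangeable groups, as in the two NR₂ halves of urea). Dedup-by
canonical-sorting is cross-checked in the tests against a brute-force
orbit count over the generated permutation group: amide (3 points, N-pair
symmetric) gives 18, urea (4 points, two swappable symmetric pairs) 21.

## Statistics (`stats`)

Counting is per-molecule presence (within-molecule multiplicity is
ignored), the denominator is *all* standardized molecules including
FG-free ones, lone aromatic heteroatoms are excluded by default (they are
ring members, not classical FGs) and included via a flag, and tail
thresholds use strict inequality ("more than 1%"). Tables are invariant to
stream order and additive over disjoint collections. `min_support_filter`
updates the unique-FG count but deliberately keeps the collection totals
(denominator, singleton count) of the unfiltered table, since they
describe the collection, not the view.

## Synthetic data (`fixtures`)

The built-in panel (`data/panel.tsv`, ~50 molecules) is the primary
oracle: expected cores, rule tags, attachment shells and generalized
strings were derived by hand application of the rules, with the
derivation recorded per row. The random generator assembles molecules
from a linear fragment grammar (alkyl/aryl units, carbonyl and sulfonyl
linkers, acetal centers, three-membered heterocycles, aromatic
heterocycles, terminal halogens and charged nitro groups) and keeps only
candidates that parse and standardize, so the corpus is deterministic per
seed and spans every marking rule. It emulates the *local* motif
diversity of small drug-like molecules, not their global realism: no
stereochemistry, no fused polycycles, no macrocycles, and an artificial
motif frequency profile. Passing the corpus tests therefore demonstrates
rule correctness and order invariance, not database-level frequency
realism.

Test problem sizes — 1000 molecules for the oracle-equivalence check, 200
molecules × 5 serializations for order invariance — were chosen as the
point where rule-coverage statistics saturate for this grammar; the whole
suite runs in a few seconds.

## Known limitations

- No tautomer or stereochemistry normalization: tautomers may yield
  different groups (that is faithful to the graph each tautomer presents).
- Aromaticity-model sensitivity, as discussed above.
- The pseudo-SMILES dialect is a counting key first; round-tripping it
  into a molecule object requires the `--smarts-ish` rendering and
  accepts the loss of the R/environment role distinction.
- Database-scale frequency profiling (e.g. a full ChEMBL bioactive
  extract, where the amide form should rank first) is an at-scale smoke
  test to run manually with `fgfind`/`fgstats`; it is not reproduced at
  test scale.
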