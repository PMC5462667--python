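"""fgscan: automatic functional-group perception for organic molecules.

Identifies every functional group in a molecule without a pattern
library — heteroatoms and activated carbons are marked by structural
rules, merged into connected cores, extracted with their typed carbon
environment, and reduced to generalized R-group pseudo-SMILES that serve
as counting keys for compound-library profiling.
"""

from .molio import (
    Molecule,
    RawRecord,
    Rejection,
    read_molecules,
    standardize,
    standardize_smiles,
    write_fg_table,
    write_rejection_log,
)
from .perceive import (
    Attachment,
    FunctionalGroup,
    MarkSet,
    extract_groups,
    mark_atoms,
    mark_carbons,
    mark_heteroatoms,
    merge_marked,
)
from .generalize import (
    GeneralizedFG,
    amide_variant_count,
    build_full_graph,
    canonical_pseudo_smiles,
    enumerate_environment_variants,
    full_form,
    generalize,
    generalize_graph,
    render_smarts_ish,
)
from .stats import (
    FrequencyTable,
    accumulate,
    merge_tables,
    min_support_filter,
    tail_summary,
)
from .fixtures import FixtureCase, builtin_panel, random_molecules

__version__ = "0.1.0"


def find_functional_groups(smiles: str, generalized: bool = True):
    """Standardize one SMILES and return its functional-group forms.

    Returns a list of :class:`GeneralizedFG` (default) or of
    full-environment pseudo-SMILES strings; raises ``ValueError`` if the
    molecule is rejected by standardization.
    """
    result = standardize_smiles(smiles)
    if isinstance(result, Rejection):
        raise ValueError(f"molecule rejected: {result.reason}")
    groups = extract_groups(result)
    if generalized:
        return [generalize(fg) for fg in groups]
    return [full_form(fg) for fg in groups]
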