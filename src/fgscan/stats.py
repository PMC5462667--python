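"""Collection-level frequency statistics of generalized functional groups.

Counting is per-molecule presence: a molecule containing a group twice
contributes one count. Percentages are fractions of *all* standardized
molecules in the collection, including molecules without any functional
group. Lone aromatic ring heteroatoms are excluded from the table by
default, matching the convention of headline FG rankings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .generalize import GeneralizedFG


@dataclass(frozen=True)
class FrequencyTable:
    """Per-collection occurrence statistics of generalized FGs.

    ``rows`` has columns ``fg`` (canonical pseudo-SMILES), ``n_molecules``
    (molecules containing the group at least once) and ``percent``
    (of ``n_total_molecules``), sorted by count descending then string.
    """

    rows: pd.DataFrame
    n_total_molecules: int
    n_unique_fgs: int
    n_singletons: int
    counting_mode: str = "per_molecule_presence"


FGItem = Union[GeneralizedFG, str]


def _key_and_lone(fg: FGItem) -> tuple[str, bool]:
    if isinstance(fg, GeneralizedFG):
        return fg.pseudo_smiles, fg.is_lone_aromatic_het
    # bare strings (e.g. re-read from a TSV): lone aromatic heteroatoms are
    # exactly the bare lowercase one-atom forms
    return fg, fg in ("n", "o", "s") or (fg.startswith("[") and fg[1:-1].islower())


def accumulate(
    stream: Iterable[tuple[str, Sequence[FGItem]]],
    include_lone_aromatic_het: bool = False,
) -> FrequencyTable:
    """Aggregate a (identifier, functional groups) stream into a table.

    Per-molecule FG sets are deduplicated before counting. Every molecule
    in the stream enters the percentage denominator, FG-free ones included.
    """
    counts: dict[str, int] = {}
    n_total = 0
    for _ident, fgs in stream:
        n_total += 1
        keys = set()
        for fg in fgs:
            key, lone = _key_and_lone(fg)
            if lone and not include_lone_aromatic_het:
                continue
            keys.add(key)
        for key in keys:
            counts[key] = counts.get(key, 0) + 1

    rows = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["fg", "n_molecules"],
    )
    rows["n_molecules"] = rows["n_molecules"].astype(int)
    rows["percent"] = (
        rows["n_molecules"] * 100.0 / n_total if n_total else 0.0
    )
    n_singletons = int((rows["n_molecules"] == 1).sum())
    return FrequencyTable(rows, n_total, len(rows), n_singletons)


def min_support_filter(table: FrequencyTable, min_molecules: int) -> FrequencyTable:
    """Keep rows present in at least ``min_molecules`` molecules.

    ``n_unique_fgs`` reflects the filtered rows; the collection totals
    (denominator, singleton count) describe the unfiltered table.
    """
    if min_molecules < 1:
        raise ValueError("min_molecules must be >= 1")
    rows = table.rows[table.rows["n_molecules"] >= min_molecules].reset_index(drop=True)
    return FrequencyTable(
        rows, table.n_total_molecules, len(rows), table.n_singletons, table.counting_mode
    )


def tail_summary(
    table: FrequencyTable, thresholds: Sequence[float] = (1.0, 0.1)
) -> dict:
    """Long-tail summary: how many groups exceed each percentage threshold
    (strict inequality), plus singleton statistics."""
    above = {
        str(t): int((table.rows["percent"] > t).sum()) for t in thresholds
    }
    share = (
        100.0 * table.n_singletons / table.n_unique_fgs if table.n_unique_fgs else 0.0
    )
    return {
        "n_total_molecules": table.n_total_molecules,
        "n_unique_fgs": table.n_unique_fgs,
        "n_singletons": table.n_singletons,
        "singleton_share_percent": share,
        "n_above_percent": above,
    }


def merge_tables(a: FrequencyTable, b: FrequencyTable) -> FrequencyTable:
    """Row-wise sum of two disjoint collections' tables (stream additivity)."""
    counts: dict[str, int] = {}
    for t in (a, b):
        for fg, n in zip(t.rows["fg"], t.rows["n_molecules"]):
            counts[fg] = counts.get(fg, 0) + int(n)
    n_total = a.n_total_molecules + b.n_total_molecules
    rows = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["fg", "n_molecules"],
    )
    rows["n_molecules"] = rows["n_molecules"].astype(int)
    rows["percent"] = rows["n_molecules"] * 100.0 / n_total if n_total else 0.0
    return FrequencyTable(rows, n_total, len(rows), int((rows["n_molecules"] == 1).sum()))


def write_table(table: FrequencyTable, path, summary_path=None, thresholds=(1.0, 0.1)) -> None:
    """Write the TSV (``fg  n_molecules  percent``) and a JSON summary."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("fg\tn_molecules\tpercent\n")
        for _, row in table.rows.iterrows():
            fh.write(f"{row['fg']}\t{int(row['n_molecules'])}\t{row['percent']:.4f}\n")
    if summary_path is not None:
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(tail_summary(table, thresholds), fh, indent=2, sort_keys=True)
            fh.write("\n")
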