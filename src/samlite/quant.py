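"""Two-pass rescue counting of mapped fragments.

Pass 1 counts fragments mapping uniquely to a protein P and normalizes by
protein length to give n_P.  Pass 2 distributes each multi-mapping fragment
across its proteins in proportion to the frozen first-pass n values,
n_P / sum(n_Q); if every candidate has zero unique evidence the fragment is
split evenly.  Each multi-mapping fragment therefore contributes exactly one
unit of count in total, and the result is independent of the order of the
mapping stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import write_tsv


@dataclass
class CountTable:
    """Per-protein counts for one sample.

    ``unique`` holds u_P (fragments mapping only to P), ``normalized`` holds
    n_P = u_P / |P|, ``rescued`` the pass-2 increments r_P, and ``final`` the
    exported abundance n_P + r_P.
    """

    protein_lengths: Mapping[str, int]
    unique: dict[str, int] = field(default_factory=dict)
    normalized: dict[str, float] = field(default_factory=dict)
    rescued: dict[str, float] = field(default_factory=dict)
    n_unique_fragments: int = 0
    n_multi_fragments: int = 0

    @property
    def final(self) -> dict[str, float]:
        proteins = set(self.normalized) | set(self.rescued)
        return {
            p: self.normalized.get(p, 0.0) + self.rescued.get(p, 0.0)
            for p in proteins
        }


def count_sample(
    mappings: Iterable[tuple[str, Sequence[str]]],
    protein_lengths: Mapping[str, int],
) -> CountTable:
    """Count one sample's mapping stream of ``(read_id, protein names)``.

    Raises KeyError-style errors if a mapped protein is missing from
    ``protein_lengths`` (the index metadata).
    """
    table = CountTable(protein_lengths=protein_lengths)
    multi: list[Sequence[str]] = []
    for read_id, proteins in mappings:
        for p in proteins:
            if p not in protein_lengths:
                raise ValueError(
                    f"read {read_id!r} maps to unknown protein {p!r}"
                )
        if len(proteins) == 0:
            continue
        if len(proteins) == 1:
            p = proteins[0]
            table.unique[p] = table.unique.get(p, 0) + 1
            table.n_unique_fragments += 1
        else:
            multi.append(tuple(dict.fromkeys(proteins)))
            table.n_multi_fragments += 1
    for p, u in table.unique.items():
        table.normalized[p] = u / protein_lengths[p]
    # pass 2: n values frozen at pass-1 results
    n = table.normalized
    rescued = table.rescued
    for proteins in multi:
        denom = sum(n.get(p, 0.0) for p in proteins)
        if denom > 0.0:
            for p in proteins:
                share = n.get(p, 0.0) / denom
                if share:
                    rescued[p] = rescued.get(p, 0.0) + share
        else:
            share = 1.0 / len(proteins)
            for p in proteins:
                rescued[p] = rescued.get(p, 0.0) + share
    return table


def build_matrix(tables: Sequence[tuple[str, CountTable]]) -> pd.DataFrame:
    """Assemble a proteins x samples matrix of final counts.

    Rows are the union of proteins with any count, sorted by name; columns
    follow the input sample order; missing entries are 0.
    """
    if not tables:
        raise ValueError("at least one sample is required")
    names = [name for name, _ in tables]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate sample names: {names}")
    finals = {name: table.final for name, table in tables}
    proteins = sorted(set().union(*[set(f) for f in finals.values()]))
    df = pd.DataFrame(
        {name: [finals[name].get(p, 0.0) for p in proteins] for name in names},
        index=pd.Index(proteins, name="protein"),
    )
    return df


def write_matrix(matrix: pd.DataFrame, path, rounded: bool = False) -> None:
    """Write the count matrix as TSV (first column = protein name).

    ``rounded=True`` rounds to the nearest integer for downstream tools that
    insist on integer counts; by default the fractional rescue values are
    kept.
    """
    out = matrix.round(0).astype(int) if rounded else matrix
    rows = [[p, *out.loc[p]] for p in out.index]
    write_tsv(rows, ["protein", *out.columns], path)
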