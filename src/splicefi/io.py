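"""Readers and writers for the plain-text interchange formats.

Matrices (expression, PSI) are TSV with the id column first and sample
IDs in the header; missing values are written as ``NA``.  Pathway sets
use the GMT layout (name, description, then member genes, tab-separated).
The reference network is a two-column edge list (extra columns ignored).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


def read_matrix(path: str | Path, index_name: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if index_name:
        df.index.name = index_name
    return df


def write_matrix(
    df: pd.DataFrame, path: str | Path, index_name: str | None = None
) -> None:
    out = df.copy()
    if index_name:
        out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse GMT: one gene set per line (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        members = {g for g in fields[2:] if g}
        if members:
            sets[fields[0]] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + sorted(set(map(str, members))))
        for name, members in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False, name=None)]


def write_edge_list(edges: Sequence[tuple[str, str]], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{a}\t{b}" for a, b in edges) + ("\n" if edges else "")
    )


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"event_id", "sample_id", "I", "E"}
    if not required.issubset(df.columns):
        raise ValueError(f"junction-count table needs columns {sorted(required)}")
    return df
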