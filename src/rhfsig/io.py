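"""Plain-text I/O for the pipeline's table formats.

All artifacts are diffable text: gene-by-sample counts as TSV (first column
gene id, header row of sample ids), sample sheets and clinical tables as CSV,
gene sets as GMT (tab-separated: name, description, members...), ortholog
maps and edge tables as TSV, reports as JSON.  Every writer has a matching
reader and ``read(write(x)) == x`` holds for each of them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd


class GMTParseError(ValueError):
    """Raised for a malformed GMT line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


# ---------------------------------------------------------------- counts TSV

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a gene-by-sample matrix as TSV; index holds gene ids."""
    df = counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------- CSV tables

def write_table_csv(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, index=index)


def read_table_csv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def write_table_tsv(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_table_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ----------------------------------------------------------------------- GMT

def write_gmt(collection: Mapping[str, set | list], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write named gene sets in GMT format (name, description, members)."""
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = descriptions.get(name, "na")
            fields = [name, desc, *sorted(str(m) for m in members)]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into name -> member set.

    A valid line has at least three tab-separated fields: the set name, a
    description, and one or more members.  Shorter lines raise
    :class:`GMTParseError` with the offending line number.
    """
    collection: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    lineno, f"expected >=3 tab-separated fields, got {len(fields)}")
            name = fields[0]
            if name in collection:
                raise GMTParseError(lineno, f"duplicate set name {name!r}")
            members = {f for f in fields[2:] if f}
            if not members:
                raise GMTParseError(lineno, f"set {name!r} has no members")
            collection[name] = members
    return collection


# ---------------------------------------------------------------------- JSON

def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
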