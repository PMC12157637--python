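"""Readers and writers for the pipeline's plain-text formats.

All matrices travel as TSV with row identifiers in the first column; gene-set
collections travel as GMT (set name, description, member gene IDs, tab
separated). Output tables carry a leading ``#`` comment line with the package
version and, when relevant, the seed that produced them, so a result file is
self-describing.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Mapping

import pandas as pd

from .errors import InvalidInputError

__version__ = "0.1.0"


def _header_comment(seed: int | None = None) -> str:
    tag = f"# trisomod {__version__}"
    if seed is not None:
        tag += f" seed={seed}"
    return tag + "\n"


def write_table(df: pd.DataFrame, path: str | os.PathLike, *, seed: int | None = None,
                index: bool = True, index_label: str | None = None) -> None:
    """Write a DataFrame as TSV with a version/seed comment header."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV matrix with identifiers in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise InvalidInputError(f"duplicate row identifiers in {path}")
    return df


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a plain TSV table (no index column)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set collection, preserving file order."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(f"malformed GMT line in {path}: {line[:80]!r}")
            name = fields[0]
            if name in sets:
                raise InvalidInputError(f"duplicate gene-set name {name!r} in {path}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_json(obj, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False, default=str)
        fh.write("\n")


def read_json(path: str | os.PathLike):
    with open(path) as fh:
        return json.load(fh)
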