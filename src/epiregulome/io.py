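"""Readers/writers for every external format the pipeline touches.

All tables are UTF-8, tab-delimited, unquoted; ids are validated against a
safe character set so that write -> read round-trips are bit-exact.
Violations raise :class:`SchemaError` with the offending location.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_kb",
    "write_kb",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
]

_ID_RE = re.compile(r"^[A-Za-z0-9._:+-]+$")

METADATA_REQUIRED = ("sample_id", "cohort", "condition")
METADATA_OPTIONAL = ("tissue", "age", "seizure_frequency", "duration", "gender")
CONDITIONS = {"disease", "control"}
KB_COLUMNS = ("regulator_id", "regulator_class", "target_id", "effect")
KB_EFFECTS = {"activation", "inhibition", "unspecified"}
KB_CLASSES = {"TF", "miRNA", "CMP"}


def _check_ids(values, what: str) -> None:
    for v in values:
        if not _ID_RE.match(str(v)):
            raise SchemaError(f"invalid {what} id {v!r} (allowed: [A-Za-z0-9._:+-])")


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)) or not np.allclose(arr, np.round(arr), atol=0):
            bad = np.argwhere(arr != np.round(arr))
            loc = (
                f"gene {df.index[bad[0][0]]!r}, sample {df.columns[bad[0][1]]!r}"
                if bad.size
                else "matrix"
            )
            raise SchemaError(f"{path}: non-integer count at {loc}")
        df = df.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative counts")
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    _check_ids(counts.index, "gene")
    _check_ids(counts.columns, "sample")
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sample metadata table; cross-validated against counts if given."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str})
    missing = set(METADATA_REQUIRED) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    unknown = set(df.columns) - set(METADATA_REQUIRED) - set(METADATA_OPTIONAL)
    if unknown:
        raise SchemaError(f"{path}: unknown column {sorted(unknown)[0]!r}")
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    bad = set(df["condition"]) - CONDITIONS
    if bad:
        raise SchemaError(f"{path}: condition must be in {sorted(CONDITIONS)}, got {sorted(bad)}")
    if counts is not None:
        absent = [s for s in df["sample_id"] if s not in set(counts.columns)]
        if absent:
            raise SchemaError(f"{path}: sample {absent[0]!r} absent from counts")
    return df.set_index("sample_id", drop=False).rename_axis(None)


def write_metadata(meta: pd.DataFrame, path) -> None:
    cols = [c for c in (*METADATA_REQUIRED, *METADATA_OPTIONAL) if c in meta.columns]
    meta[cols].to_csv(path, sep="\t", index=False)


def read_kb(path) -> pd.DataFrame:
    """Signed regulatory edge list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(KB_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    bad = set(df["effect"]) - KB_EFFECTS
    if bad:
        raise SchemaError(f"{path}: unknown effect {sorted(bad)}")
    bad = set(df["regulator_class"]) - KB_CLASSES
    if bad:
        raise SchemaError(f"{path}: unknown regulator class {sorted(bad)}")
    _check_ids(df["regulator_id"], "regulator")
    _check_ids(df["target_id"], "target")
    return df[list(KB_COLUMNS)]


def write_kb(kb: pd.DataFrame, path) -> None:
    kb[list(KB_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Standard gene-matrix-transposed format: name, description, members."""
    sets: dict[str, set[str]] = {}
    text = Path(path).read_text().splitlines()
    if not any(line.strip() for line in text):
        raise SchemaError(f"{path}: empty GMT file")
    for lineno, line in enumerate(text, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(f"{path}:{lineno}: GMT line has < 3 fields")
        name, _desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise SchemaError(f"{path}:{lineno}: duplicate set name {name!r}")
        if len(members) != len(set(members)):
            warnings.warn(f"{path}:{lineno}: duplicated members in {name!r} deduplicated",
                          stacklevel=2)
        if not members:
            raise SchemaError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = set(members)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Generic TSV writer with a stable float representation."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
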