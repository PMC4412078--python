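"""TSV/JSON readers and writers for the package's external formats.

All tabular formats are plain TSV: edge lists are two headerless columns;
expression matrices have gene ids in the first column and sample ids in the
header; group files map sample id to group label ("A"/"normal" vs
"B"/"cancer").  Floats are written at 12 significant digits so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .cohort import Cohort
from .graphs import NetworkInputError

FLOAT_FMT = "%.12g"

_GROUP_ALIASES = {
    "a": "A", "normal": "A", "n": "A", "control": "A",
    "b": "B", "cancer": "B", "c": "B", "tumour": "B", "tumor": "B", "case": "B",
}


def read_expression(path, pseudocount: float | None = None) -> pd.DataFrame:
    """Genes x samples matrix: first column gene id, header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise NetworkInputError(f"{path}: empty expression matrix")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise NetworkInputError(f"{path}: duplicate gene id {dup!r}")
    df = df.astype(np.float64)
    if pseudocount is not None:
        df = df + pseudocount
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def read_groups(path) -> pd.Series:
    """Two-column TSV sample -> group; labels normalised to 'A'/'B'."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     dtype=str, comment="#")
    labels = {}
    for _, row in df.iterrows():
        g = _GROUP_ALIASES.get(str(row["group"]).strip().lower())
        if g is None:
            raise NetworkInputError(
                f"{path}: unrecognised group label {row['group']!r}"
            )
        labels[str(row["sample"]).strip()] = g
    return pd.Series(labels, name="group")


def write_groups(groups: pd.Series, path) -> None:
    groups.to_csv(path, sep="\t", header=False)


def read_cohort(expr_path, groups_path, pseudocount: float | None = None) -> Cohort:
    return Cohort(read_expression(expr_path, pseudocount), read_groups(groups_path))


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
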