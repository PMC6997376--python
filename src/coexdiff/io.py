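"""Validated readers and writers for the pipeline's plain-text formats.

Counts and expression matrices are gene-major TSVs with a header row of
sample ids; the design is a CSV; categories use the GMT dialect
(term, description, then tab-separated gene ids).  Readers tolerate mixed
line endings; writers always emit Unix newlines, so a write -> read
round-trip is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
    "write_truth_json",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    if counts.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    if counts.isna().any().any():
        raise FormatError(f"{path}: missing values in count matrix")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise FormatError(f"{path}: counts must be integers")
        counts = counts.round().astype(np.int64)
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    counts.index.name = "gene"
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, index_col=0)
    required = {"group", "sex", "week"}
    missing = required - set(design.columns)
    if missing:
        raise FormatError(f"{path}: design missing columns {sorted(missing)}")
    if design.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in design")
    design["group"] = pd.Categorical(
        design["group"], categories=pd.unique(design["group"])
    )
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index_label="sample_id", lineterminator="\n")


def read_gene_lengths(path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in tab.columns:
        raise FormatError(f"{path}: gene metadata needs a 'length' column")
    lengths = tab["length"]
    if (lengths <= 0).any():
        raise FormatError(f"{path}: non-positive gene lengths")
    return lengths


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene",
                                    lineterminator="\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT category file: term <tab> description <tab> gene ids..."""
    categories: dict[str, set[str]] = {}
    with open(path, newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
                )
            term = fields[0]
            if term in categories:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            categories[term] = set(fields[2:])
    return categories


def write_gmt(categories: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w", newline="\n") as fh:
        for term in categories:
            genes = "\t".join(sorted(categories[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_table(table: pd.DataFrame, path, sep: str = "\t", index: bool = False) -> None:
    table.to_csv(path, sep=sep, index=index, lineterminator="\n")


def write_truth_json(truth, path) -> None:
    """Serialise a GroundTruth record to JSON."""
    payload = {
        "de_log2fc": {g: dict(row) for g, row in truth.de_log2fc.iterrows()},
        "module_membership": {g: int(m) for g, m in truth.module_membership.items()},
        "module_loadings": truth.module_loadings,
        "dispersions": {g: float(v) for g, v in truth.dispersions.items()},
        "size_factors": {s: float(v) for s, v in truth.size_factors.items()},
        "behaviour_zone_probs": truth.behaviour_zone_probs,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
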