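"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and design tables are tab-separated text with a header
row; gene sets use the GMT convention (set name, description, then member
genes, one set per line); simulation ground truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .containers import ExpressionDataset, SampleDesign

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_gmt",
    "write_gmt",
    "write_truth_json",
    "read_truth_json",
]


def read_matrix_tsv(path: str | Path, scale: str = "log2", platform: str = "") -> ExpressionDataset:
    vals = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionDataset(values=vals, scale=scale, platform=platform)


def write_matrix_tsv(ds: ExpressionDataset, path: str | Path) -> None:
    ds.values.to_csv(path, sep="\t", index_label="gene")


def read_design_tsv(path: str | Path) -> SampleDesign:
    tab = pd.read_csv(path, sep="\t", index_col=0, dtype={"condition": str})
    return SampleDesign(tab)


def write_design_tsv(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_truth_json(truth: Mapping, path: str | Path) -> None:
    def _default(obj):
        try:
            return obj.tolist()
        except AttributeError:
            return str(obj)

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_default)


def read_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
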