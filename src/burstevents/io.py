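"""Tabular I/O: TSV tables with a JSON-compatible metadata header."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import MFDataset

__all__ = ["write_tsv", "read_tsv", "write_json", "read_mf_tsv", "write_mf_tsv"]


def write_tsv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a data frame as TSV with '#'-prefixed JSON metadata lines."""
    path = Path(path)
    with path.open("w") as fh:
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True, default=float) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                try:
                    meta.update(json.loads(line.lstrip("# ")))
                except json.JSONDecodeError:
                    pass
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return df, meta


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def write_mf_tsv(path, data: MFDataset, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("provenance", data.provenance)
    write_tsv(path, data.to_frame(), meta)


def read_mf_tsv(path) -> MFDataset:
    df, meta = read_tsv(path)
    return MFDataset(
        m_mean=df["m_mean"].to_numpy(),
        fano=df["fano"].to_numpy(),
        weight=df["weight"].to_numpy() if "weight" in df else None,
        provenance=meta.get("provenance", "user"),
    )
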