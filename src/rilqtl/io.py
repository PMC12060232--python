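"""Readers and writers for the pipeline's text formats.

All tables are tab-separated with explicit headers; missing dosage is
``NA``; null distributions are single-column text with a comment header
recording seed and permutation count; nested summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AncestryMatrix, NullDistribution, validate_window_map


class ParseError(ValueError):
    pass


def write_ancestry_matrix(matrix: AncestryMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "ril"
    out = df.copy()
    # integer-looking cells, NA for missing
    for c in out.columns:
        out[c] = out[c].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


def read_ancestry_matrix(path) -> AncestryMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    dosage = np.empty(df.shape, dtype=float)
    for j, c in enumerate(df.columns):
        col = df[c].to_numpy()
        for i, v in enumerate(col):
            if v == "NA":
                dosage[i, j] = np.nan
            elif v in ("0", "1", "2"):
                dosage[i, j] = float(v)
            else:
                raise ParseError(
                    f"invalid dosage {v!r} at row {df.index[i]!r}, column {c!r}"
                )
    return AncestryMatrix(
        df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object), dosage
    )


def write_window_map(wmap: pd.DataFrame, path) -> None:
    validate_window_map(wmap).to_csv(path, sep="\t", index=False)


def read_window_map(path) -> pd.DataFrame:
    return validate_window_map(pd.read_csv(path, sep="\t"))


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scan_table(scan: pd.DataFrame, wmap: pd.DataFrame, path) -> None:
    out = wmap[["window_id", "arm", "cM"]].merge(scan, on="window_id", how="right")
    out.to_csv(path, sep="\t", index=False)


def read_scan_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_null(null: NullDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# statistic={null.statistic} n_perm={null.n_perm} seed={null.seed}\n")
        fh.write("value\n")
        for v in null.values:
            fh.write(f"{float(v)!r}\n")


def read_null(path) -> NullDistribution:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError("null distribution file missing metadata header")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        values = pd.read_csv(fh, sep="\t", float_precision="round_trip")[
            "value"
        ].to_numpy(dtype=float)
    return NullDistribution(
        values,
        n_perm=int(meta["n_perm"]),
        seed=int(meta["seed"]),
        statistic=meta["statistic"],
    )


def write_qtl_calls(calls, path_tsv=None, path_json=None) -> None:
    records = [c.to_dict() for c in calls]
    if path_tsv is not None:
        pd.DataFrame(records).to_csv(path_tsv, sep="\t", index=False)
    if path_json is not None:
        Path(path_json).write_text(json.dumps(records, indent=2, default=str) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError("config file must contain a mapping")
    return cfg
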