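"""CSV/TSV dialects for tables, metadata, truth, and result artifacts.

Feature tables are CSV with samples as rows, the first column
``sample_id``, one column per metabolite, and missing values written as
empty cells (the literal ``NA`` is also accepted on read).  Metadata is
CSV; truth tables and all result frames are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable, RAW

__all__ = [
    "read_feature_csv",
    "write_feature_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "read_truth_tsv",
    "write_truth_tsv",
    "write_tsv",
    "write_manifest",
]

_NA_VALUES = ["", "NA"]


def read_feature_csv(path, scale: str = RAW) -> FeatureTable:
    df = pd.read_csv(
        path, index_col="sample_id", na_values=_NA_VALUES, keep_default_na=False
    )
    return FeatureTable(df, scale)


def write_feature_csv(table: FeatureTable, path) -> None:
    table.data.to_csv(path, na_rep="", index_label="sample_id")


def read_metadata_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)


def write_metadata_csv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_manifest(path, **entries) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=_default) + "\n")
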