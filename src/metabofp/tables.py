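"""Core in-memory containers for the pipeline.

A :class:`FeatureTable` wraps a samples × metabolites :class:`pandas.DataFrame`
of abundances together with a ``scale`` tag recording where in the fixed
preprocessing chain (raw → log2 → autoscaled) the values currently sit.  The
tag lets downstream operations enforce the pipeline contract — in particular,
fold changes are a raw-scale quantity and are rejected on transformed data.

Sample metadata travels as a plain DataFrame with a ``sample_id`` column, a
``group`` column taking values ``control`` / ``case``, and optional nuisance
covariates (sex, litter, date_of_birth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"
AUTOSCALED = "autoscaled"
_SCALES = (RAW, LOG2, AUTOSCALED)

GROUP_CONTROL = "control"
GROUP_CASE = "case"


class PipelineOrderError(RuntimeError):
    """An operation was applied at the wrong point of the preprocessing chain."""


@dataclass
class FeatureTable:
    """Samples × metabolites abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample ID with one column per metabolite.
        Missing cells are NaN.
    scale:
        One of ``"raw"``, ``"log2"``, ``"autoscaled"``.
    """

    data: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if not self.data.index.is_unique:
            raise ValueError("sample IDs must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("feature IDs must be unique")
        self.data = self.data.astype(float)
        if self.scale == RAW:
            vals = self.data.to_numpy()
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError("raw-scale intensities must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def require_scale(self, *scales: str, op: str = "operation") -> None:
        if self.scale not in scales:
            raise PipelineOrderError(
                f"{op} requires a table on scale {scales}, got {self.scale!r}; "
                "the pipeline order is filter → impute → fold change (raw) → log2 → autoscale"
            )

    def require_complete(self, op: str = "operation") -> None:
        if self.n_missing:
            raise ValueError(f"{op} requires a table with no missing values (impute first)")

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.scale)


def check_metadata(metadata: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    """Validate a metadata frame and return it indexed by sample_id."""
    meta = metadata.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    if not meta.index.is_unique:
        raise ValueError("duplicate sample IDs in metadata")
    if "group" not in meta.columns:
        raise ValueError("metadata must contain a 'group' column")
    bad = set(meta["group"]) - {GROUP_CONTROL, GROUP_CASE}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected control/case")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in meta.index]
        if missing:
            raise ValueError(f"samples without metadata/group label: {missing}")
        meta = meta.loc[list(sample_ids)]
    return meta


def group_masks(metadata: pd.DataFrame, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (control, case) masks aligned to ``sample_ids``."""
    meta = check_metadata(metadata, sample_ids)
    grp = meta["group"].to_numpy()
    return grp == GROUP_CONTROL, grp == GROUP_CASE
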