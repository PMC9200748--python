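"""Annotated well/image × feature tables.

A ``FeatureTable`` couples a values matrix (pandas DataFrame, rows are
image or well identifiers) with a per-feature annotation triple
(compartment, channel, feature_type) and per-row metadata (batch, role,
source).  Feature names follow the CellProfiler-style convention
``<compartment>_<feature_type>_<channel>_<detail>`` so annotations can be
recovered from names alone; delimited-text round trips encode metadata
columns with a ``Metadata_`` prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .constants import COMPARTMENTS, FEATURE_TYPES, FLUOR_CHANNELS


@dataclass
class FeatureTable:
    data: pd.DataFrame
    annotations: pd.DataFrame
    meta: pd.DataFrame
    planted: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.data.columns.is_unique:
            raise ValueError("feature names must be unique")
        if not self.data.index.is_unique:
            raise ValueError("row identifiers must be unique")
        missing = set(self.data.columns) - set(self.annotations.index)
        if missing:
            raise ValueError(f"features lack annotations: {sorted(missing)[:5]} ...")
        bad = set(self.annotations.columns) >= {"compartment", "channel", "feature_type"}
        if not bad:
            raise ValueError("annotations must have compartment, channel, feature_type columns")

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def select(self, features: list[str]) -> "FeatureTable":
        """Restrict to the given features (order preserved)."""
        return FeatureTable(self.data[features].copy(),
                            self.annotations.loc[features].copy(),
                            self.meta.copy())

    def rows_where(self, mask) -> "FeatureTable":
        return FeatureTable(self.data.loc[mask].copy(), self.annotations.copy(),
                            self.meta.loc[mask].copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.annotations.copy(), self.meta.copy())

    def to_csv(self, path: Path):
        out = self.meta.add_prefix("Metadata_").join(self.data)
        out.to_csv(path, index_label="row_id")

    @classmethod
    def from_csv(cls, path: Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="row_id")
        meta_cols = [c for c in df.columns if c.startswith("Metadata_")]
        meta = df[meta_cols].rename(columns=lambda c: c[len("Metadata_"):])
        data = df.drop(columns=meta_cols)
        ann = pd.DataFrame([parse_feature_name(c) for c in data.columns], index=data.columns)
        return cls(data=data, annotations=ann, meta=meta)


def parse_feature_name(name: str) -> dict:
    """Recover the (compartment, feature_type, channel) triple from a name."""
    parts = name.split("_")
    comp = parts[0] if parts and parts[0] in COMPARTMENTS else "cell"
    ftype = "intensity"
    for ft in FEATURE_TYPES:
        token = ft.replace("_", "")
        if token in [p.lower() for p in parts] or ft in name.lower():
            ftype = ft
            break
    chan = "none"
    for ch in FLUOR_CHANNELS:
        if ch in parts:
            chan = ch
            break
    return {"compartment": comp, "feature_type": ftype, "channel": chan}


def make_feature_name(compartment: str, feature_type: str, channel: str, detail) -> str:
    return f"{compartment}_{feature_type}_{channel}_{detail}"
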