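"""Core in-memory containers shared by every pipeline stage.

Expression data travels as a feature x sample :class:`pandas.DataFrame`
wrapped in :class:`ExpressionDataset`, which carries the scale flag
(``linear`` or ``log2``), a platform tag and optional probe-level feature
annotation.  Sample-level metadata (condition, donor, batch, time point)
lives in :class:`SampleDesign`; every grouped statistic in the pipeline is
defined against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "SampleDesign", "LOG2_SANITY_MAX"]

# log2 microarray intensities live roughly in [5, 16]; values above this
# almost certainly mean linear-scale data was mislabelled.
LOG2_SANITY_MAX = 30.0


@dataclass
class ExpressionDataset:
    """A feature x sample expression matrix with scale and platform metadata.

    Parameters
    ----------
    values
        Features in rows (probe or gene ids as the index), samples in
        columns.  No missing values are permitted.
    scale
        ``"log2"`` or ``"linear"``.
    platform
        Free-text platform tag (e.g. an array family name).
    features
        Optional per-feature annotation indexed like ``values``; the
        column ``gene_symbol`` drives probe collapsing.
    """

    values: pd.DataFrame
    scale: str = "log2"
    platform: str = ""
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "log2" and np.nanmax(self.values.to_numpy()) > LOG2_SANITY_MAX:
            warnings.warn(
                f"log2-flagged data contains values > {LOG2_SANITY_MAX}; "
                "check the scale flag",
                stacklevel=2,
            )
        if self.features is not None and not self.features.index.equals(self.values.index):
            self.features = self.features.reindex(self.values.index)

    # -- convenience ------------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset_features(self, features: Iterable[str]) -> "ExpressionDataset":
        idx = pd.Index(features)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise KeyError(f"features not in dataset: {list(missing[:5])} ...")
        feats = self.features.loc[idx] if self.features is not None else None
        return replace(self, values=self.values.loc[idx], features=feats)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionDataset":
        idx = pd.Index(samples)
        feats = self.features
        return replace(self, values=self.values[idx], features=feats)

    def to_linear(self) -> "ExpressionDataset":
        if self.scale == "linear":
            return self
        return replace(self, values=2.0 ** self.values, scale="linear")

    def to_log2(self) -> "ExpressionDataset":
        if self.scale == "log2":
            return self
        vals = self.values.where(self.values > 0, other=np.nan)
        if vals.isna().any().any():
            raise ValueError("cannot log2-transform nonpositive values")
        return replace(self, values=np.log2(vals), scale="log2")


@dataclass
class SampleDesign:
    """Per-sample condition / donor / batch / time-point labels.

    The underlying table is indexed by sample id and must cover every
    sample of the matrix it is used with (checked by :meth:`validate_for`).
    """

    table: pd.DataFrame

    REQUIRED = ("condition",)

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"design table lacks required column {col!r}")
        if self.table["condition"].isna().any() or (self.table["condition"] == "").any():
            raise ValueError("every sample needs a non-empty condition")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in design: {dups}")

    @classmethod
    def from_mapping(
        cls,
        condition: Mapping[str, str],
        donor: Mapping[str, str] | None = None,
        batch: Mapping[str, str] | None = None,
        time_point: Mapping[str, object] | None = None,
    ) -> "SampleDesign":
        tab = pd.DataFrame({"condition": pd.Series(condition)})
        for name, col in (("donor", donor), ("batch", batch), ("time_point", time_point)):
            if col is not None:
                tab[name] = pd.Series(col)
        return cls(tab)

    # -- accessors --------------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.table["condition"]))

    def samples_of(self, condition: str) -> list[str]:
        return list(self.table.index[self.table["condition"] == condition])

    def condition_of(self, samples: Iterable[str]) -> pd.Series:
        return self.table.loc[list(samples), "condition"]

    @property
    def batches(self) -> list[str]:
        if "batch" not in self.table.columns:
            return []
        return list(pd.unique(self.table["batch"]))

    def subset(self, samples: Iterable[str]) -> "SampleDesign":
        return SampleDesign(self.table.loc[list(samples)].copy())

    def validate_for(self, ds: ExpressionDataset) -> None:
        missing = ds.samples.difference(self.table.index)
        if len(missing):
            raise ValueError(f"samples missing from design: {list(missing)}")


def group_means(ds: ExpressionDataset, design: SampleDesign) -> pd.DataFrame:
    """Per-gene mean over samples of each condition (gene x condition)."""
    design.validate_for(ds)
    cond = design.condition_of(ds.samples)
    return ds.values.T.groupby(cond.values).mean().T
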