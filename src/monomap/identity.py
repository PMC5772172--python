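"""Cross-dataset identity mapping by four-group profile correlation.

To ask whether an in vitro derived cell population transcriptionally
resembles an in vivo population profiled on another platform, both
datasets are reduced to the same gene universe and to k comparable
condition groups (k = 4 in the original design).  Per gene, the Pearson
correlation between the two k-vectors of group means measures whether
the gene's expression pattern transfers across datasets; genes with
r above a cutoff AND a fold-change of the target group over every other
group above a second cutoff in *both* datasets are the shared identity
genes.

A composite target (two in vitro conditions standing in for one in vivo
population) uses the minimum of the two condition means as the target
value, so a gene must be elevated in both conditions to qualify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, SampleDesign
from .differential import DifferentialResult

__all__ = [
    "GroupProfile",
    "harmonize_genes",
    "group_mean_profiles",
    "per_gene_profile_correlation",
    "shared_identity_genes",
    "specific_deg_sets",
]


@dataclass
class GroupProfile:
    """Per-gene vector of k group-mean expressions (log2), ordered."""

    means: pd.DataFrame  # gene x group, columns in group order

    def __post_init__(self) -> None:
        if self.means.shape[1] < 2:
            raise ValueError("a profile needs at least 2 groups")

    @property
    def groups(self) -> list[str]:
        return list(self.means.columns)

    @property
    def genes(self) -> pd.Index:
        return self.means.index


def harmonize_genes(
    ds_a: ExpressionDataset, ds_b: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to their common gene symbols, same row order."""
    common = ds_a.genes.intersection(ds_b.genes).sort_values()
    if common.empty:
        raise ValueError("the datasets share no gene symbols")
    return ds_a.subset_features(common), ds_b.subset_features(common)


def group_mean_profiles(
    ds: ExpressionDataset,
    design: SampleDesign,
    grouping: Mapping[str, str],
    group_order: Sequence[str],
) -> GroupProfile:
    """Collapse conditions into ordered groups of column means.

    ``grouping`` maps every condition present in the data onto one of
    the ``group_order`` labels; multiple conditions may share a group.
    """
    design.validate_for(ds)
    cond = design.condition_of(ds.samples)
    unmapped = sorted(set(cond) - set(grouping))
    if unmapped:
        raise ValueError(f"conditions not mapped to a group: {unmapped}")
    labels = cond.map(grouping)
    means = ds.values.T.groupby(labels.values).mean().T
    missing = [g for g in group_order if g not in means.columns]
    if missing:
        raise ValueError(f"groups with no samples: {missing}")
    return GroupProfile(means[list(group_order)])


def per_gene_profile_correlation(pa: GroupProfile, pb: GroupProfile) -> pd.Series:
    """Pearson r between the two group-mean vectors of each gene.

    Genes with a constant profile in either dataset have undefined
    correlation and are reported as NaN.
    """
    if list(pa.groups) != list(pb.groups):
        raise ValueError("group order differs between the two profiles")
    if not pa.genes.equals(pb.genes):
        raise ValueError("profiles are not aligned on the same genes")
    A = pa.means.to_numpy(dtype=float)
    B = pb.means.to_numpy(dtype=float)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((A * A).sum(axis=1))
    nb = np.sqrt((B * B).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=1) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return pd.Series(r, index=pa.genes, name="r")


def _target_fold_changes(
    profile: GroupProfile, target: str | Sequence[str]
) -> pd.DataFrame:
    """Signed FC of the target group's mean against each other group.

    For a composite target (sequence of groups) the minimum of the
    target means per gene is the target value.
    """
    means = profile.means
    if isinstance(target, str):
        targets = [target]
    else:
        targets = list(target)
    missing = [t for t in targets if t not in means.columns]
    if missing:
        raise ValueError(f"target group(s) missing from the profile: {missing}")
    tval = means[targets].min(axis=1)
    others = [g for g in means.columns if g not in targets]
    out = {}
    for g in others:
        d = tval - means[g]
        out[g] = np.where(d >= 0, 2.0 ** d, -(2.0 ** (-d)))
    return pd.DataFrame(out, index=means.index)


def shared_identity_genes(
    pa: GroupProfile,
    pb: GroupProfile,
    target_a: str | Sequence[str],
    target_b: str | Sequence[str],
    r_min: float = 0.4,
    fc_min: float = 1.3,
    exclude: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genes co-expressed in the matched target groups of both datasets.

    Keeps genes with profile correlation r > ``r_min`` whose target
    group is elevated over every other group by FC > ``fc_min`` in both
    datasets (strict inequalities).  Genes with undefined r fail the r
    filter.  Returns a table with r and the per-comparison FCs of both
    sides, sorted by r descending.
    """
    if not -1 < r_min < 1:
        raise ValueError("r_min must lie in (-1, 1)")
    r = per_gene_profile_correlation(pa, pb)
    fca = _target_fold_changes(pa, target_a).add_prefix("A_vs_")
    fcb = _target_fold_changes(pb, target_b).add_prefix("B_vs_")
    keep = (r > r_min).fillna(False)
    keep &= (fca > fc_min).all(axis=1)
    keep &= (fcb > fc_min).all(axis=1)
    tab = pd.concat([r, fca, fcb], axis=1).loc[keep.to_numpy()]
    if exclude:
        tab = tab.drop(index=[g for g in exclude if g in tab.index])
    return tab.sort_values("r", ascending=False, kind="mergesort")


def specific_deg_sets(
    contrast_degs: Mapping[str, Sequence[str]],
    focus: Sequence[str] | None = None,
) -> dict[str, list[str]]:
    """Exclusive DEG sets: each contrast minus the DEGs of every other.

    ``contrast_degs`` maps contrast name -> its DEG list (up and down
    pooled or whichever direction the caller selected).  ``focus``
    restricts the output to certain contrasts while still subtracting
    all others.
    """
    if len(contrast_degs) < 2:
        raise ValueError("need at least 2 contrasts for exclusivity")
    names = list(contrast_degs)
    out: dict[str, list[str]] = {}
    for name in focus if focus is not None else names:
        others: set[str] = set()
        for other in names:
            if other != name:
                others |= set(contrast_degs[other])
        out[name] = sorted(set(contrast_degs[name]) - others)
    return out
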