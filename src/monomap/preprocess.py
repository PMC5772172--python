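"""Harmonization of raw expression matrices into analysis-ready form.

The pipeline's microarray inputs pass through: present-call filtering on
condition-group means, collapse of probes to one row per gene, quantile
normalization, and bridge-sample batch correction.  RNA-seq count inputs
pass through median-of-ratios size-factor normalization with a group-mean
expression filter.  Variable-gene selection and sample-correlation
matrices support the exploratory views.

Conventions
-----------
* "Present" means the maximum over condition-group means reaches a
  platform-specific log2 cutoff; features strictly below it are dropped.
* Probe collapse keeps, per gene, the probe with the highest mean
  expression across all samples; unannotated probes are dropped.
* Batch correction assumes a condition profiled in every batch (the
  bridge); per gene, each batch is shifted so its bridge-sample mean
  equals the grand mean of all bridge samples.  Only an additive
  per-gene location shift is removed — within-batch contrasts are
  untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, SampleDesign, group_means

__all__ = [
    "present_call_filter",
    "collapse_probes",
    "quantile_normalize",
    "bridge_batch_correct",
    "top_variable",
    "size_factors_and_filter",
    "sample_correlation_matrix",
    "donorwise_average",
]


def present_call_filter(
    ds: ExpressionDataset, design: SampleDesign, threshold: float
) -> ExpressionDataset:
    """Keep features whose maximum condition-group mean is >= ``threshold``.

    The boundary is kept: a feature with maximum group mean exactly at
    the cutoff counts as present (only strictly lower values are
    excluded).
    """
    if not np.isfinite(threshold):
        raise ValueError("present-call threshold must be finite")
    gm = group_means(ds, design)
    keep = gm.max(axis=1) >= threshold
    return ds.subset_features(ds.genes[keep.to_numpy()])


def collapse_probes(
    ds: ExpressionDataset, probe_to_gene: Mapping[str, str] | pd.Series
) -> ExpressionDataset:
    """Reduce a probe-keyed matrix to one row per gene symbol.

    Per gene, the surviving row is the probe with the highest mean
    expression across all samples; probes without a gene annotation are
    dropped.  Ties go to the lexicographically smallest probe id.
    """
    mapping = pd.Series(probe_to_gene)
    if mapping.index.duplicated().any():
        dup = mapping.index[mapping.index.duplicated()].tolist()
        raise ValueError(f"duplicate probe rows in the probe->gene map: {dup[:5]}")
    annotated = ds.genes.intersection(mapping.index)
    mapping = mapping.loc[annotated].dropna()
    mapping = mapping[mapping != ""]
    if mapping.empty:
        raise ValueError("no probe maps to a gene symbol")
    means = ds.values.loc[mapping.index].mean(axis=1)
    # deterministic arg-max: sort by (gene, -mean, probe id), keep the first
    choice = (
        pd.DataFrame({"gene": mapping, "mean": means})
        .reset_index(names="probe")
        .sort_values(["gene", "mean", "probe"], ascending=[True, False, True], kind="mergesort")
    )
    winners = choice.drop_duplicates("gene", keep="first")
    vals = ds.values.loc[winners["probe"]].copy()
    vals.index = pd.Index(winners["gene"].to_numpy(), name="gene")
    feats = None
    if ds.features is not None:
        feats = ds.features.loc[winners["probe"]].copy()
        feats.index = vals.index
    return replace(ds, values=vals.sort_index(), features=None if feats is None else feats.sort_index())


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample column onto the mean distribution of order statistics.

    After normalization all columns share one multiset of values and the
    within-column ranking is preserved.  Tied values receive the mean of
    the reference values at their tied ranks, which makes the transform
    idempotent.
    """
    X = ds.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)  # mean order statistics
    ranks = ds.values.rank(axis=0, method="average").to_numpy()  # 1-based, halves on ties
    # interpolate the reference at (possibly fractional) rank positions
    out = np.interp(ranks, np.arange(1, X.shape[0] + 1), reference)
    vals = pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns)
    return replace(ds, values=vals)


def bridge_batch_correct(
    ds: ExpressionDataset, design: SampleDesign, bridge_condition: str
) -> ExpressionDataset:
    """Remove additive per-gene batch offsets using bridge samples.

    For every gene and batch the offset is the batch's bridge-sample
    mean minus the grand mean over all bridge samples; it is subtracted
    from every sample of the batch.  Afterwards the per-gene bridge
    means agree across batches to numerical precision.
    """
    design.validate_for(ds)
    sub = design.table.loc[ds.samples]
    if "batch" not in sub.columns:
        raise ValueError("design has no batch column")
    is_bridge = sub["condition"] == bridge_condition
    for batch, grp in sub.groupby("batch", sort=False):
        if not (grp["condition"] == bridge_condition).any():
            raise ValueError(
                f"batch {batch!r} contains no sample of bridge condition {bridge_condition!r}"
            )
    bridge_cols = ds.samples[is_bridge.to_numpy()]
    grand = ds.values[bridge_cols].mean(axis=1)
    vals = ds.values.copy()
    for batch, grp in sub.groupby("batch", sort=False):
        b_bridge = grp.index[grp["condition"] == bridge_condition]
        offset = ds.values[b_bridge].mean(axis=1) - grand
        vals[grp.index] = vals[grp.index].sub(offset, axis=0)
    return replace(ds, values=vals)


def top_variable(ds: ExpressionDataset, n: int) -> list[str]:
    """The ``n`` features with the largest across-sample variance.

    Ties break lexicographically on the feature id, so the selection is
    deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(ds.genes):
        raise ValueError(f"n={n} exceeds the {len(ds.genes)} available features")
    var = ds.values.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var}).sort_index().sort_values("var", ascending=False, kind="mergesort")
    return list(order.index[:n])


def size_factors_and_filter(
    counts: pd.DataFrame,
    design: SampleDesign,
    min_mean: float = 10.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization plus a group-mean expression filter.

    Size factors follow the median-of-ratios recipe: the reference is
    the per-gene geometric mean over samples, computed on genes with all
    counts positive; each sample's factor is the median of its
    count/reference ratios.  Normalized counts are count/factor.  Genes
    are kept iff at least one condition-group mean of the normalized
    counts reaches ``min_mean``; finally all normalized values below 1
    are clamped to 1 so downstream ratios cannot explode.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    zero_samples = counts.columns[(arr.sum(axis=0) == 0)]
    if len(zero_samples):
        raise ValueError(f"samples with all-zero counts: {list(zero_samples)}")
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has positive counts in every sample")
    log_ref = np.log(arr[all_pos]).mean(axis=1)  # log geometric mean
    ratios = np.log(arr[all_pos]) - log_ref[:, None]
    factors = pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns, name="size_factor")
    norm = counts / factors
    norm_ds = ExpressionDataset(norm, scale="linear")
    gm = group_means(norm_ds, design)
    keep = (gm >= min_mean).any(axis=1)
    norm = norm.loc[keep.to_numpy()]
    norm = norm.where(norm >= 1.0, other=1.0)
    return norm, factors


def sample_correlation_matrix(
    ds: ExpressionDataset, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample columns.

    Restricted to ``genes`` when given.  Samples with a constant profile
    yield undefined correlations, reported as NaN with a warning; the
    diagonal is exactly 1.
    """
    sub = ds if genes is None else ds.subset_features(genes)
    X = sub.values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    # a column of identical values can have sd ~ eps from summation roundoff
    const = sd <= 1e-12 * np.maximum(1.0, np.abs(X.mean(axis=0)))
    if const.any():
        names = list(sub.samples[const])
        warnings.warn(f"constant sample profiles, correlation undefined: {names}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=sub.samples, columns=sub.samples)


def donorwise_average(
    ds: ExpressionDataset,
    design: SampleDesign,
    conditions: Sequence[str],
    merged_label: str,
) -> tuple[ExpressionDataset, SampleDesign]:
    """Average samples of the given conditions donor-by-donor.

    Public monocyte data distinguishes classical and intermediate
    monocytes; the in-house sets profile only classical ones, so the two
    subsets of each donor are averaged into one column before import and
    relabelled ``merged_label``.  Samples of other conditions pass
    through unchanged.
    """
    design.validate_for(ds)
    tab = design.table.loc[ds.samples]
    merge = tab["condition"].isin(conditions)
    keep_cols = list(ds.samples[~merge.to_numpy()])
    new_cols, new_rows = {}, {}
    for donor, grp in tab[merge].groupby("donor"):
        col = f"{merged_label}_{donor}"
        new_cols[col] = ds.values[grp.index].mean(axis=1)
        row = grp.iloc[0].copy()
        row["condition"] = merged_label
        new_rows[col] = row
    vals = pd.concat([ds.values[keep_cols], pd.DataFrame(new_cols)], axis=1)
    tab_out = pd.concat([tab.loc[keep_cols], pd.DataFrame(new_rows).T])
    tab_out.index.name = tab.index.name
    return replace(ds, values=vals), SampleDesign(tab_out)
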