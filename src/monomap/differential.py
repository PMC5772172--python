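"""Per-gene differential testing, signed fold-changes and DEG selection.

Fold-changes use the signed linear-ratio convention common to microarray
suites: FC = 2**(mA - mB) when group A's log2 mean is the larger, and
-(2**(mB - mA)) otherwise, so |FC| >= 1 always and values never fall in
(-1, 1).

The condition test is a per-gene fixed-effects linear model
``expression ~ condition + covariate`` (covariate = donor or batch, or
none), with an F test on the condition factor.  Mixed-model software
treats donor/batch as random effects; with the balanced designs used
here the fixed-effects F test for condition is the same test, and keeps
the estimator a pair of least-squares fits.  Multiple testing uses
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionDataset, SampleDesign, group_means

__all__ = [
    "DifferentialResult",
    "signed_fold_change",
    "anova_condition_test",
    "bh_fdr",
    "deg_select",
    "deg_test",
    "fc_vs_overall_mean",
]


@dataclass
class DifferentialResult:
    """Per-gene statistics for one contrast.

    ``table`` columns: ``fc`` (signed linear fold-change), ``F``, ``p``,
    ``q`` (BH-adjusted).  ``contrast`` documents what was compared.
    """

    table: pd.DataFrame
    contrast: str = ""

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def _signed_ratio(log2_diff: pd.Series | np.ndarray) -> np.ndarray:
    """Map a log2 mean difference onto the signed linear-ratio scale."""
    d = np.asarray(log2_diff, dtype=float)
    return np.where(d >= 0, 2.0 ** d, -(2.0 ** (-d)))


def signed_fold_change(
    ds: ExpressionDataset, design: SampleDesign, group_a: str, group_b: str
) -> pd.Series:
    """Signed linear fold-change of ``group_a`` versus ``group_b`` per gene."""
    if ds.scale != "log2":
        raise ValueError("signed_fold_change expects log2-scale data")
    a = design.samples_of(group_a)
    b = design.samples_of(group_b)
    a = [s for s in a if s in ds.samples]
    b = [s for s in b if s in ds.samples]
    if not a or not b:
        raise ValueError(f"empty group in contrast {group_a!r} vs {group_b!r}")
    diff = ds.values[a].mean(axis=1) - ds.values[b].mean(axis=1)
    return pd.Series(_signed_ratio(diff), index=ds.genes, name=f"{group_a}_vs_{group_b}")


def _design_matrix(labels: pd.Series) -> np.ndarray:
    """Treatment-coded dummy block (first level dropped)."""
    dummies = pd.get_dummies(labels, drop_first=True, dtype=float)
    return dummies.to_numpy()


def _rss(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares of every row of Y on the column space of X.

    Uses an SVD-based orthonormal basis so rank-deficient design
    matrices (e.g. redundant dummy columns) project correctly.
    """
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    Q = U[:, :rank]
    resid = Y - (Y @ Q) @ Q.T
    return np.einsum("ij,ij->i", resid, resid), rank


def anova_condition_test(
    ds: ExpressionDataset,
    design: SampleDesign,
    covariate: str | None = None,
) -> pd.DataFrame:
    """Per-gene F test for the condition factor.

    Fits ``expression ~ condition (+ covariate)`` by least squares and
    compares against the covariate-only (or intercept-only) model.
    Returns a DataFrame with columns ``F`` and ``p``.  Genes with zero
    residual variance get F = inf and p = 0; designs without residual
    degrees of freedom yield NaN.
    """
    design.validate_for(ds)
    sub = design.table.loc[ds.samples]
    if sub["condition"].nunique() < 2:
        raise ValueError("need at least 2 conditions")
    if covariate is not None and covariate not in sub.columns:
        raise ValueError(f"design has no column {covariate!r}")
    n = len(sub)
    ones = np.ones((n, 1))
    cond_block = _design_matrix(sub["condition"])
    cov_block = _design_matrix(sub[covariate]) if covariate else np.empty((n, 0))
    X_full = np.hstack([ones, cond_block, cov_block])
    X_red = np.hstack([ones, cov_block])

    Y = ds.values.to_numpy(dtype=float)
    rss_full, rank_full = _rss(Y, X_full)
    rss_red, rank_red = _rss(Y, X_red)
    df1 = rank_full - rank_red
    df2 = n - rank_full
    if df1 <= 0:
        raise ValueError("condition factor is confounded with the covariate")

    F = np.full(Y.shape[0], np.nan)
    p = np.full(Y.shape[0], np.nan)
    if df2 > 0:
        # tiny negative rss from fp roundoff is clamped
        rss_full = np.clip(rss_full, 0.0, None)
        delta = np.clip(rss_red - rss_full, 0.0, None)
        scale = np.maximum(np.abs(rss_red), 1.0)
        exact = rss_full <= 1e-12 * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (delta / df1) / (rss_full / df2)
        F[exact & (delta > 0)] = np.inf
        F[exact & (delta <= 1e-12 * scale)] = 0.0
        p = stats.f.sf(F, df1, df2)
        p[np.isinf(F)] = 0.0
    return pd.DataFrame({"F": F, "p": p}, index=ds.genes)


def bh_fdr(p: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q values.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p values, capped
    at 1; NaN p values propagate as NaN without entering the ranking.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[ok] = q
    return out


def deg_test(
    ds: ExpressionDataset,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    covariate: str | None = None,
) -> DifferentialResult:
    """Two-group differential test: signed FC plus ANOVA F/p/q.

    Restricts the data to the two groups, fits the condition (+
    covariate) model there, and attaches the signed fold-change of
    ``group_a`` versus ``group_b``.
    """
    samples = [
        s
        for s in ds.samples
        if design.table.loc[s, "condition"] in (group_a, group_b)
    ]
    sub = ds.subset_samples(samples)
    sub_design = design.subset(samples)
    stats_tab = anova_condition_test(sub, sub_design, covariate=covariate)
    fc = signed_fold_change(sub, sub_design, group_a, group_b)
    tab = stats_tab.assign(fc=fc)[["fc", "F", "p"]]
    tab["q"] = bh_fdr(tab["p"])
    return DifferentialResult(table=tab, contrast=f"{group_a} vs {group_b}")


def deg_select(
    result: DifferentialResult, fc_cut: float = 2.0, q_cut: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split a differential result into up- and down-regulated gene lists.

    A gene is up iff FC >= ``fc_cut`` and q < ``q_cut``; down iff
    FC <= -``fc_cut`` and q < ``q_cut``.  The FC boundary is inclusive,
    the q boundary strict.
    """
    if fc_cut <= 1:
        raise ValueError("fc_cut must exceed 1 (signed-ratio scale)")
    tab = result.table
    sig = tab["q"] < q_cut
    up = list(tab.index[(tab["fc"] >= fc_cut) & sig])
    down = list(tab.index[(tab["fc"] <= -fc_cut) & sig])
    return up, down


def fc_vs_overall_mean(ds: ExpressionDataset, design: SampleDesign) -> pd.DataFrame:
    """Signed FC of each condition's mean against the mean of condition means.

    The overall reference is the unweighted mean over condition-group
    means (not the pooled sample mean), so unbalanced group sizes do not
    tilt it.  Returns a gene x condition table on the signed-ratio
    scale.
    """
    if ds.scale != "log2":
        raise ValueError("fc_vs_overall_mean expects log2-scale data")
    gm = group_means(ds, design)
    overall = gm.mean(axis=1)
    diff = gm.sub(overall, axis=0)
    return pd.DataFrame(_signed_ratio(diff.to_numpy()), index=gm.index, columns=gm.columns)
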