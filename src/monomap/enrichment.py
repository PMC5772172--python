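"""Gene set enrichment analysis with a phenotype-permutation null.

The test asks whether the members of a gene set concentrate at either
end of a ranking of all genes by differential expression between two
phenotype classes:

* ranking metric — signal-to-noise, (mu_A - mu_B) / (sigma_A + sigma_B),
  with each sigma floored at 0.2 * |mu| (0.2 when the mean is zero) so
  low-variance genes cannot dominate;
* enrichment score (ES) — the signed maximum deviation of a weighted
  Kolmogorov-Smirnov running sum: set members ("hits") add
  |metric|**p normalized by the total hit weight, non-members subtract
  1/(N - Nh);
* null distribution — recompute the metric, ranking and ES under
  permuted phenotype labels; when fewer distinct label assignments
  exist than requested permutations, they are enumerated exhaustively
  instead of sampled, avoiding duplicate-permutation bias;
* NES — ES divided by the mean |null ES| of matching sign; the nominal
  p is the same-sign tail fraction, and FDR follows the NES-pooling
  procedure of the canonical tool.

A gene-set permutation mode (random sets of equal size scored on the
observed ranking) is available for designs too small to permute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionDataset

__all__ = [
    "GseaResult",
    "signal_to_noise_ranking",
    "enrichment_score",
    "gsea_permutation",
]


@dataclass
class GseaResult:
    """Per-set enrichment statistics.

    ``table`` columns: ES, NES, p (nominal), q (FDR), size, n_perm;
    ``leading_edge`` maps set name -> the members driving the ES.
    """

    table: pd.DataFrame
    leading_edge: dict[str, list[str]] = field(default_factory=dict)
    permutation_type: str = "phenotype"


def _s2n_metric(Y: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Signal-to-noise for genes x samples ``Y``; ``mask_a`` marks class A.

    Supports a 2-D mask (permutations x samples) and then returns a
    genes x permutations matrix.
    """
    M = np.atleast_2d(mask_a).astype(float)  # P x n
    n_a = M.sum(axis=1)
    n_b = M.shape[1] - n_a
    sum_a = Y @ M.T
    sum_b = Y.sum(axis=1, keepdims=True) - sum_a
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    sq_a = (Y ** 2) @ M.T
    sq_b = (Y ** 2).sum(axis=1, keepdims=True) - sq_a
    # sample variance (ddof=1)
    var_a = (sq_a - n_a * mean_a ** 2) / (n_a - 1)
    var_b = (sq_b - n_b * mean_b ** 2) / (n_b - 1)
    sd_a = np.sqrt(np.clip(var_a, 0.0, None))
    sd_b = np.sqrt(np.clip(var_b, 0.0, None))

    def floor(sd, mean):
        f = 0.2 * np.abs(mean)
        f = np.where(f == 0, 0.2, f)
        return np.maximum(sd, f)

    return (mean_a - mean_b) / (floor(sd_a, mean_a) + floor(sd_b, mean_b))


def signal_to_noise_ranking(
    ds: ExpressionDataset, phenotypes: Mapping[str, str] | pd.Series, classes: tuple[str, str] | None = None
) -> pd.Series:
    """Rank all genes by the signal-to-noise metric, descending.

    ``phenotypes`` labels every sample with one of exactly two classes;
    ``classes`` fixes which is A (numerator first) — default is the two
    labels in sorted order.  Each class needs >= 2 samples.  Ties break
    by gene id so the ordering is deterministic.
    """
    labels = pd.Series(phenotypes).loc[ds.samples]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 phenotype classes, got {uniq}")
    cls_a, cls_b = classes if classes is not None else (uniq[0], uniq[1])
    if {cls_a, cls_b} != set(uniq):
        raise ValueError("classes must name the two phenotype labels")
    if (labels == cls_a).sum() < 2 or (labels == cls_b).sum() < 2:
        raise ValueError("each phenotype class needs at least 2 samples")
    vals = ds.values.sort_index()  # gene-id order fixes tie-breaks
    metric = _s2n_metric(vals.to_numpy(dtype=float), (labels.loc[vals.columns] == cls_a).to_numpy())[:, 0]
    s = pd.Series(metric, index=vals.index, name="s2n")
    order = np.argsort(-s.to_numpy(), kind="stable")
    return s.iloc[order]


def enrichment_score(
    ranked: pd.Series, gene_set: Sequence[str], p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score of a gene set on a ranked list.

    ``ranked`` is the metric indexed by gene, already ordered.  Returns
    (ES, running sum, leading edge).  The leading edge comprises the
    set members at or before the ES extremum for positive ES, and at or
    after it for negative ES.
    """
    members = set(gene_set) & set(ranked.index)
    if not members:
        raise ValueError("gene set is disjoint from the ranked list")
    is_hit = ranked.index.isin(members)
    n = len(ranked)
    n_h = int(is_hit.sum())
    if n_h == n:
        raise ValueError("gene set covers the whole list; ES undefined")
    w = np.abs(ranked.to_numpy(dtype=float)) ** p * is_hit
    hit_cum = np.cumsum(w) / w.sum()
    miss_cum = np.cumsum(~is_hit) / (n - n_h)
    running = hit_cum - miss_cum
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(ranked.index[: i_ext + 1], is_hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.index[i_ext:], is_hit[i_ext:]) if h]
    return es, running, leading


def _es_batch(metric: np.ndarray, genes: pd.Index, membership: np.ndarray, p: float) -> np.ndarray:
    """ES of one gene set for every metric column (genes x P)."""
    order = np.argsort(-metric, axis=0, kind="stable")
    sorted_metric = np.take_along_axis(metric, order, axis=0)
    is_hit = membership[order]
    n, P = metric.shape
    n_h = membership.sum()
    w = np.abs(sorted_metric) ** p * is_hit
    hit_cum = np.cumsum(w, axis=0) / w.sum(axis=0, keepdims=True)
    miss_cum = np.cumsum(~is_hit, axis=0) / (n - n_h)
    running = hit_cum - miss_cum
    idx = np.argmax(np.abs(running), axis=0)
    return running[idx, np.arange(P)]


def _phenotype_masks(labels: np.ndarray, cls_a: str, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null class-A masks: exhaustive when few distinct assignments exist."""
    n = labels.size
    n_a = int((labels == cls_a).sum())
    n_distinct = comb(n, n_a)
    if n_distinct < 2:
        raise ValueError(
            "fewer than 2 distinct label assignments; use gene-set permutation "
            "(permutation_type='gene_set') instead"
        )
    if n_distinct <= n_perm:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, pick in enumerate(combinations(range(n), n_a)):
            masks[i, list(pick)] = True
        return masks
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n_a, replace=False)] = True
    return masks


def gsea_permutation(
    ds: ExpressionDataset,
    phenotypes: Mapping[str, str] | pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    classes: tuple[str, str] | None = None,
    permutation_type: str = "phenotype",
) -> GseaResult:
    """Full GSEA: observed ES, permutation null, NES, nominal p and FDR.

    Phenotype permutation recomputes the signal-to-noise ranking for
    every relabelling; distinct assignments are enumerated exhaustively
    when fewer than ``n_perm`` exist.  Gene-set permutation scores
    random same-size sets against the observed ranking.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if permutation_type not in ("phenotype", "gene_set"):
        raise ValueError("permutation_type must be 'phenotype' or 'gene_set'")
    rng = np.random.default_rng(seed)
    labels = pd.Series(phenotypes).loc[ds.samples]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 phenotype classes, got {uniq}")
    cls_a, _ = classes if classes is not None else (uniq[0], uniq[1])

    vals = ds.values.sort_index()
    genes = vals.index
    Y = vals.to_numpy(dtype=float)
    obs_mask = (labels.loc[vals.columns] == cls_a).to_numpy()
    obs_metric = _s2n_metric(Y, obs_mask)[:, 0]
    obs_order = np.argsort(-obs_metric, kind="stable")
    ranked = pd.Series(obs_metric[obs_order], index=genes[obs_order])

    set_names = list(gene_sets)
    memberships = {}
    for name in set_names:
        memb = genes.isin(set(gene_sets[name]))
        if not memb.any():
            raise ValueError(f"gene set {name!r} is disjoint from the dataset")
        memberships[name] = memb

    # null ES matrix: sets x permutations
    if permutation_type == "phenotype":
        masks = _phenotype_masks(labels.loc[vals.columns].to_numpy(), cls_a, n_perm, rng)
        null_metric = _s2n_metric(Y, masks)  # genes x P
        null_es = np.vstack(
            [_es_batch(null_metric, genes, memberships[nm], weight) for nm in set_names]
        )
    else:
        null_rows = []
        obs_metric_mat = obs_metric[:, None]
        for nm in set_names:
            size = int(memberships[nm].sum())
            es_row = np.empty(n_perm)
            for i in range(n_perm):
                rand = np.zeros(len(genes), dtype=bool)
                rand[rng.choice(len(genes), size=size, replace=False)] = True
                es_row[i] = _es_batch(obs_metric_mat, genes, rand, weight)[0]
            null_rows.append(es_row)
        null_es = np.vstack(null_rows)

    rows, leading_edges, nes_null_pool = [], {}, []
    obs_nes = {}
    for i, nm in enumerate(set_names):
        es, _, leading = enrichment_score(ranked, gene_sets[nm], p=weight)
        leading_edges[nm] = leading
        null = null_es[i]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        if same.size:
            p_nom = float((np.abs(same) >= abs(es)).mean())
        else:
            p_nom = 1.0 / (null.size + 1)
        # normalize this set's null ES the same way, for the FDR pool
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        nes_null_pool.append(null_nes[np.isfinite(null_nes)])
        obs_nes[nm] = nes
        rows.append((nm, es, nes, p_nom, int(memberships[nm].sum()), null.size))

    tab = pd.DataFrame(rows, columns=["set", "ES", "NES", "p", "size", "n_perm"]).set_index("set")
    tab["q"] = _gsea_fdr(tab["NES"].to_numpy(), np.concatenate(nes_null_pool) if nes_null_pool else np.array([]))
    tab = tab[["ES", "NES", "p", "q", "size", "n_perm"]]
    return GseaResult(table=tab, leading_edge=leading_edges, permutation_type=permutation_type)


def _gsea_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """FDR q per the NES-pooling convention, capped at 1."""
    q = np.full(obs_nes.shape, np.nan)
    finite = np.isfinite(obs_nes)
    for i in np.flatnonzero(finite):
        nes = obs_nes[i]
        if nes >= 0:
            null_tail = (null_nes >= nes).sum()
            null_side = (null_nes >= 0).sum()
            obs_tail = (obs_nes[finite] >= nes).sum()
            obs_side = (obs_nes[finite] >= 0).sum()
        else:
            null_tail = (null_nes <= nes).sum()
            null_side = (null_nes < 0).sum()
            obs_tail = (obs_nes[finite] <= nes).sum()
            obs_side = (obs_nes[finite] < 0).sum()
        if null_side == 0 or obs_side == 0 or obs_tail == 0:
            q[i] = np.nan
            continue
        q[i] = min(1.0, (null_tail / null_side) / (obs_tail / obs_side))
    return q
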