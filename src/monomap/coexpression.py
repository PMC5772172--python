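"""Correlation-threshold co-expression graphs and condition clusters.

A co-expression graph connects two genes when the Pearson correlation of
their expression profiles reaches a threshold; genes without any edge
are dropped, and connected components below a minimum size are pruned.
By default the correlation is computed on the linear (anti-log2) scale,
matching how such networks are usually drawn from microarray data.

Condition clusters arise by overlaying, per gene, the fold-change of
each condition against the overall mean: a node is assigned to the
condition of its maximal fold-change provided that fold-change reaches
a membership threshold (1.5 by default); nodes below it stay
unlabelled.  For time-course data, the genes qualifying at two
consecutive time points form the overlap sets that trace response waves
travelling through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionDataset

__all__ = [
    "CoexpressionGraph",
    "build_coexpression_graph",
    "assign_condition_clusters",
    "consecutive_timepoint_overlap",
    "master_regulator_postfilter",
]


@dataclass
class CoexpressionGraph:
    """Thresholded correlation graph with component labels and overlays."""

    graph: nx.Graph
    r_min: float
    min_component: int
    fc_overlay: pd.DataFrame | None = None      # gene x condition signed FC
    condition_labels: pd.Series | None = None   # node -> condition (or NaN)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def component_of(self) -> pd.Series:
        lab = {}
        for i, comp in enumerate(sorted(self.components, key=lambda c: (-len(c), min(c)))):
            for g in comp:
                lab[g] = i
        return pd.Series(lab, name="component").sort_index()

    def edge_list(self) -> pd.DataFrame:
        rows = [(u, v, d["r"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])


def build_coexpression_graph(
    ds: ExpressionDataset,
    genes: Sequence[str] | None = None,
    r_min: float = 0.93,
    min_component: int = 5,
    scale: str = "linear",
) -> CoexpressionGraph:
    """Connect genes whose profile correlation reaches ``r_min``.

    Computes all-pairs Pearson correlations between gene profiles on
    the requested scale, keeps edges with r >= ``r_min`` (boundary
    included), drops edgeless genes, then removes connected components
    with fewer than ``min_component`` nodes.  Genes with constant
    profiles have undefined correlation and are excluded up front.
    """
    if scale not in ("linear", "log2"):
        raise ValueError("scale must be 'linear' or 'log2'")
    if len(ds.samples) < 3:
        raise ValueError("need at least 3 samples for meaningful correlations")
    sub = ds if genes is None else ds.subset_features(pd.Index(genes).intersection(ds.genes))
    sub = sub.to_linear() if scale == "linear" else sub.to_log2()
    X = sub.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    ok = sd > 0
    if not ok.all():
        import warnings

        warnings.warn(
            f"{int((~ok).sum())} constant gene profiles excluded (undefined correlation)",
            stacklevel=2,
        )
    gene_ids = sub.genes[ok]
    corr = np.corrcoef(X[ok])
    corr = np.atleast_2d(corr)
    G = nx.Graph()
    iu, ju = np.where(np.triu(corr >= r_min, k=1))
    for i, j in zip(iu, ju):
        G.add_edge(gene_ids[i], gene_ids[j], r=float(corr[i, j]))
    for comp in list(nx.connected_components(G)):
        if len(comp) < min_component:
            G.remove_nodes_from(comp)
    return CoexpressionGraph(graph=G, r_min=r_min, min_component=min_component)


def assign_condition_clusters(
    cg: CoexpressionGraph,
    fc_overlay: pd.DataFrame,
    condition_order: Sequence[str],
    fc_min: float = 1.5,
) -> pd.Series:
    """Label every node with the condition of its maximal fold-change.

    ``fc_overlay`` is a gene x condition table of signed fold-changes
    against the overall mean.  A node gets the condition of its largest
    FC provided that FC >= ``fc_min``; otherwise it stays unlabelled
    (NaN).  Ties take the earliest condition in ``condition_order``.
    The labels are stored on the graph object and returned.
    """
    missing_cond = [c for c in condition_order if c not in fc_overlay.columns]
    if missing_cond:
        raise ValueError(f"conditions missing from the FC overlay: {missing_cond}")
    nodes = cg.nodes
    missing_nodes = [g for g in nodes if g not in fc_overlay.index]
    if missing_nodes:
        raise ValueError(f"FC overlay lacks nodes: {missing_nodes[:5]}")
    sub = fc_overlay.loc[nodes, list(condition_order)]
    arr = sub.to_numpy(dtype=float)
    best = np.argmax(arr, axis=1)  # first max wins -> earliest condition on ties
    best_fc = arr[np.arange(len(nodes)), best]
    labels = pd.Series(
        [condition_order[b] if fc >= fc_min else np.nan for b, fc in zip(best, best_fc)],
        index=pd.Index(nodes, name="gene"),
        name="condition",
    )
    cg.fc_overlay = sub
    cg.condition_labels = labels
    return labels


def consecutive_timepoint_overlap(
    fc_overlay: pd.DataFrame,
    time_order: Sequence[str],
    fc_min: float = 1.5,
) -> tuple[dict[tuple[str, str], list[str]], dict[str, list[str]]]:
    """Genes shared between the clusters of consecutive time points.

    A gene belongs to time point t's cluster when its FC against the
    overall mean at t reaches ``fc_min``.  Returns the overlap set of
    every adjacent pair and, per time point, the genes exclusive to it
    (qualifying there and at no other time point).
    """
    if len(time_order) < 2:
        raise ValueError("need at least 2 ordered time points")
    missing = [t for t in time_order if t not in fc_overlay.columns]
    if missing:
        raise ValueError(f"time points missing from the FC overlay: {missing}")
    member = {t: set(fc_overlay.index[fc_overlay[t] >= fc_min]) for t in time_order}
    overlaps = {
        (a, b): sorted(member[a] & member[b])
        for a, b in zip(time_order[:-1], time_order[1:])
    }
    exclusive = {}
    for t in time_order:
        others = set().union(*(member[o] for o in time_order if o != t))
        exclusive[t] = sorted(member[t] - others)
    return overlaps, exclusive


def master_regulator_postfilter(
    candidates: pd.DataFrame, nes_min: float = 3.0
) -> pd.DataFrame:
    """Filter externally predicted regulators: NES >= cutoff, then uniqueness.

    ``candidates`` needs columns ``regulator``, ``cell_type`` and
    ``NES``.  Rows below ``nes_min`` are dropped first (the boundary is
    kept); regulators that survive for more than one cell type are then
    removed entirely, leaving only cell-type-unique predictions.
    """
    required = {"regulator", "cell_type", "NES"}
    if not required.issubset(candidates.columns):
        raise ValueError(f"candidate table needs columns {sorted(required)}")
    passed = candidates[candidates["NES"] >= nes_min]
    counts = passed.groupby("regulator")["cell_type"].nunique()
    unique_regs = set(counts.index[counts == 1])
    return passed[passed["regulator"].isin(unique_regs)].reset_index(drop=True)
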