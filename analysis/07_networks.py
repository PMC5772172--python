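#!/usr/bin/env python
"""Co-expression networks: condition clusters on the array study and
consecutive-time-point overlaps on the count time course."""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from context import (
    CLUSTER_BLOCKS,
    CONDITIONS,
    DATA,
    RESULTS,
    TIME_COURSE,
    ensure_dirs,
)

from monomap import coexpression as cx
from monomap import differential as dd
from monomap import io as mio
from monomap import preprocess as pp
from monomap.containers import ExpressionDataset


def main() -> None:
    ensure_dirs()
    # --- condition clusters on the array study -------------------------
    ds = mio.read_matrix_tsv(DATA / "platformA_corrected.tsv", platform="A")
    design = mio.read_design_tsv(DATA / "design.tsv").subset(list(ds.samples))
    block_genes = [g for genes in CLUSTER_BLOCKS.values() for g in genes]
    graph = cx.build_coexpression_graph(
        ds, genes=block_genes, r_min=0.6, min_component=5, scale="linear"
    )
    fc = dd.fc_vs_overall_mean(ds, design)
    labels = cx.assign_condition_clusters(graph, fc, CONDITIONS, fc_min=1.5)
    graph.edge_list().to_csv(RESULTS / "coexpression_edges.tsv", sep="\t", index=False)
    labels.to_csv(RESULTS / "condition_clusters.tsv", sep="\t")
    truth_map = {g: c for c, genes in CLUSTER_BLOCKS.items() for g in genes}
    labelled = labels.dropna()
    acc = np.mean([truth_map[g] == lab for g, lab in labelled.items()])
    print(
        f"array network: {len(graph.nodes)} nodes, "
        f"{graph.graph.number_of_edges()} edges, "
        f"{len(graph.components)} components"
    )
    print(f"condition-cluster labels: {len(labelled)} assigned, accuracy {acc:.2f}")

    # --- time-course network and overlaps ------------------------------
    counts = mio.read_matrix_tsv(DATA / "timecourse_counts.tsv", scale="linear").values
    tc_design = mio.read_design_tsv(DATA / "timecourse_design.tsv")
    norm, factors = pp.size_factors_and_filter(counts.astype(float), tc_design, min_mean=10)
    log_ds = ExpressionDataset(np.log2(norm), scale="log2")
    fc_tc = dd.fc_vs_overall_mean(log_ds, tc_design)
    tps = list(TIME_COURSE.time_points)
    overlaps, exclusive = cx.consecutive_timepoint_overlap(fc_tc, tps, fc_min=1.5)
    truth = mio.read_truth_json(DATA / "truth_timecourse.json")
    summary = {}
    for (a, b), genes in overlaps.items():
        truth_ov = len(set(truth["clusters"][a]) & set(truth["clusters"][b]))
        summary[f"{a}->{b}"] = {"recovered": len(genes), "planted": truth_ov}
        print(f"overlap {a} -> {b}: {len(genes)} genes (planted {truth_ov})")
    for t in tps:
        print(f"exclusive to {t}: {len(exclusive[t])} genes")
    with open(RESULTS / "timecourse_overlaps.json", "w") as fh:
        json.dump(summary, fh, indent=1)


if __name__ == "__main__":
    main()
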