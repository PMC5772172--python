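"""End-to-end recovery and calibration benchmarks on planted truth.

Each function simulates a study with the synthetic-data generators, runs
the corresponding pipeline stage, and scores the result against the
recorded truth.  They are the package's own accuracy report: the tests
assert bounds on them, the analysis drivers print them, and the
acceptance script serializes them.

All benchmarks take a single integer seed; derived seeds stay below
2**31.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import coexpression as cx
from . import deconvolution as dc
from . import differential as dd
from . import enrichment as en
from . import identity as idm
from . import preprocess as pp
from .containers import ExpressionDataset
from .simulate import (
    PlantedSignal,
    SimulationConfig,
    TimeCourseConfig,
    simulate_expression_study,
    simulate_gene_sets,
    simulate_mixtures,
    simulate_time_course_counts,
)

__all__ = [
    "deg_recovery",
    "identity_recovery",
    "deconvolution_recovery",
    "cluster_label_accuracy",
    "bridge_shift_error",
    "size_factor_recovery",
    "timecourse_overlap_recovery",
    "gsea_planted_p",
    "null_deg_empty_fraction",
    "gsea_null_calibration",
]

_MOD = 2**31 - 1


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % _MOD


def deg_recovery(seed: int, n_genes: int = 200, n_planted: int = 20) -> dict:
    """Recall of planted +2 log2 effects (n=3/group, sd 0.25) at FC>=2, q<0.05."""
    planted = tuple(f"G{i:04d}" for i in range(1, n_planted + 1))
    cfg = SimulationConfig(
        n_genes=n_genes,
        groups=[("MO", 3), ("IL4", 3)],
        noise_sd=0.25,
        planted=[PlantedSignal(planted, ("IL4",), 2.0)],
        seed=seed,
    )
    (ds, _), design, truth = simulate_expression_study(cfg)
    res = dd.deg_test(ds, design.subset(list(ds.samples)), "IL4", "MO")
    up, _ = dd.deg_select(res, fc_cut=2.0, q_cut=0.05)
    hits = len(set(truth.planted_genes("IL4")) & set(up))
    return {"recall": hits / n_planted, "n_up": len(up), "n": n_genes}


def identity_recovery(seed: int, n_genes: int = 2000, n_planted: int = 25) -> dict:
    """Precision/recall of shared identity genes: 25 matched 4-group
    patterns (+1 log2, sd 0.2) among 2,000 background genes."""
    planted = tuple(f"G{i:04d}" for i in range(1, n_planted + 1))
    groups = ["infDC", "DC", "Mac", "MO"]
    cfg = SimulationConfig(
        n_genes=n_genes,
        groups=[(g, 3) for g in groups],
        noise_sd=0.2,
        planted=[PlantedSignal(planted, ("infDC",), 1.0, shared_across_datasets=True)],
        seed=seed,
    )
    (dsa, dsb), design, truth = simulate_expression_study(cfg)
    ha, hb = idm.harmonize_genes(dsa, dsb)
    grouping = {g: g for g in groups}
    pa = idm.group_mean_profiles(ha, design.subset(list(ha.samples)), grouping, groups)
    pb = idm.group_mean_profiles(hb, design.subset(list(hb.samples)), grouping, groups)
    out = idm.shared_identity_genes(pa, pb, "infDC", "infDC", r_min=0.4, fc_min=1.3)
    got = set(out.index)
    tp = len(got & set(planted))
    return {
        "precision": tp / len(got) if got else 0.0,
        "recall": tp / n_planted,
        "n_found": len(got),
        "n": n_genes,
    }


def _marker_basis(rng: np.random.Generator, n_genes: int = 100, n_types: int = 5) -> dc.SignatureBasis:
    genes = [f"g{i:03d}" for i in range(n_genes)]
    types = [f"T{t + 1}" for t in range(n_types)]
    per = n_genes // (n_types + 1)
    B = pd.DataFrame(rng.uniform(20, 200, size=(n_genes, n_types)), index=genes, columns=types)
    for t in range(n_types):
        B.iloc[t * per : (t + 1) * per, t] *= 10
    return dc.SignatureBasis(B)


def deconvolution_recovery(seed: int, n_mixtures: int = 50) -> dict:
    """Mean per-sample RMSE of nu-SVR fractions on noisy 5-type mixtures
    (noise sd = 0.1 x basis mean)."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    basis = _marker_basis(rng)
    fractions = pd.DataFrame(
        rng.dirichlet(np.ones(len(basis.cell_types)), size=n_mixtures),
        index=[f"m{i}" for i in range(n_mixtures)],
        columns=basis.cell_types,
    )
    noise_sd = 0.1 * basis.matrix.to_numpy().mean()
    mix, truth = simulate_mixtures(basis, fractions, noise_sd=noise_sd, seed=_sub_seed(seed, 2))
    res = dc.svr_fractions(mix, basis)
    rmse = np.sqrt(((res.fractions - truth) ** 2).mean(axis=1))
    return {"rmse_mean": float(rmse.mean()), "rmse_max": float(rmse.max()), "n": n_mixtures}


def cluster_label_accuracy(seed: int, genes_per_cluster: int = 40) -> dict:
    """Condition-cluster label accuracy on planted +1.5 log2 blocks."""
    conds = ["c1", "c2", "c3", "c4"]
    planted = [
        PlantedSignal(
            tuple(f"G{i + genes_per_cluster * j:04d}" for i in range(1, genes_per_cluster + 1)),
            (conds[j],),
            1.5,
        )
        for j in range(4)
    ]
    cfg = SimulationConfig(
        n_genes=10 * genes_per_cluster,
        groups=[(c, 3) for c in conds],
        noise_sd=0.3,
        planted=planted,
        seed=seed,
    )
    (ds, _), design, _ = simulate_expression_study(cfg)
    design = design.subset(list(ds.samples))
    all_planted = [g for sig in planted for g in sig.genes]
    graph = cx.build_coexpression_graph(
        ds, genes=all_planted, r_min=0.6, min_component=5, scale="linear"
    )
    fc = dd.fc_vs_overall_mean(ds, design)
    labels = cx.assign_condition_clusters(graph, fc, conds, fc_min=1.5).dropna()
    truth_map = {g: sig.conditions[0] for sig in planted for g in sig.genes}
    acc = float(np.mean([truth_map[g] == lab for g, lab in labels.items()])) if len(labels) else 0.0
    return {"accuracy": acc, "n_labelled": int(len(labels)), "n": len(all_planted)}


def bridge_shift_error(seed: int, n_genes: int = 100) -> dict:
    """Max |residual batch offset| after bridge correction at zero noise."""
    cfg = SimulationConfig(
        n_genes=n_genes,
        groups=[("MO", 2), ("X", 2)],
        noise_sd=0.0,
        batch_shift_sd=1.5,
        n_batches=2,
        seed=seed,
    )
    (ds, _), design, truth = simulate_expression_study(cfg)
    design = design.subset(list(ds.samples))
    corrected = pp.bridge_batch_correct(ds, design, "MO")
    # after correction, per-gene bridge means must agree across batches
    err = 0.0
    tab = design.table
    bridge = tab.index[tab["condition"] == "MO"]
    per_batch = {
        b: corrected.values[list(grp.index.intersection(bridge))].mean(axis=1)
        for b, grp in tab.groupby("batch")
    }
    batches = list(per_batch)
    for b in batches[1:]:
        err = max(err, float((per_batch[b] - per_batch[batches[0]]).abs().max()))
    return {"max_error": err, "n": n_genes}


def size_factor_recovery(seed: int) -> dict:
    """Relative error of median-of-ratios factors on planted library sizes."""
    sf_true = [1.0] * 3 + [2.0] * 3 + [4.0] * 3 + [1.0] * 3
    cfg = TimeCourseConfig(n_genes=800, size_factors=sf_true, frac_low=0.0)
    counts, design, truth = simulate_time_course_counts(cfg, seed=seed)
    _, factors = pp.size_factors_and_filter(counts.astype(float), design, min_mean=0)
    got = factors.to_numpy()
    got = got / np.exp(np.mean(np.log(got)))  # normalize geometric mean to 1
    want = np.asarray(sf_true) / np.exp(np.mean(np.log(sf_true)))
    rel = np.abs(got - want) / want
    return {"max_rel_error": float(rel.max()), "n": len(sf_true)}


def timecourse_overlap_recovery(seed: int) -> dict:
    """Recovered consecutive-time-point overlap vs the planted fraction 0.5."""
    cfg = TimeCourseConfig(
        n_genes=1500, cluster_size=60, overlap_fraction=0.5, effect=4.0, frac_low=0.0
    )
    counts, design, truth = simulate_time_course_counts(cfg, seed=seed)
    norm, _ = pp.size_factors_and_filter(counts.astype(float), design, min_mean=10)
    ds = ExpressionDataset(np.log2(norm), scale="log2")
    fc = dd.fc_vs_overall_mean(ds, design)
    tps = list(cfg.time_points)
    overlaps, _ = cx.consecutive_timepoint_overlap(fc, tps, fc_min=1.5)
    fracs = []
    for a, b in zip(tps[:-1], tps[1:]):
        member_a = set(fc.index[fc[a] >= 1.5])
        fracs.append(len(overlaps[(a, b)]) / max(len(member_a), 1))
    err = max(abs(f - cfg.overlap_fraction) for f in fracs)
    return {"max_abs_error": float(err), "fractions": fracs, "n": cfg.n_genes}


def gsea_planted_p(seed: int) -> dict:
    """Nominal p of a set of planted phenotype-associated genes
    (+1.5 log2, 5 vs 5 samples, 100 background genes)."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    vals = rng.normal(8, 1, size=(100, 10))
    vals[:15, :5] += 1.5
    ds = ExpressionDataset(
        pd.DataFrame(vals, index=[f"g{i:03d}" for i in range(100)],
                     columns=[f"s{i}" for i in range(10)])
    )
    pheno = pd.Series(["A"] * 5 + ["B"] * 5, index=ds.samples)
    sets, name = simulate_gene_sets(
        list(ds.genes), 3, 15, enriched_genes=[f"g{i:03d}" for i in range(15)],
        seed=_sub_seed(seed, 4),
    )
    res = en.gsea_permutation(ds, pheno, sets, n_perm=1000, seed=_sub_seed(seed, 5), classes=("A", "B"))
    return {
        "p": float(res.table.loc[name, "p"]),
        "nes": float(res.table.loc[name, "NES"]),
        "n": 100,
    }


def null_deg_empty_fraction(seed: int, n_seeds: int = 100) -> dict:
    """Fraction of null simulations (no planted effect) whose DEG lists
    are empty at FC 2 / q 0.05."""
    empty = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_genes=200, groups=[("A", 3), ("B", 3)], noise_sd=0.25,
            seed=_sub_seed(seed, 10 + k),
        )
        (ds, _), design, _ = simulate_expression_study(cfg)
        res = dd.deg_test(ds, design.subset(list(ds.samples)), "A", "B")
        up, down = dd.deg_select(res, fc_cut=2.0, q_cut=0.05)
        if not up and not down:
            empty += 1
    return {"empty_fraction": empty / n_seeds, "n": n_seeds}


def gsea_null_calibration(seed: int, n_seeds: int = 50) -> dict:
    """Kolmogorov distance between null GSEA nominal p values and the
    uniform distribution, over independent null simulations."""
    ps = []
    for k in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 100 + k))
        vals = rng.normal(8, 1, size=(60, 10))
        ds = ExpressionDataset(
            pd.DataFrame(vals, index=[f"g{i:03d}" for i in range(60)],
                         columns=[f"s{i}" for i in range(10)])
        )
        pheno = pd.Series(["A"] * 5 + ["B"] * 5, index=ds.samples)
        members = [f"g{i:03d}" for i in rng.choice(60, size=10, replace=False)]
        res = en.gsea_permutation(
            ds, pheno, {"S": members}, n_perm=252, seed=_sub_seed(seed, 200 + k),
            classes=("A", "B"),
        )
        ps.append(float(res.table["p"].iloc[0]))
    ps_sorted = np.sort(ps)
    grid = np.arange(1, len(ps_sorted) + 1) / len(ps_sorted)
    ks = float(np.max(np.abs(ps_sorted - grid)))
    return {"ks_distance": ks, "bound": 1.63 / np.sqrt(n_seeds), "n": n_seeds}
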