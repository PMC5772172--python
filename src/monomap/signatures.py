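"""Bespoke gene-list constructions for monocyte-derived cell biology.

Five list-building procedures recur throughout the analysis:

* the common monocyte-derived signature — genes consistently induced or
  repressed in every derived-cell condition versus blood monocytes,
  with a pairwise fold-change consistency filter across the derived
  conditions;
* subset-specific surface markers — genes whose fold-change against
  every other cell type clears a cutoff, restricted to a surfaceome
  universe;
* pattern-recognition-receptor profiles — receptor genes with at least
  one derived-vs-monocyte |FC| at or above a cutoff;
* the IL-4 meta-signature — genes up (or down) after IL-4 exposure in
  at least two of three independent datasets;
* the time-resolved transcriptional-regulator filter — regulators
  induced by IL-4 at both early and late time points, over both the
  monocyte and the GM-CSF-only reference.

Each returned :class:`GeneSignature` carries provenance sufficient to
replay the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, SampleDesign, group_means
from .differential import DifferentialResult, signed_fold_change

__all__ = [
    "GeneSignature",
    "common_monocyte_derived_signature",
    "subset_specific_markers",
    "prr_regulated",
    "il4_meta_signature",
    "tr_specific_candidates",
]


@dataclass
class GeneSignature:
    induced: list[str]
    repressed: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clash = set(self.induced) & set(self.repressed)
        if clash:
            raise ValueError(f"genes in both directions: {sorted(clash)[:5]}")

    def as_gmt(self, name: str) -> dict[str, list[str]]:
        return {f"{name}_UP": sorted(self.induced), f"{name}_DOWN": sorted(self.repressed)}


def common_monocyte_derived_signature(
    deg_pairs: Sequence[tuple[list[str], list[str]]],
    ds: ExpressionDataset,
    design: SampleDesign,
    derived_conditions: Sequence[str],
    consistency_fc: float = 1.7,
) -> GeneSignature:
    """Intersect per-contrast DEG lists, then enforce expression consistency.

    Parameters
    ----------
    deg_pairs
        (up, down) gene lists from the contrasts of each derived-cell
        condition versus the shared monocyte reference.
    derived_conditions
        The derived-cell groups whose pairwise group-mean ratios must
        all stay <= ``consistency_fc`` for a gene to survive (strict
        ``>`` drops it).
    """
    if len(deg_pairs) < 2:
        raise ValueError("need at least 2 contrasts to intersect")
    up = set(deg_pairs[0][0])
    down = set(deg_pairs[0][1])
    for u, d in deg_pairs[1:]:
        up &= set(u)
        down &= set(d)

    gm = group_means(ds, design)[list(derived_conditions)]

    def consistent(genes: set[str]) -> list[str]:
        keep = []
        for g in sorted(genes):
            means = gm.loc[g]
            max_ratio = max(
                2.0 ** abs(means[a] - means[b]) for a, b in combinations(means.index, 2)
            )
            if not max_ratio > consistency_fc:
                keep.append(g)
        return keep

    prov = {
        "n_contrasts": len(deg_pairs),
        "pre_filter": {"up": sorted(up), "down": sorted(down)},
        "consistency_fc": consistency_fc,
        "derived_conditions": list(derived_conditions),
    }
    return GeneSignature(induced=consistent(up), repressed=consistent(down), provenance=prov)


def subset_specific_markers(
    ds: ExpressionDataset,
    design: SampleDesign,
    target: str,
    others: Sequence[str],
    universe: Sequence[str] | None = None,
    fc_cut: float = 2.0,
    exclude: Sequence[str] | None = None,
    exclude_prefixes: Sequence[str] = (),
) -> list[str]:
    """Genes specific to ``target``: FC against every other group > ``fc_cut``.

    When a ``universe`` (e.g. the present surfaceome) is given the scan
    is restricted to it first.  ``exclude`` removes named genes and
    ``exclude_prefixes`` drops symbol families (e.g. ``HLA-``) last.
    """
    if target in others:
        raise ValueError("target group also listed among the others")
    genes = ds.genes if universe is None else ds.genes.intersection(universe)
    sub = ds.subset_features(genes)
    keep = pd.Series(True, index=sub.genes)
    for other in others:
        fc = signed_fold_change(sub, design, target, other)
        keep &= fc > fc_cut
    out = [g for g in sub.genes[keep.to_numpy()]]
    if exclude:
        drop = set(exclude)
        out = [g for g in out if g not in drop]
    for pref in exclude_prefixes:
        out = [g for g in out if not g.startswith(pref)]
    return out


def prr_regulated(
    ds: ExpressionDataset,
    design: SampleDesign,
    derived_groups: Sequence[str],
    reference: str,
    prr_genes: Sequence[str],
    fc_cut: float = 2.0,
) -> pd.DataFrame:
    """Receptor genes with at least one derived-vs-reference |FC| >= cutoff.

    Returns the retained genes' per-group signed fold-changes (columns =
    derived groups), plus per-replicate fold-changes against the
    reference mean in columns named ``<sample>``; boundaries are
    inclusive on both sides (>= fc_cut or <= -fc_cut).
    """
    if not len(prr_genes):
        raise ValueError("empty receptor gene list")
    present = ds.genes.intersection(prr_genes)
    sub = ds.subset_features(present)
    fcs = pd.DataFrame(
        {g: signed_fold_change(sub, design, g, reference) for g in derived_groups}
    )
    keep = ((fcs >= fc_cut) | (fcs <= -fc_cut)).any(axis=1)
    fcs = fcs.loc[keep.to_numpy()]
    # per-replicate FCs of the derived samples vs the reference group mean
    ref_mean = sub.values[design.samples_of(reference)].mean(axis=1)
    rep_cols = {}
    for g in derived_groups:
        for s in design.samples_of(g):
            if s in sub.samples:
                d = (sub.values[s] - ref_mean).loc[fcs.index]
                rep_cols[s] = np.where(d >= 0, 2.0 ** d, -(2.0 ** (-d)))
    reps = pd.DataFrame(rep_cols, index=fcs.index)
    return pd.concat([fcs, reps], axis=1)


def il4_meta_signature(
    dataset_degs: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    min_datasets: int = 2,
) -> GeneSignature:
    """Genes induced (or repressed) by IL-4 in >= ``min_datasets`` datasets.

    Each dataset contributes one (up, down) pair.  A gene qualifying for
    both directions is contradictory evidence; such genes go into the
    provenance ``conflicts`` list and into neither signature half.
    """
    if len(dataset_degs) < 2:
        raise ValueError("need at least 2 datasets")
    up_count: dict[str, int] = {}
    down_count: dict[str, int] = {}
    for up, down in dataset_degs.values():
        for g in set(up):
            up_count[g] = up_count.get(g, 0) + 1
        for g in set(down):
            down_count[g] = down_count.get(g, 0) + 1
    induced = {g for g, c in up_count.items() if c >= min_datasets}
    repressed = {g for g, c in down_count.items() if c >= min_datasets}
    conflicts = induced & repressed
    prov = {
        "datasets": list(dataset_degs),
        "min_datasets": min_datasets,
        "conflicts": sorted(conflicts),
    }
    return GeneSignature(
        induced=sorted(induced - conflicts),
        repressed=sorted(repressed - conflicts),
        provenance=prov,
    )


def tr_specific_candidates(
    ds: ExpressionDataset,
    design: SampleDesign,
    tr_genes: Sequence[str],
    il4_early: str,
    il4_late: str,
    gmcsf: str,
    reference: str,
    fc: float = 1.5,
) -> pd.DataFrame:
    """Transcriptional regulators specifically induced by IL-4 over time.

    Keeps regulators satisfying all five conditions: FC(early vs ref) >
    ``fc``, FC(late vs ref) > ``fc``, FC(early vs GM-CSF) > ``fc``,
    FC(late vs GM-CSF) > ``fc`` and FC(GM-CSF vs ref) > 1 — i.e. IL-4
    induction beyond the GM-CSF-only state at both time points, with
    GM-CSF itself not below the reference.  Rows are ordered by mean
    expression in the early IL-4 condition, descending.
    """
    for cond in (il4_early, il4_late, gmcsf, reference):
        if cond not in design.conditions:
            raise ValueError(f"condition {cond!r} missing from the design")
    present = ds.genes.intersection(tr_genes)
    sub = ds.subset_features(present)
    tab = pd.DataFrame(
        {
            "early_vs_ref": signed_fold_change(sub, design, il4_early, reference),
            "late_vs_ref": signed_fold_change(sub, design, il4_late, reference),
            "early_vs_gmcsf": signed_fold_change(sub, design, il4_early, gmcsf),
            "late_vs_gmcsf": signed_fold_change(sub, design, il4_late, gmcsf),
            "gmcsf_vs_ref": signed_fold_change(sub, design, gmcsf, reference),
        }
    )
    keep = (
        (tab["early_vs_ref"] > fc)
        & (tab["late_vs_ref"] > fc)
        & (tab["early_vs_gmcsf"] > fc)
        & (tab["late_vs_gmcsf"] > fc)
        & (tab["gmcsf_vs_ref"] > 1)
    )
    tab = tab.loc[keep.to_numpy()].copy()
    tab["early_expression"] = sub.values.loc[tab.index, design.samples_of(il4_early)].mean(axis=1)
    return tab.sort_values("early_expression", ascending=False, kind="mergesort")
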