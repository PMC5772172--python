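"""Synthetic expression studies with recorded ground truth.

Every downstream stage of the pipeline (batch correction, differential
testing, signature construction, identity mapping, deconvolution,
enrichment, network clustering) is exercised against data produced here,
so each generator emits the planted truth alongside the data:

* :func:`simulate_expression_study` — a two-platform microarray-style
  study: log2-normal noise, additive per-gene per-batch shifts, a bridge
  condition present in every batch, and planted condition-specific
  signals that may be shared across the two platforms.
* :func:`simulate_mixtures` — linear-scale convex mixtures of a cell-type
  basis for deconvolution benchmarks.
* :func:`simulate_time_course_counts` — a negative-binomial count matrix
  over ordered time-point conditions with planted condition clusters that
  overlap between consecutive time points by a configured fraction.
* :func:`simulate_gene_sets` — random gene sets plus one set enriched
  among planted-effect genes, for enrichment calibration.

All randomness flows from a single integer seed per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, SampleDesign

__all__ = [
    "PlantedSignal",
    "SimulationConfig",
    "TimeCourseConfig",
    "SyntheticTruth",
    "simulate_expression_study",
    "simulate_mixtures",
    "simulate_time_course_counts",
    "simulate_gene_sets",
]


@dataclass(frozen=True)
class PlantedSignal:
    """A set of genes elevated (or suppressed) in target conditions.

    ``effect`` is a log2 offset added to every sample of every target
    condition.  ``shared_across_datasets`` plants the same signal in both
    platforms of a two-platform study, which makes the genes recoverable
    by cross-dataset profile correlation.
    """

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    effect: float
    shared_across_datasets: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("planted effect size must be finite")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids within a planted signal must be unique")


@dataclass
class SimulationConfig:
    """Design of a two-platform expression study.

    ``groups`` lists (condition, n_donors) pairs; every condition appears
    in both platforms with its own donors.  Donor-samples of each
    condition are distributed round-robin over ``n_batches`` batches, so
    the bridge condition needs at least ``n_batches`` donors.
    """

    n_genes: int
    groups: Sequence[tuple[str, int]]
    baseline_mean: float = 8.0          # log2 units
    baseline_gene_sd: float = 0.0       # per-gene baseline spread (log2)
    noise_sd: float = 0.25              # log2 units
    batch_shift_sd: float = 0.0         # sd of per-gene per-batch shifts
    n_batches: int = 1
    bridge_condition: str | None = None  # defaults to the first group
    gene_overlap: float = 1.0           # fraction of genes shared by the platforms
    planted: Sequence[PlantedSignal] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.groups:
            raise ValueError("at least one condition group required")
        if self.bridge_condition is None:
            self.bridge_condition = self.groups[0][0]
        conds = [c for c, _ in self.groups]
        if self.bridge_condition not in conds:
            raise ValueError(f"bridge condition {self.bridge_condition!r} not among groups")
        n_planted = len({g for sig in self.planted for g in sig.genes})
        if self.n_genes < n_planted:
            raise ValueError("n_genes must cover all planted genes")
        if not 0 < self.gene_overlap <= 1:
            raise ValueError("gene_overlap must be in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside simulated data."""

    planted: tuple[PlantedSignal, ...] = ()
    batch_shifts: dict[str, pd.DataFrame] = field(default_factory=dict)
    mixture_fractions: pd.DataFrame | None = None
    dispersion: float | None = None
    clusters: dict[str, list[str]] = field(default_factory=dict)
    size_factors: pd.Series | None = None

    def planted_genes(self, condition: str | None = None) -> list[str]:
        out: list[str] = []
        for sig in self.planted:
            if condition is None or condition in sig.conditions:
                out.extend(g for g in sig.genes if g not in out)
        return out


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _build_design(config: SimulationConfig, tag: str) -> SampleDesign:
    rows = []
    for cond, n_donors in config.groups:
        for d in range(n_donors):
            batch = d % config.n_batches
            sample = f"{tag}_{cond}_d{d + 1}"
            rows.append((sample, cond, f"{tag}_d{d + 1}", f"{tag}.b{batch + 1}"))
    tab = pd.DataFrame(rows, columns=["sample", "condition", "donor", "batch"]).set_index("sample")
    # every batch must contain the bridge condition
    for batch, sub in tab.groupby("batch"):
        if config.bridge_condition not in set(sub["condition"]):
            raise ValueError(
                f"batch {batch!r} contains no sample of bridge condition "
                f"{config.bridge_condition!r}; give the bridge condition at "
                f"least {config.n_batches} donors"
            )
    return SampleDesign(tab)


def _simulate_platform(
    config: SimulationConfig,
    genes: list[str],
    design: SampleDesign,
    rng: np.random.Generator,
    shared_only: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 matrix for one platform plus its per-gene batch-shift table."""
    n_g, samples = len(genes), design.samples
    base = np.full(n_g, float(config.baseline_mean))
    if config.baseline_gene_sd > 0:
        # per-gene baselines spread the marginal distribution, as on real
        # arrays; without it quantile normalization is degenerate because
        # all background genes tie at one expression level
        base = base + rng.normal(0.0, config.baseline_gene_sd, size=n_g)
    mat = np.tile(base[:, None], (1, len(samples)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    cond = design.table["condition"]
    for sig in config.planted:
        if shared_only and not sig.shared_across_datasets:
            continue
        rows = [gene_pos[g] for g in sig.genes if g in gene_pos]
        cols = np.flatnonzero(cond.isin(sig.conditions).to_numpy())
        if rows and len(cols):
            mat[np.ix_(rows, cols)] += sig.effect
    mat += rng.normal(0.0, config.noise_sd, size=mat.shape)

    batches = sorted(set(design.table["batch"]))
    shifts = pd.DataFrame(0.0, index=genes, columns=batches)
    if config.batch_shift_sd > 0 and len(batches) > 1:
        # the first batch is the untouched reference
        for b in batches[1:]:
            shifts[b] = rng.normal(0.0, config.batch_shift_sd, size=n_g)
    for b in batches:
        cols = np.flatnonzero((design.table["batch"] == b).to_numpy())
        mat[:, cols] += shifts[b].to_numpy()[:, None]
    return pd.DataFrame(mat, index=genes, columns=samples), shifts


def simulate_expression_study(
    config: SimulationConfig,
) -> tuple[tuple[ExpressionDataset, ExpressionDataset], SampleDesign, SyntheticTruth]:
    """Simulate a two-platform study with overlapping gene universes.

    Returns the dataset pair (platforms ``A`` and ``B``), one design
    covering the samples of both, and the planted truth.  Signals with
    ``shared_across_datasets=False`` appear only on platform ``A``.
    """
    rng = np.random.default_rng(config.seed)
    all_genes = _gene_ids(config.n_genes)
    n_shared = int(round(config.gene_overlap * config.n_genes))
    shared, rest = all_genes[:n_shared], all_genes[n_shared:]
    half = len(rest) // 2
    genes_a = shared + rest[:half]
    genes_b = shared + rest[half:]

    design_a = _build_design(config, "A")
    design_b = _build_design(config, "B")
    mat_a, shifts_a = _simulate_platform(config, genes_a, design_a, rng, shared_only=False)
    mat_b, shifts_b = _simulate_platform(config, genes_b, design_b, rng, shared_only=True)

    design = SampleDesign(pd.concat([design_a.table, design_b.table]))
    truth = SyntheticTruth(
        planted=tuple(config.planted),
        batch_shifts={"A": shifts_a, "B": shifts_b},
    )
    ds_a = ExpressionDataset(mat_a, scale="log2", platform="A")
    ds_b = ExpressionDataset(mat_b, scale="log2", platform="B")
    return (ds_a, ds_b), design, truth


def simulate_mixtures(
    basis,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Linear-scale mixtures of a cell-type basis with known fractions.

    Parameters
    ----------
    basis
        A :class:`~monomap.deconvolution.SignatureBasis` or a plain
        gene x cell-type DataFrame on linear scale.
    fractions
        Mixture-sample x cell-type table; rows must be nonnegative and
        sum to 1 within 1e-8.
    noise_sd
        Standard deviation of additive Gaussian noise on the linear
        scale (absolute units; scale it to the basis mean yourself).

    Returns the mixture dataset and a copy of the truth fractions.
    """
    matrix = getattr(basis, "matrix", basis)
    if not isinstance(matrix, pd.DataFrame):
        raise TypeError("basis must expose a gene x cell-type DataFrame")
    fr = fractions[matrix.columns]  # align column order; KeyError if types missing
    arr = fr.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("mixture fractions must be nonnegative")
    bad = np.abs(arr.sum(axis=1) - 1.0) > 1e-8
    if bad.any():
        raise ValueError(
            f"mixture fraction rows must sum to 1: offending samples "
            f"{list(fr.index[bad])}"
        )
    rng = np.random.default_rng(seed)
    mix = matrix.to_numpy() @ arr.T
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, size=mix.shape)
    mix = np.clip(mix, 0.0, None)
    ds = ExpressionDataset(
        pd.DataFrame(mix, index=matrix.index, columns=fr.index),
        scale="linear",
        platform="mixture",
    )
    return ds, fractions.copy()


@dataclass
class TimeCourseConfig:
    """Design of a negative-binomial time-course count study.

    ``time_points`` are ordered condition labels.  Each condition gets a
    planted cluster of ``cluster_size`` genes elevated ``effect``-fold;
    a fraction ``overlap_fraction`` of each cluster is carried over into
    the next time point's cluster, mimicking genes shared between
    consecutive response waves.
    """

    n_genes: int = 2000
    time_points: Sequence[str] = ("0h", "6h", "24h", "72h")
    n_donors: int = 3
    baseline_mean: float = 200.0        # expected counts at size factor 1
    dispersion: float = 0.05            # NB: var = mu + dispersion * mu^2
    cluster_size: int = 40
    effect: float = 4.0                 # fold elevation of cluster genes
    overlap_fraction: float = 0.5
    size_factors: Sequence[float] | None = None  # one per sample, else all 1
    frac_low: float = 0.1               # genes planted below the mean-10 filter

    def __post_init__(self) -> None:
        if len(self.time_points) < 2:
            raise ValueError("need at least 2 time-point conditions")
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.overlap_fraction <= 0.5:
            # carried genes come from the previous cluster's fresh members,
            # so a gene spans at most two consecutive clusters; beyond 0.5
            # that chain-free construction is impossible
            raise ValueError("overlap_fraction must lie in [0, 0.5]")


def simulate_time_course_counts(
    config: TimeCourseConfig, seed: int = 0
) -> tuple[pd.DataFrame, SampleDesign, SyntheticTruth]:
    """Negative-binomial counts over ordered time-point conditions.

    Library-size factors multiply every expected count of a sample, so
    median-of-ratios normalization should recover their ratios.  The
    truth records the per-condition clusters and the size factors.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_ids(config.n_genes)
    tps = list(config.time_points)
    samples, conds, donors = [], [], []
    for t in tps:
        for d in range(config.n_donors):
            samples.append(f"{t}_d{d + 1}")
            conds.append(t)
            donors.append(f"d{d + 1}")
    n_s = len(samples)
    sf = np.ones(n_s) if config.size_factors is None else np.asarray(config.size_factors, float)
    if sf.shape != (n_s,):
        raise ValueError(f"size_factors must have one entry per sample ({n_s})")

    # per-gene baseline means: lognormal spread around the configured mean,
    # with a low-expressed tail below the mean-count filter
    base = config.baseline_mean * rng.lognormal(0.0, 0.5, size=config.n_genes)
    n_low = int(round(config.frac_low * config.n_genes))
    low_idx = rng.choice(config.n_genes, size=n_low, replace=False)
    base[low_idx] = rng.uniform(0.1, 3.0, size=n_low)

    # planted clusters with consecutive-time-point carry-over
    eligible = [i for i in range(config.n_genes) if i not in set(low_idx)]
    rng.shuffle(eligible)
    pool = iter(eligible)
    n_carry = int(round(config.overlap_fraction * config.cluster_size))
    clusters: dict[str, list[int]] = {}
    prev_fresh: list[int] = []
    for t in tps:
        # carry only from the previous cluster's *fresh* genes, so no gene
        # spans more than two consecutive time points
        carried = prev_fresh[:n_carry]
        fresh = [next(pool) for _ in range(config.cluster_size - len(carried))]
        clusters[t] = carried + fresh
        prev_fresh = fresh

    mu = np.tile(base[:, None], (1, n_s))
    cond_arr = np.asarray(conds)
    for t, idx in clusters.items():
        cols = np.flatnonzero(cond_arr == t)
        mu[np.ix_(idx, cols)] *= config.effect
    mu = mu * sf[None, :]

    if config.dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / config.dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    design = SampleDesign(
        pd.DataFrame(
            {"condition": conds, "donor": donors, "time_point": conds},
            index=pd.Index(samples, name="sample"),
        )
    )
    truth = SyntheticTruth(
        clusters={t: [genes[i] for i in idx] for t, idx in clusters.items()},
        size_factors=pd.Series(sf, index=samples),
        dispersion=config.dispersion,
    )
    return counts_df, design, truth


def simulate_gene_sets(
    universe: Sequence[str],
    n_sets: int,
    set_size: int,
    enriched_genes: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, list[str]], str | None]:
    """Random gene sets plus one set enriched in planted-effect genes.

    Returns the GMT-style collection and the name of the enriched set
    (``None`` when ``enriched_genes`` is not given).  The enriched set
    draws as many members as possible from ``enriched_genes`` and pads
    with random universe genes.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe size")
    if set_size == len(universe):
        warnings.warn("set_size equals the universe size; enrichment is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        members = rng.choice(universe, size=set_size, replace=False)
        sets[f"RANDOM_{i + 1:03d}"] = sorted(members.tolist())
    enriched_name = None
    if enriched_genes is not None:
        core = [g for g in enriched_genes if g in set(universe)][:set_size]
        if not core:
            raise ValueError("no enriched gene lies in the universe")
        pad_pool = [g for g in universe if g not in set(core)]
        pad = rng.choice(pad_pool, size=set_size - len(core), replace=False).tolist() if set_size > len(core) else []
        enriched_name = "PLANTED_SET"
        sets[enriched_name] = sorted(core + pad)
    return sets, enriched_name
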