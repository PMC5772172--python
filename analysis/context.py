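"""Shared study conditions for the numbered analysis drivers.

One place defines the simulated two-platform study, the mixture
benchmark and the time-course design, so every driver works on the same
conditions.  Outputs land under ``results/``.
"""

from pathlib import Path

from monomap import PlantedSignal, SimulationConfig, TimeCourseConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

SEED = 1

CONDITIONS = ["MO", "Mac", "DC", "infDC"]

# 25 genes with a matched in-vivo-like pattern shared across platforms,
# plus 40-gene condition-specific blocks for network clustering
IDENTITY_GENES = tuple(f"G{i:04d}" for i in range(1, 26))
CLUSTER_BLOCKS = {
    cond: tuple(f"G{i + 100 + 40 * j:04d}" for i in range(1, 41))
    for j, cond in enumerate(CONDITIONS)
}

# 4 donors per condition so the condition + batch model keeps residual
# degrees of freedom in two-group contrasts
STUDY = SimulationConfig(
    n_genes=2000,
    groups=[(c, 4) for c in CONDITIONS],
    baseline_mean=8.0,
    baseline_gene_sd=1.5,
    noise_sd=0.2,
    # kept moderate: per-gene batch shifts interact with the nonlinear
    # quantile normalization, so the additive bridge correction inverts
    # them only approximately (see docs/methods.md)
    batch_shift_sd=0.4,
    n_batches=3,
    bridge_condition="MO",
    gene_overlap=0.85,
    planted=[
        PlantedSignal(IDENTITY_GENES, ("infDC",), 1.0, shared_across_datasets=True),
        *[
            PlantedSignal(genes, (cond,), 1.5, shared_across_datasets=False)
            for cond, genes in CLUSTER_BLOCKS.items()
        ],
    ],
    seed=SEED,
)

TIME_COURSE = TimeCourseConfig(
    n_genes=1500,
    time_points=("0h", "6h", "24h", "72h"),
    n_donors=3,
    cluster_size=60,
    effect=4.0,
    overlap_fraction=0.5,
    size_factors=[1.0, 1.5, 0.7] * 4,
)


def ensure_dirs() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
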