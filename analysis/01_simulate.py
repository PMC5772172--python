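#!/usr/bin/env python
"""Simulate the study: a two-platform expression study with planted
identity genes and condition blocks, plus a negative-binomial time
course.  Writes the matrices, designs and truth tables under
``results/data/``."""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from context import DATA, SEED, STUDY, TIME_COURSE, ensure_dirs

from monomap import io as mio
from monomap import simulate_expression_study, simulate_time_course_counts


def main() -> None:
    ensure_dirs()
    (ds_a, ds_b), design, truth = simulate_expression_study(STUDY)
    mio.write_matrix_tsv(ds_a, DATA / "platformA.tsv")
    mio.write_matrix_tsv(ds_b, DATA / "platformB.tsv")
    mio.write_design_tsv(design, DATA / "design.tsv")
    mio.write_truth_json(
        {
            "planted": [
                {
                    "genes": list(sig.genes),
                    "conditions": list(sig.conditions),
                    "effect": sig.effect,
                    "shared": sig.shared_across_datasets,
                }
                for sig in truth.planted
            ],
            "batch_shifts": {k: v.to_dict() for k, v in truth.batch_shifts.items()},
        },
        DATA / "truth_study.json",
    )

    counts, tc_design, tc_truth = simulate_time_course_counts(TIME_COURSE, seed=SEED)
    counts.to_csv(DATA / "timecourse_counts.tsv", sep="\t", index_label="gene")
    mio.write_design_tsv(tc_design, DATA / "timecourse_design.tsv")
    mio.write_truth_json(
        {"clusters": tc_truth.clusters, "size_factors": tc_truth.size_factors.to_dict()},
        DATA / "truth_timecourse.json",
    )

    print(f"platform A: {ds_a.values.shape[0]} genes x {ds_a.values.shape[1]} samples")
    print(f"platform B: {ds_b.values.shape[0]} genes x {ds_b.values.shape[1]} samples")
    print(f"shared genes: {len(set(ds_a.genes) & set(ds_b.genes))}")
    print(f"time course: {counts.shape[0]} genes x {counts.shape[1]} samples")
    print(f"planted signals: {len(truth.planted)}; seed {SEED}")


if __name__ == "__main__":
    main()
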