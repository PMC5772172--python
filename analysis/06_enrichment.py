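#!/usr/bin/env python
"""GSEA of the planted infDC-like identity set: the genes elevated in
the infDC condition should enrich at the top of the infDC-vs-monocyte
signal-to-noise ranking, while random sets stay null."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from context import DATA, IDENTITY_GENES, RESULTS, SEED, ensure_dirs

from monomap import enrichment as en
from monomap import io as mio
from monomap import simulate_gene_sets


def main() -> None:
    ensure_dirs()
    ds = mio.read_matrix_tsv(DATA / "platformA_corrected.tsv", platform="A")
    design = mio.read_design_tsv(DATA / "design.tsv")
    keep = [
        s for s in ds.samples
        if design.table.loc[s, "condition"] in ("infDC", "MO")
    ]
    sub = ds.subset_samples(keep)
    pheno = design.condition_of(keep)

    sets, planted_name = simulate_gene_sets(
        list(sub.genes), n_sets=10, set_size=25,
        enriched_genes=list(IDENTITY_GENES), seed=SEED,
    )
    mio.write_gmt(sets, DATA / "gene_sets.gmt")
    res = en.gsea_permutation(
        sub, pheno, sets, n_perm=1000, seed=SEED, classes=("infDC", "MO")
    )
    res.table.to_csv(RESULTS / "gsea_results.tsv", sep="\t")
    planted = res.table.loc[planted_name]
    print(
        f"planted set: ES {planted['ES']:.3f}, NES {planted['NES']:.3f}, "
        f"p {planted['p']:.4f}, FDR q {planted['q']:.4f}"
    )
    others = res.table.drop(planted_name)
    print(
        f"{len(others)} random sets: median |NES| {others['NES'].abs().median():.3f}, "
        f"min p {others['p'].min():.3f}"
    )
    print(f"leading edge of planted set: {len(res.leading_edge[planted_name])} genes")


if __name__ == "__main__":
    main()
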