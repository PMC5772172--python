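# monomap

Tools for asking whether in vitro monocyte-derived cells — macrophages
differentiated with M-CSF, dendritic-cell-like cells differentiated with
GM-CSF ± IL-4 — are transcriptional counterparts of the inflammatory
mononuclear phagocytes found in vivo, and for dissecting the
time-dependent IL-4 programme that shapes them.

The question is awkward because the relevant profiles live on different
platforms (different microarray families, RNA-seq time courses) with
batch structure, probe-level redundancy and no shared normalization.
`monomap` implements the complete analysis chain as a tested, reusable
pipeline and ships a synthetic-data generator that plants known truth,
so every stage is scored against ground truth without any external
download.

## The analysis chain

1. **Harmonization** (`monomap.preprocess`) — present-call filtering
   (max condition-group mean ≥ a platform cutoff), probe→gene collapse
   (highest mean expression wins), quantile normalization, and
   bridge-sample batch correction: a condition profiled in every batch
   (blood monocytes) anchors per-gene additive offsets,
   `x'_{gs} = x_{gs} − (mean_{bridge∈batch(s)} x_g − mean_{bridge} x_g)`.
2. **Differential expression** (`monomap.differential`) — per-gene OLS
   `expression ~ condition + covariate` with an F test on condition,
   signed fold-changes `FC = ±2^{|m_A − m_B|}`, Benjamini–Hochberg FDR,
   and DEG selection (|FC| ≥ 2, q < 0.05 by default).
3. **Signatures** (`monomap.signatures`) — the common derived-cell
   signature (intersection over contrasts, then a ≤1.7-fold pairwise
   consistency filter across derived conditions), subset-specific
   surface markers (all one-vs-rest FC > 2), receptor profiles, the
   IL-4 meta-signature (direction supported by ≥2 of 3 datasets) and
   the five-condition time-resolved regulator filter.
4. **Identity mapping** (`monomap.identity`) — per gene, Pearson
   correlation between the two datasets' k-vectors of group means;
   shared identity genes need r > 0.4 plus target-vs-every-other-group
   FC > 1.3 in *both* datasets (composite targets use the minimum of
   their group means).
5. **Deconvolution** (`monomap.deconvolution`) — a gene × cell-type
   signature basis from one-vs-rest markers, then linear ν-SVR
   (ν ∈ {0.25, 0.5, 0.75}, best reconstruction wins; negative
   coefficients truncated, renormalized to fractions).
6. **Enrichment** (`monomap.enrichment`) — GSEA: signal-to-noise
   ranking `(μ_A − μ_B)/(σ_A + σ_B)` with σ floors, weighted-KS
   enrichment score, phenotype-permutation null (exhaustive enumeration
   when few distinct relabellings exist), NES, nominal p and FDR.
7. **Co-expression networks** (`monomap.coexpression`) — edges at
   Pearson r ≥ threshold on anti-log2 profiles, pruning of small
   components, condition-cluster labels by argmax fold-change vs the
   overall mean (≥1.5), and consecutive-time-point overlap sets for
   count time courses (normalized by median-of-ratios size factors,
   mean ≥ 10 filter, values < 1 clamped to 1).

`monomap.simulate` generates every input with recorded truth: a
two-platform study with partially overlapping gene universes, per-batch
per-gene shifts and bridge samples; linear-scale cell mixtures of known
fractions; negative-binomial time-course counts with planted
condition clusters that overlap between consecutive time points; and
gene-set collections with one planted enriched set.

## Worked example

The numbered drivers under `analysis/` run the whole chain on one
simulated study (2,000 genes, four conditions × 4 donors, 3 batches,
two platforms sharing 85 % of genes, 25 planted cross-platform identity
genes and four 40-gene condition blocks):

```
$ python analysis/01_simulate.py
platform A: 1850 genes x 16 samples
platform B: 1850 genes x 16 samples
shared genes: 1700

$ python analysis/02_preprocess.py
platform A: residual bridge offset after correction = 1.78e-15

$ python analysis/03_differential.py
infDC vs MO: 43 up, 37 down; planted-block recall 0.95
common signature: 0 up / 29 down before consistency filter; 0 / 29 after

$ python analysis/04_identity_mapping.py
common present genes: 1700
shared identity genes (r > 0.4, all FC > 1.3): 25
precision 1.00, recall 1.00 vs 25 planted genes

$ python analysis/05_deconvolution.py
signature basis: 160 genes x 4 types, condition number 5.3
50 noisy mixtures: mean per-sample RMSE 0.0079 (max 0.0178)

$ python analysis/06_enrichment.py
planted set: ES 0.978, NES 1.592, p 0.0286, FDR q 0.0312

$ python analysis/07_networks.py
array network: 160 nodes, 3119 edges, 4 components
condition-cluster labels: 160 assigned, accuracy 1.00
overlap 6h -> 24h: 30 genes (planted 30)
```

Reading the numbers: batch correction removes the planted shifts to
machine precision; the 25 planted identity genes are recovered exactly
by the four-group correlation filter; ν-SVR recovers mixture fractions
to ~0.8 % RMSE under 10 % noise; the planted gene set is the only one
significant at FDR < 0.25 with nominal p < 0.05; the co-expression
components coincide with the planted condition blocks; and the
time-course cluster overlaps match the planted 50 % carry-over.  The
common signature's 29 repressed genes are the monocyte-specific block —
genes high in monocytes and consistently lower in every derived
condition.

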