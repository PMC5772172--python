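# Methods

This note records the models, conventions and numerical choices behind
`monomap`, and what the synthetic benchmarks do and do not establish.

## Data model and conventions

Expression travels as a feature × sample matrix with an explicit scale
flag. Microarray-style data is log2; count data is linear and only
log2-transformed after normalization and clamping. A log2-flagged
matrix containing values above 30 triggers a warning, since that almost
always means a linear matrix was mislabelled.

Fold-changes use the signed linear-ratio convention of microarray
suites: `FC = 2^(mA−mB)` when group A's log2 mean is larger, else
`−2^(mB−mA)`. Values never fall in (−1, 1), `FC = 1` means equality,
and thresholds like "FC ≥ 2 or ≤ −2" read literally. Boundary
semantics follow the conventions the thresholds came with: fold-change
cutoffs are inclusive where stated as "≥", the FDR cutoff `q < 0.05` is
strict, present calls keep a feature exactly at the cutoff, and network
thresholds `r ≥ r_min` are inclusive.

## Harmonization

**Present calls.** A feature is present when the maximum over
condition-group means reaches a platform-specific log2 cutoff. The
cutoff is a config value, not a constant, because it legitimately
differs between array generations (7, 6.95, 6.75 are typical values
for the platforms this pipeline targets).

**Probe collapse.** Per gene, the probe with the highest *mean*
expression across all samples survives. "Highest expression" and
"highest mean expression" are both in circulation; the mean is
order-independent and is the convention adopted throughout. Ties break
lexicographically on the probe id, making the collapse deterministic.

**Quantile normalization.** Columns are forced onto the mean
distribution of order statistics. Tied values receive the mean of the
reference values at their tied (fractional) ranks, which makes the
transform idempotent to 1e-12 — a property the test suite checks.

**Bridge batch correction.** The model is a per-gene additive location
shift per batch, estimated from the bridge condition (a condition
profiled in every batch) against the grand bridge mean, and subtracted
from all samples of the batch. This is the minimal model the bridge
design identifies; it leaves within-batch contrasts exactly invariant
and inverts an additively planted shift exactly at zero noise. It makes
no claim of equivalence to mixed-model batch removal as implemented in
commercial suites; that algorithm is unspecified and unrecoverable.

One interaction matters in practice: quantile normalization is
nonlinear, so per-gene batch shifts applied *before* QN are no longer
exactly additive *after* it, and the bridge correction then inverts
them only approximately. With batch-shift spread comparable to or
larger than the biological noise, the residual inflates the per-gene
error variance visibly (the analysis drivers use shift sd 0.4 against
noise sd 0.2 and still lose some power). The zero-noise exactness
benchmark deliberately runs without QN in the loop.

**Count normalization.** Median-of-ratios size factors (reference =
per-gene geometric mean over genes positive in every sample), genes
kept when some condition-group mean of normalized counts reaches 10,
then all normalized values below 1 clamped to 1 so log-ratios cannot
explode on near-zero counts. The implementation is cross-checked
against pydeseq2's size factors in the test suite.

## Differential testing

Per gene, a fixed-effects OLS fit of `expression ~ condition
(+ covariate)` with an F test on the condition factor, vectorized over
genes via an SVD-based projection (robust to rank-deficient dummy
blocks). Donor and batch enter as fixed covariates rather than random
effects: with balanced designs the condition F test coincides with the
mixed-model test, and the estimator stays two least-squares fits. This
is a deliberate deviation from mixed-model software; unbalanced designs
with strong covariate structure are where the two can diverge.

Zero residual variance yields `F = +∞, p = 0` rather than an error;
designs without residual degrees of freedom yield NaN. A practical
consequence of small designs: each covariate level costs residual
degrees of freedom, and with 3 donors per group a two-group contrast
with a 3-level batch covariate retains only 2, which makes BH-corrected
significance nearly unattainable regardless of effect size. The
benchmark conditions (n = 3/group, sd 0.25, +2 log2 effects) therefore
test the plain two-group model, and the analysis drivers use 4 donors
per condition when the batch covariate is in the model.

BH FDR is the step-up procedure with monotonicity enforcement, capped
at 1; NaN p values propagate without entering the ranking.

## Signatures and identity mapping

Signature constructions are pure set-and-threshold logic; each returned
signature carries provenance (input lists, thresholds, conflicts)
sufficient to replay it exactly. Genes qualifying as both induced and
repressed in the IL-4 meta-signature are contradictory evidence and go
into a reported conflict list, into neither direction — a signature
gene must have one direction.

Identity mapping correlates, per gene, the k-vectors of group means
(log2) of two gene-harmonized datasets; k = 4 in the motivating design.
Genes pass with r > 0.4 and target-vs-every-other-group FC > 1.3 in
both datasets (strict inequalities); an undefined correlation (constant
profile) counts as failing. Composite targets (two conditions standing
in for one population) use the minimum of the two group means, so a
gene must be elevated in both. With k = 4 points per correlation the r
filter alone is weak (r > 0.4 admits much noise); the double FC filter
does most of the work, which is why the planted-recovery benchmark
reaches precision and recall ≥ 0.9.

## Deconvolution

The signature basis holds linear-scale group means over the union of
one-vs-rest marker genes (BH q < 0.3, positive FC, top-k by FC per
type; k = 50 by default). For estimation, basis and mixture are
standardized — the basis *globally* (one mean and sd over all entries)
so the relative scale of cell-type columns survives; each mixture
column by its own mean and sd. A linear ν-SVR (C = 1) is fit at
ν ∈ {0.25, 0.5, 0.75}; the fit with the lowest reconstruction RMSE
wins; negative coefficients are truncated at zero and the rest
renormalized to sum to 1. Global basis standardization is what makes
noiseless mixtures recover exactly: per-column z-scoring would reweight
each fraction by its column's spread. Scaling a mixture column by any
positive constant provably leaves the estimate unchanged. No empirical
p value via Monte-Carlo mixtures is computed.

## Enrichment

Signal-to-noise is `(μA − μB)/(σA + σB)` with sample sd (ddof = 1) and
each σ floored at `0.2·|μ|` (0.2 when the mean is 0) — the canonical
floor; it is exposed as configuration since tools differ here. The
enrichment score is the signed maximum deviation of the weighted-KS
running sum (hits add `|metric|^p` normalized by the hit total, misses
subtract `1/(N−Nh)`; p = 1 by default). The null permutes phenotype
labels and recomputes metric, ranking and ES; when fewer distinct label
assignments exist than requested permutations they are enumerated
exhaustively (e.g. 20 for a 3+3 design), eliminating
duplicate-permutation bias. NES divides ES by the mean |null ES| of
matching sign; nominal p is the same-sign tail fraction; FDR follows
the NES-pooling procedure of the canonical tool, capped at 1. A
gene-set permutation mode (random same-size sets on the observed
ranking) is the documented fallback for designs too small to permute.
Default reporting conventions are nominal p < 0.05 and FDR < 0.25;
they annotate, never truncate, the output.

## Co-expression networks

Edges connect genes with Pearson r ≥ the threshold on anti-log2
profiles (log2 available by flag); genes without any qualifying edge
are dropped, then components below the minimum size are pruned.
Typical operating points: r ≥ 0.93 with components ≥ 5 for
genome-scale DEG networks, 0.83/≥4 and 0.85/≥3 for transcriptional-
regulator networks, 0.87/≥4 for time courses. Only edges at or above
the threshold are kept among retained nodes — whether the original
graph-layout tools retain sub-threshold edges between retained nodes is
ambiguous, so this implementation fixes the testable convention.

Condition clusters replace manual curation with a deterministic rule:
each node takes the condition of its maximal fold-change against the
unweighted mean of condition means, provided that FC ≥ 1.5 (the same
membership threshold used for cluster gene lists); ties take the
earliest condition in the supplied order. Time-course overlap sets are
the genes qualifying (FC ≥ 1.5) at both of two consecutive time
points; exclusive sets qualify at exactly one time point.

The master-regulator post-filter operates on an external prediction
table (regulator, cell type, NES): rows below NES 3 drop (boundary
kept), then regulators surviving for more than one cell type drop
entirely. Motif scanning itself is out of scope.

## Synthetic data

The generators define the benchmark conditions:

* **Arrays** — additive Gaussian noise in log2 space; per-gene
  per-batch additive shifts (first batch is the reference); a bridge
  condition in every batch (configs violating this are rejected naming
  the batch); two platforms with a configurable shared-gene fraction;
  planted signals as log2 offsets on target conditions, optionally
  shared across platforms. `baseline_gene_sd` spreads per-gene
  baselines (0 by default for analytic exactness; the analysis drivers
  use 1.5, since a degenerate marginal distribution makes quantile
  normalization behave pathologically).
* **Mixtures** — linear-scale convex combinations of a basis plus
  Gaussian noise, clipped at 0; fraction rows must sum to 1 within
  1e-8.
* **Counts** — negative binomial with `var = μ + αμ²` (Poisson below
  α = 1e-8), per-sample library-size factors, lognormal per-gene
  baselines with a configurable low-expressed tail, and per-condition
  clusters of elevated genes. Cluster carry-over draws only from the
  previous cluster's fresh members, so a gene spans at most two
  consecutive time points; this caps the overlap fraction at 0.5 and
  keeps "overlap" identifiable against the overall mean.
* **Gene sets** — random draws plus one set seeded from planted-effect
  genes.

All randomness flows from one integer seed per call; identical seeds
give byte-identical output. What the generators do *not* emulate:
probe-level bead chemistry, sequencing-read noise, realistic gene–gene
correlation beyond the planted blocks, or heavy-tailed outlier samples.
Passing benchmarks therefore demonstrate correctness of the algorithms
under their stated assumptions, not robustness to real-data pathology.

## Benchmark problem sizes

The recovery and calibration benchmarks (in `monomap.benchmarks`,
reported by `scripts/acceptance.py`) use: 200 genes with 20 planted
+2 log2 effects for DEG recall; 2,000 genes with 25 planted identity
genes; 50 mixtures of a 100-gene, 5-type basis at 10 % noise; four
40-gene condition blocks for cluster labelling; 100-gene studies for
bridge exactness; 800–1,500-gene count matrices for size factors and
overlaps; 100 null simulations for DEG type-I control; and 50 null
simulations (5+5 samples, exhaustive 252-permutation null) for GSEA
p-value calibration against a Kolmogorov bound at roughly the 1 %
level. The whole report runs in a few seconds on one CPU.
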