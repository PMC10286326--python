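# Methods

This note records the models, conventions and numerical choices behind
`screscue`, in the order the pipeline applies them.

## Quality control and normalization

Per cell we compute the number of detected genes (count > 0), the total
count, and the mitochondrial fraction (mitochondrial counts / total; 0 for
an all-zero cell, which the other filter removes anyway). A cell is kept
iff `n_detected >= min_genes` (default 600) **and**
`mito_fraction <= max_mito` (default 0.15): the exclusion is strictly
"fewer than" / "greater than", so cells sitting exactly on a threshold are
retained. After filtering, genes expressed in zero retained cells are
pruned; no other gene-level filter is applied.

Normalization is counts-per-10k with a natural log1p:
`v = ln(1 + 1e4 · count / cell_total)` — the default convention of the
standard single-cell toolkits. The scale factor and log base are recorded
in `uns['normalization']` so alternatives remain auditable. Zero counts
map exactly to zero and within-cell rank order is preserved.

## Differential expression

The per-gene test is the two-sided Wilcoxon rank-sum on normalized values.
Two modes:

- **exact** (automatic for n + m ≤ 14): enumerates all C(n+m, n)
  assignments of the pooled average ranks and counts assignments whose
  rank-sum deviates from the null mean by at least the observed deviation.
  This is valid under ties and is the reference the test suite checks
  against brute-force enumeration.
- **approximate**: normal approximation with average ranks, tie-corrected
  variance n·m/12·[(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity
  correction — numerically identical to `scipy.stats.mannwhitneyu`'s
  asymptotic method. All-tied input returns p = 1.

A known limitation: with heavy ties at very small n the exact two-sided p
is a step function with central jumps of 0.1–0.3, which no smooth
approximation can track pointwise; the approximation is unbiased on
average and does not flip clear significance calls, but individual
small-sample tied p-values can differ from exact by more than 0.02. In
practice the automatic exact mode covers that regime.

The fold change is `log2[(mean_A(e^v − 1) + 1)/(mean_B(e^v − 1) + 1)]`
(exponentiated means with a pseudocount of one, reported in base 2). Genes
enter the marker table when expressed in at least `min_pct = 0.1` of the
cells of one group; thresholds (|log2FC| > 0.25, p < 0.05, both strict)
are applied only afterwards, so no gene is silently dropped between the
table and the DEG sets. BH-adjusted p-values are reported for transparency
but do not decide set membership, matching the raw-p convention of the
analysis this package implements. A cluster is only tested when both
groups have ≥ 3 cells of it.

## Rescue analysis

Rescue requires significance in both contrasts at the stated thresholds —
no sign-flip-only relaxation — so each rescue set is a subset of its
disease-DEG parent and rescue ratios are bounded in [0, 1]. Ratio
denominators are direction-matched (down-rescue over disease-up). Ratios
with an empty denominator are reported missing (NaN), never 0. Frequency
top-k ties break lexicographically; per-direction and pooled frequency
tables are both produced since pooling conventions vary. Composition
log2FC of a cluster between groups is missing (with a warning, no
pseudocount) when either proportion is zero.

Because the two contrasts share the disease cells, their test statistics
are positively coupled: a chance fluctuation of a gene's disease-group
mean pushes the gene toward opposite-signed significance in both
contrasts at once. Under a null with no planted effects this yields a
floor of a few spurious rescue genes per cluster per 2000 genes at
200-cell groups (≈ 4–5 at the default dispersion, ≈ 2.5 even at
near-Poisson noise), even though the per-gene false-positive rate is
exactly nominal (5% at α = 0.05). Users comparing rescue counts across
clusters should keep this additive floor in mind; it shrinks with larger
fold-change cuts and larger groups.

## Regulon rescue targets and module scores

Regulon tables are (TF, target, importance) rows; duplicate pairs collapse
to the maximum importance with a warning, negative importances are format
errors. A TF's rescue target genes are its targets ∩ a cluster's
down-rescue set, sorted by importance descending with lexicographic
tie-break, truncated to `top_n = 20`. The network inference itself is
consumed, not re-run.

Gene-set scores per cell use binned controls: all genes are cut into
`n_bins = 24` equal-frequency bins of average normalized expression; each
set gene contributes `min(n_ctrl, bin size)` control genes sampled without
replacement from its bin (seeded generator, sampling order fixed by sorted
set genes); the score is the mean over set genes minus the mean over the
pooled controls. Capping at the bin occupancy means the all-genes set
pools every gene as its own control and scores exactly zero — a
self-consistency property the tests assert. Set genes are *not* excluded
from the control pool; with `n_ctrl = 100` and transcriptome-scale
universes the controls approximate the expression-matched background.
By default the whole matrix is scored with one control pool; restrict the
AnnData to one cluster first to use per-cluster pools. The seed is a
required argument — scores are only reproducible given it.

## Correlation screen

Spearman rho is the product-moment correlation of average ranks.
Two-sided p: for n ≤ 9, exact enumeration of all n! permutations of one
rank vector (valid under ties); for larger n, the t-transform
t = r·√((n−2)/(1−r²)) with a continuity correction of half the no-ties
rho lattice step, 6/(n(n²−1)), subtracted from |rho| before the
transform. The correction aligns the smooth tail with the ≥-counting
permutation convention at small n (worst deviation 0.014 at n = 8 versus
0.024 uncorrected) and vanishes at large n (≈ 1e-4 effect at n = 50).
All-constant input yields missing (NaN), not 0.

The screen keeps candidates with rho > 0.15 **and** p < 0.01, both
strict, positive correlations only (an absolute-value option exists, off
by default), focal gene excluded, computed over a caller-chosen cell
subset (default: all cells; the pipeline uses the focal cluster pooled
across the three groups). At least 10 cells are required so the
t-approximation applies.

## Over-representation

`P(X ≥ k)` for X ~ Hypergeometric(N, K, n) via `scipy.stats.hypergeom.sf`
(k = 0 returns exactly 1), with BH q-values across the collection. The
universe is explicit — the pipeline uses all genes surviving QC — rather
than an implicit web-tool background, so results are reproducible; set and
query genes outside the universe are dropped with a logged count.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
clustered three-condition counts with planted, directional, partially
rescued disease effects. Counts are negative binomial,
`NB(mean = s_cell · μ_gene · m_{cluster,group,gene}, shape r)` via a
gamma–Poisson mixture, with:

- gene baselines μ log-normal(μ = 0, σ = 1) — a realistic right-skewed
  mean distribution giving ≈ 3300 counts and ≈ 1100 detected genes per
  cell at 2000 genes, comfortably above the QC defaults;
- one global NB shape r = 2 (overdispersion in the range fitted to
  droplet UMI data; a single global value is the simplest model under
  which the rank-based test is calibrated — verified: 5.0% of null genes
  at p < 0.05);
- cell size factors log-normal(0, 0.3), giving ≈ 30% library-size spread;
- 5% of genes flagged mitochondrial (named `mt-…`), with no group effect,
  so QC is testable without confounding DE;
- per cluster, a `disease_effect_fraction` (default 0.10) of non-mito
  genes gets its disease-group mean multiplied by 2^(±magnitude), sign
  Bernoulli(1/2) per gene so both rescue directions are exercised; a
  `rescue_fraction` (default 0.5) of each directional set returns to
  baseline in the treated group, the rest keeps the disease mean;
- one shared gene universe, perturbed sets drawn independently per
  cluster, enabling cross-cluster frequency statistics.

The reference conditions used by the acceptance checks are 3 clusters ×
200 cells/group/cluster × 2000 genes with |log2FC| = 1 — sizes at which
the whole pipeline runs in seconds while DE power is realistic (per-cluster
recovery of planted rescue genes at sensitivity and precision ≥ 0.9).

What the generator does **not** model: mouse-level replicate structure
(the emulated design pools animals into one library per group),
batch effects, doublets, ambient RNA, cell-cycle structure, UMI
saturation, gene–gene correlation beyond the shared group effect, and
per-gene dispersion variation. Passing recovery tests therefore show the
pipeline's statistics behave as designed under clean NB assumptions — not
that real tissue data will reach the same sensitivity.

Companion generators produce a regulon table whose designated TF covers a
configurable share of one cluster's planted rescue set (importances
log-normal, positive), and GMT gene-set collections with one
planted-enriched set and uniform decoys.

## Degenerate inputs and tie-breaks (summary)

- all-tied Wilcoxon samples → p = 1; empty samples → error
- all-zero cell → mito fraction 0 (and removed by the gene filter)
- zero-total cell at normalization → error (QC first)
- empty rescue-ratio denominator, zero composition proportion,
  all-constant correlation input → missing, never 0
- ordering tie-breaks are lexicographic everywhere (frequency top-k,
  importance ranking, ORA p-ties) so outputs are order-invariant
- pipeline outputs carry a provenance header (version, config hash, seed)

## Known limitations

Raw-p DEG membership (by design) means DEG and rescue counts scale with
gene number under the null; the shared-disease-group rescue floor above
adds to that. The module-score control pool includes set genes, which
slightly attenuates scores for very large sets. The correlation screen's
t-approximation is not exact under heavy ties, though the permutation mode
covers small samples. The CLI's `de` and `score` subcommands apply the
default QC thresholds; use the library API or the pipeline config for
non-default thresholds.
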