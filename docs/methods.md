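# Methods

## Generative model for the bulk experiment

Counts are simulated from the standard RNA-seq gamma–Poisson mixture. For
gene *i* in sample *j*,

    E[y_ij] = s_j · b_ij · 2^( m_i + β · a(g_j, t_j) · 1[i ∈ planted module] )
    Var[y_ij] = μ_ij + α_i μ_ij²

where `s_j` is a library-size factor drawn log-uniformly from
`libsize_range`, `b_ij = 2^δ` is an optional per-batch per-gene shift with
δ ~ N(0, `batch_sd_log2`), `m_i` is a baseline log2 mean drawn uniformly
from `baseline_log2_mean_range`, and `α_i` is a per-gene NB dispersion
drawn uniformly from `dispersion_range`. The latent abundance
`a(genotype, stage)` encodes the biology being emulated: a basal-progenitor
population absent at E12.5 that rises to its full abundance at E14.5 in
wild type (0, 0.5, 1), never forms in the knockout (0, 0, 0), and is
restored in the rescue (0, 0.5, 1). Planted-module genes shift with `a` on
the log2 scale by effect size β (default 2, i.e. four-fold at full
abundance), which simultaneously creates differential expression across
design cells and coexpression across samples — the two signals the
downstream stages consume.

Defaults and why:

- design: 3 genotypes × 3 stages × 3 replicates (27 samples), one batch.
- β = 2.0 (log2): a strong marker-gene effect; the screen and network
  benchmarks are defined at this value.
- `dispersion_range = (0.005, 0.05)`: pooled embryonic tissue from
  littermates with high-integrity RNA is a low-biological-variability
  regime; typical NB dispersions for such designs sit in this band at
  moderate-to-high expression. This is also the regime in which a
  three-replicate design has meaningful power for two-fold effects.
- `baseline_log2_mean_range = (3, 10)` for the generic generator. The
  recovery benchmark (`recovery_benchmark_config`: 200 planted among 2200
  genes) narrows it to (7, 10) — markers of an abundant cell type are not
  detection-floor genes, and two-fold effects at three replicates are
  statistically invisible below roughly 100 mean counts, so benchmarking
  recovery there would measure sequencing depth, not the method.
- No empirical mean–dispersion trend and no doublet/ambient modeling for
  single cells: moments stay exact, so the simulation's oracles are exact.

What passing tests on these data do **not** show: robustness to
mean-dispersion coupling, outlier counts, unmodeled confounders, or
ambient contamination present in real libraries; the generator is a
statistical emulator of the design, not of a sequencer.

## Differential expression

Size factors are median-of-ratios against the per-gene geometric mean
over genes with no zero counts; with a single sample the factor is 1 and
there is deliberately no pseudo-reference fallback. Dispersion is a
per-gene method of moments, `α = max over design cells of (s² − μ)/μ²` on
normalized counts, floored at 1e-8 — conservative by construction and
deliberately free of empirical-Bayes shrinkage machinery. Each contrast is
fit as a pairwise comparison on the samples of its two levels: an NB
log-link regression with offset `log s_j` and optional categorical
covariates (batch), solved by IRLS with working weights `μ/(1 + αμ)` at
fixed α, at most 100 iterations. The Wald statistic is the contrast
coefficient over its Fisher-information standard error (both reported in
log2 units; positive log2FC means higher in the numerator level); p-values
are two-sided normal tails, adjusted by Benjamini–Hochberg with NA
p-values excluded from the denominator and returned as NA.

Known limitation: at three replicates the plug-in moment dispersion is
noisy, and its noise makes raw Wald p-values anticonservative by a few
percent (we measure ≈0.08 at nominal 0.05). The calibration benchmarks
therefore evaluate the Wald machinery at the simulation's known α; real
analyses at n = 3 should expect this inflation, which is exactly why
production DE tools shrink dispersion estimates.

The variance-stabilizing step used upstream of the network is a shifted
log: `log2(count/sf + 1)`. It is closed-form, monotone, and adequate for
correlation-based downstream computation. Batch, when present, enters the
DE model as a covariate and the network input as per-batch gene-wise mean
centering in log space.

## The candidate screen

Screen atoms are thresholded conditions on one contrast: `up`
(padj < threshold and log2FC ≥ +f), `down` (mirror), `not_significant`
(padj ≥ threshold); NA padj fails every atom and the gene is recorded as
dropped. Atoms combine through arbitrary AND/OR/NOT expressions. The
default rule operationalizes the perturbation logic: (up E12.5→E13.5 OR up
E13.5→E14.5) AND down in cKO at E14.5 AND not-significant in rescue vs WT
at E14.5. Two open choices are resolved as follows and are configurable:
the WT rise may occur at either stage step (OR, not AND), and "restored in
rescue" is absence of evidence at padj ≥ 0.05 — an equivalence-band atom
(|log2FC| ≤ b AND padj ≥ threshold) is available for users who want a
positive statement of normality. The bulk screen applies no fold-change
floor; the early-response filter fixes ≥2-fold within 4 h at adjusted
p < 0.05.

## Coexpression network

Sample outliers are removed in a single pass by standardized connectivity:
sample adjacency `(1 + cor)/2`, connectivity k = row sums, Z.K < −2 drops
the sample (sd of k computed with ddof = 1; if sd = 0 all samples are
kept). Soft power is the smallest β in 1..20 whose connectivity
distribution fits a scale-free law — squared Pearson correlation of
log10 p(k) vs log10 k over 10 equal-width bins, counted only when the
slope is negative — at R² ≥ 0.8, else the largest candidate with a warning
flag. Adjacency is `|cor|^β` (unsigned, the default; the sign convention
is configurable) with unit diagonal; topological overlap is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij).

Modules are branches of an average-linkage tree on 1 − TOM cut at a static
height (default 0.95, chosen once from the block-model behaviour of
average linkage: background pairs concentrate near dissimilarity 1, module
pairs well below), with clusters under `min_module_size = 30` labeled
`unassigned`; the dynamic-tree-cut refinement is intentionally out of
scope, trading a little sensitivity for a deterministic, testable rule.
Module labels are M1, M2, … by decreasing size with lexicographic
tie-breaks. The module eigengene is the first right-singular vector of the
z-scored module block (unit norm, sign oriented so mean gene correlation
is nonnegative); kME is the Pearson correlation of a gene with an
eigengene; modules whose eigengenes correlate above R = 0.85 (strictly)
are merged iteratively, largest correlation first, recomputing eigengenes
after each merge. Hub genes are module members with kME ≥ 0.8 (the
threshold is configurable; there is no canonical value). Eigengene group
effects use one-way ANOVA with Tukey–Kramer post-hoc pairs (studentized
range; unequal n handled by the Kramer form); the degenerate case of
identical groups with zero variance returns F = 0, p = 1 with a flag.

## Module preservation

Each module learned in a reference dataset is scored in a test dataset by
two composites: density (mean off-diagonal intramodule adjacency in test)
and connectivity (the median of two correlations — intramodular
connectivity profiles ref vs test, and intramodule adjacency entries ref
vs test). The null reassigns the test network's module labels to random
same-size gene sets over the common universe, keeping the reference
membership fixed; permuting both sides instead lets module-contaminated
random sets mimic preservation and inverts the statistic. Z-scores
standardize observed against null (ddof = 1), Zsummary is the mean of
Zdensity and Zconnectivity, and the conventional bands apply: below 2, no
evidence; above 10, strong preservation. At least 50 permutations are
required (default 200).

## Enrichment statistics

Fisher's exact test is two-sided under the probability-ordering definition
(all tables with fixed margins whose probability does not exceed the
observed one), with the ad/bc odds-ratio convention — this matters for
degenerate tables, where both fully separated tables are equally extreme
and the two-sided minimum is twice the single-table probability. The
random-set control mirrors blinded in-situ scoring: positivity defaults to
score {3} (BG-specific), with {2, 3} selectable; random comparison lists
are drawn without replacement from scored non-candidate genes. GSEA uses
the weighted running sum (hit steps |score|^p normalized by the in-set
total, p = 1 by default; miss steps −1/(N − |S|)); ES is the signed
extremum; the null shuffles gene labels; NES divides ES by the mean |ES|
of same-sign permutations; the permutation p is the same-sign exceedance
fraction with add-one smoothing so it is never exactly zero; across a
collection, FDR follows the same-sign NES-ratio convention.

## Single-cell overdispersion

Cells are depth-normalized to a fixed 10,000-count total (a fixed target
keeps the statistic invariant to global rescaling), log1p-transformed, and
genes z-scored. A gene set's score is λ₁, the fraction of its total
variance on the first principal component; the null is λ₁ of random
same-size gene sets (default 200), and Z = (λ₁ − null mean)/null sd. With
multiple sets tested, a Bonferroni-style adjustment on the normal scale
converts the tail probability; Z > 1.96 corresponds to p < 0.05. Per-cell
scores are first-component projections oriented so the top-loading gene is
positive. Cell flagging thresholds at median + k·(1.4826·MAD) rather than
mean + k·sd: when the signature population is a sizable fraction p of
cells, the mean/sd cutoff sits at `p·m + k·√(p(1−p))·m`, which for p = 0.2
and k = 2 equals the signature mode itself and caps recall near 50%; the
robust cutoff tracks the unperturbed bulk. The non-robust rule remains
available.

## Cross-species comparison

Harmonization keeps only one-to-one ortholog records (records sharing a
gene with any other record count as not single-copy) and drops rRNA- and
mitochondria-flagged genes, reporting a tally per reason. Species
differential expression reuses the NB Wald machinery with species as the
factor and batch as a covariate when it is not confounded with species;
global comparability is the Spearman correlation (average ranks on ties,
t-approximation p) of per-species mean shifted-log expression. Marker
panels report fractions up / down / unchanged at padj < 0.05.

## Orchestration and problem sizes

The pipeline derives each stage's seed as `global_seed XOR crc32(stage)`,
so a rerun of the same config is identical and stages are independently
reproducible. Benchmarks and the acceptance script run at desk scale —
2,200 genes × 27 samples for bulk recovery, 500 genes × 1,000 cells for
single-cell scoring, 2,000 genes × 5 + 5 samples for the cross-species
null, 200 permutations for preservation and 1,000 for GSEA — sizes chosen
so the full suite completes in about a minute on one CPU while leaving
every statistic comfortably inside its asymptotic regime.

## Known limitations

- The static height cut can absorb a few background genes into a strong
  module at lenient heights; the default 0.95 keeps module purity ≥ 0.95
  on the benchmark but is a tunable, not a guarantee.
- Dispersion is unshrunk; see the DE section for the n = 3 calibration
  consequence.
- The preservation composite is a two-statistic reduction of a much larger
  family; it matches the 2/10 interpretation bands but is not numerically
  comparable to other tools' Zsummary.
- GSEA reports no leading-edge subsets and uses plain permutation
  p-values, not adaptive multi-level estimation.
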