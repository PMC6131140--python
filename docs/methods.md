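# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic-cohort experiments do and do not
demonstrate.

## Synthetic cohorts

The generator emulates the structure of a 25-patient anaplastic-meningioma
study: two latent transcriptome subgroups (12 C1 / 13 C2), multi-omic
layers, and survival follow-up. It is first-class, tested code — every
downstream stage is validated against its planted truth.

**Expression.** Counts are negative binomial with Var = μ + αμ² (global
α = 0.1 by default, per-gene optional). The mean model is
μ_gj = s_j · q_g · 2^(L·1[g marker ∧ j∈C1]) · 2^(b_g·batch_j), with
baselines q_g ~ logNormal(log 50, 1.3), library scales s_j ~
logNormal(0, 0.15) (geometric mean 1), marker effect L = 5 log2 units on 6
genes, and a batch coefficient b_g ∈ {0, ±batch_lfc} on a configurable
fraction of genes (default half). Seven housekeeping transcripts (RPL37A,
EIF2B1, CASC3, IPO8, MRPL19, PGK1, POP4 — a published control set for
transcript assays in meningioma) are simulated with no subgroup effect;
whether they carry the batch effect is a flag (`batch_affects_controls`,
default off). Batch assignment is random by default; `batch_confound` sets
the probability that a sample's batch follows its subgroup, for
confounding stress tests.

**Survival.** Exponential event times at 5×10⁻⁴ events/day for C2 (mean
≈ 5.5 years, matching a cohort in which most favourable-subgroup patients
are alive at follow-up) and 17× that rate for C1, administratively censored
at 5 years. Proportional hazards holds by construction, so hazard-ratio
recovery is well defined.

**Methylation.** Beta values arise by logistic transform of Gaussian
M-values (σ = 0.3 on the natural-logit scale), giving bimodal baselines
without boundary pathologies. Fifty planted probes get a group beta-value
difference of 0.3 (direction random), always on autosomal promoter/island
CpGs passing the detection and SNP filters so they survive standard
filtering; logistic averaging attenuates the realised mean difference by a
few percent, which the generator tests account for. Non-planted probes get
realistic annotation (≈5% X/Y, 3% SNP-adjacent, 40% promoter, 30% island,
2% with a detection failure in one sample).

**Copy number.** A reduced synthetic genome (six chromosomes, 0.9 Gb
total — full-genome coordinates would only slow the binning without adding
information) with neutral backgrounds at ploidy 2 (80%) or 4 (20%),
whole-chromosome single-copy changes with probability 0.15 per chromosome,
and planted focal (0.2–0.9 Mb) windows: zero copies over a tumour
suppressor or 6–8 / 10–12 copies over an oncogene on diploid / tetraploid
backgrounds. Driver-gene coordinates (CDKN2A, NF2, SMARCB1, MYCN, CDK4)
are placements on this synthetic genome, not real positions.

**Catalogues.** Poisson counts around exposures × profiles over the
canonical 96 trinucleotide channels. Default profiles are two
disjoint-support signatures (flat over the C>T and C>A contexts), default
exposures 500–3000 mutations per sample with random mixing weights.

What the generator does **not** emulate: read-level noise, IDAT
intensities, genomic covariance structure (LD, replication timing),
gene–gene correlation beyond the planted factors, non-proportional
hazards, and cell-type composition effects in methylation. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated models, not robustness to every artefact of real tumour data.

## Expression subtyping

Size factors are median-of-ratios over genes expressed in all samples,
rescaled to geometric mean 1. The variance-stabilising transform is
log2(normalised + 1) with optional shrinkage toward the gene mean, weight
w = α̂/(α̂+1) from the method-of-moments dispersion — an explicit,
monotone, testable stand-in for regularised-log transforms; bit-equality
with any external implementation is deliberately not a goal. Poisson
distances follow the deviance formula with the shared-rate MLE split by
size factors. Clustering uses scipy's agglomerative linkage (complete by
default, configurable {complete, average, ward}; recorded in the
partition's provenance) on the top-250-variance transcripts; k is chosen
by maximum mean silhouette over k = 2..5, ties to the smallest k. PCA
(top-500-variance genes, gene-centred, unscaled) fixes each component's
sign so its largest-magnitude loading is positive.

## Differential expression

Per gene, IRLS for the NB log-link regression (max 50 iterations,
|Δcoef| < 1e-8, ridge 1e-6 for separability), vectorised across genes.
Dispersions: method-of-moments estimates, trend α(μ) = a/μ + b fitted by
least squares, log-scale shrinkage with weight 0.5 toward the trend —
enough stabilisation for 25-sample fits while keeping the estimator
transparent. Genes with base mean < 1 are excluded from testing
(reported); non-convergent genes get missing p-values and are excluded
from the BH denominator. Null calibration at these settings is ≈0.046
rejections at p < 0.05 (the acceptance suite checks 0.035–0.065).

The control-gene factor is the leading singular vector of the centred
log-normalised housekeeping submatrix, scaled to unit variance — valid
because housekeeping expression is biologically constant, so its
covariation is technical. Hidden factors are principal components of
expression residuals after projecting out the intercept, the control
factor **and the condition of interest**. Protecting the condition is a
deliberate choice: with only six very strong markers, an unprotected
factor simply re-learns the subgroup axis and absorbs the effect being
tested. The batch-confounding stress test uses batch_lfc = 2 on half the
genes including controls and P(batch follows subgroup) = 0.6 — strong
association without collinearity. A documented limitation: when batch and
subgroup are nearly collinear (confound probability ≳ 0.8, i.e. only one
or two discordant samples), no covariate adjustment can identify the
subgroup effect and the planted markers are lost; this is a property of
the design, not of the estimator.

## Marker minimisation

Candidates are the top-50 |PC1| transcripts passing |log2FC| > 4 and
padj < 1e-4 in the primary (and optionally a secondary) comparison,
ordered by |PC1| (ties by gene id). "Iterative reduction" is greedy prefix
elimination: drop the weakest PC1 contributor while reclustering on the
remaining genes still matches the reference partition exactly (ARI = 1,
labels swappable); stop at the first failure. This makes the returned set
recapitulating by construction and every superset along the path
recapitulating too. Exhaustive minimum-size search over all subsets is
available for ≤ 20 candidates and bounds the greedy result from below in
tests. On clean synthetic cohorts the panel often shrinks to one or two
transcripts — a single 32-fold marker separates the groups perfectly;
noisier data keeps more. A PCA separation score (silhouette of the
reference split in PC1–PC2 space) is reported but not binding.

## Survival

Kaplan–Meier uses the left-continuous convention (subjects censored at an
event time remain at risk there). The log-rank test accumulates
hypergeometric moments per distinct event time with the standard tie
correction d(n−d)/(n−1). The hazard ratio is the score-based
Mantel–Haenszel/Peto estimator exp((O₁−E₁)/V) with CI
exp((O₁−E₁)/V ± 1.96/√V); the commercial package the field typically uses
reports the same form, and its CI covers the true HR in ≈98% of simulated
25-patient cohorts here. The χ² p-value is anticonservative relative to
the exact permutation null in very small samples (absolute error up to
~0.08 at n = 8, shrinking with n); the test suite quantifies this against
a vectorised permutation oracle and verifies agreement within Monte-Carlo
error on a 100-subject tie-free table.

## Methylation

Detection-p exclusion drops a probe failing (p > 0.01) in **any** sample —
the strictest reading of "positions with background signal"; per-sample
masking is available as an option. Δβ for more than two groups is the
maximum pairwise group-mean difference (the plain difference for two).
Supervised clustering uses Manhattan distances with Ward linkage (the
Lance–Williams recurrence applied to L1 distances, as R's hclust does);
unsupervised clustering uses the 75 highest-variance probes with complete
linkage. Array normalisation and IDAT processing are out of scope — the
module ingests beta values plus detection p-values.

## Copy number

"Relative copy-number change adjusting for ploidy" is total_cn − ploidy
(zero meaning no change on any background); a log2(total_cn/ploidy)
option exists. Bins take the value of the segment covering their
midpoint; uncovered bins count as no change. The diploid/tetraploid
amplification boundary is ploidy ≤ 3 → threshold 5, else 9. Gene–segment
overlap is ≥ 1 bp; focality is judged on segment length (< 1 Mb), not
overlap length.

## Signatures

KL-NMF via multiplicative updates (scikit-learn's solver), best of
n_restarts by generalised KL; signatures L1-normalised with scale moved
into exposures, so exposures are expected mutation counts. Stability is
the mean cosine of Hungarian-matched signatures across restarts — a
desk-scale simplification of bootstrap-clustering stability frameworks.
Model selection scores each k by mean stability minus reconstruction KL
relative to k = 1, which picks the planted k = 2 reliably on two-signature
cohorts. Zero-count channels use the 0·log 0 = 0 convention.

## Enrichment

The hypergeometric overlap test is upper-tail P(X ≥ overlap). Functional
class scoring uses mean |statistic| per set against same-size random gene
draws (without replacement) from the universe of genes with a statistic;
sets with < 80% coverage are skipped and logged. Hallmark-level p-values
combine member sets with Fisher's method (p floored at 1/n_perm) — an
explicit design choice, since no aggregation rule is canonical. The
universe defaults to all genes with a computed statistic and is
configurable; overlap p-values are sensitive to this choice.

## Problem sizes and determinism

Synthetic experiments use 2000 genes, 2000 probes, 25 samples and a
0.9-Gb genome — scales at which every stage's statistical behaviour
(calibration, recovery, coverage) is measurable while the full suite and
the acceptance script each run in minutes on one core. All randomness
flows from a single root seed through stable per-stage derived seeds
(CRC32 of the stage name mixed with the root), so any stage is
individually reproducible and pipeline reports are content-identical
across reruns.
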