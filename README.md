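# meningiomics

Multi-omic subgroup discovery for anaplastic (WHO grade III) meningioma.

Anaplastic meningiomas are aggressive meningeal tumours whose transcriptomes
split into two prognostic subgroups — C1 (poor prognosis, SWI/SNF-mutant
enriched) and C2 (favourable) — that can be recapitulated by a handful of
marker transcripts and are mirrored in promoter methylation. This package
implements that discovery chain as a tested, reusable pipeline for
statistically minded genomics researchers, exercised end to end on synthetic
multi-omic cohorts with known ground truth (the original patient data is
controlled-access).

## The analysis chain

* **Expression subtyping** — median-of-ratios size factors
  `s_j = median_g (k_gj / (∏_j k_gj)^{1/n})`; a variance-stabilising
  `log2(k/s + 1)` transform; Poisson deviance dissimilarity between samples
  `d(a,b) = √Σ_g [dev(x_ga; μ_ga) + dev(x_gb; μ_gb)]` with the shared-rate
  MLE `μ_ga = s_a (x_ga + x_gb)/(s_a + s_b)`, computed over the 250 most
  variable transcripts; hierarchical clustering with silhouette-based
  selection of k.
* **Differential expression** — per-gene negative-binomial log-linear
  regression (Var = μ + αμ²) with size-factor offsets, method-of-moments
  dispersion shrunk toward an `α(μ) = a/μ + b` trend, Wald tests on the
  subgroup coefficient, Benjamini–Hochberg correction; unwanted variation is
  absorbed by a control-gene (housekeeping) factor plus hidden factors
  orthogonal to both the known covariates and the comparison.
* **Marker minimisation** — intersect the top-50 |PC1|-loading transcripts
  (PCA on the top-500 variable genes) with genes at |log2FC| > 4 and
  padj < 1e-4, then greedily drop the weakest PC1 contributor while
  unsupervised reclustering still reproduces the partition (ARI = 1).
* **Survival** — Kaplan–Meier curves, the log-rank (Mantel-Cox) test, and
  the Mantel–Haenszel hazard ratio `HR = exp((O₁−E₁)/V)` with 95% CI
  `exp((O₁−E₁)/V ± 1.96/√V)`.
* **Methylation** — EPIC-style probe exclusions (detection p > 0.01 in any
  sample, SNP within 10 bp, X/Y, non promoter-and-island), per-probe ANOVA
  at FDR < 0.01 with a Δβ > 0.2 effect gate, Manhattan/Ward clustering, and
  unsupervised clustering on the 75 highest-variance probes.
* **Copy number** — ploidy-adjusted aggregate profiles (total copies minus
  ploidy, median and quartiles in 10-kb bins) and focal (< 1 Mb) driver
  rules: homozygous deletions over tumour suppressors; oncogene
  amplifications above 5 copies (diploid) or 9 (tetraploid); truncating
  variants in tumour suppressors.
* **Mutational signatures** — multi-restart KL-NMF over 96-channel
  trinucleotide catalogues with Hungarian-matched stability scores and NNLS
  exposure attribution.
* **Enrichment** — upper-tail hypergeometric overlap tests and permutation
  functional class scoring over hallmark-mapped gene-set collections.

The synthetic cohort generator (`meningiomics.synthetic_cohort`) plants all
of the corresponding ground truth: subgroup labels, marker genes, a
laboratory batch effect carried by housekeeping controls, exponential
survival with a true hazard ratio, differentially methylated promoter/island
probes, focal CNV drivers, and signature exposures.

## Worked example

The numbered drivers under `analysis/` run the whole study on one simulated
cohort (writing tables under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_expression_subtyping.py
python analysis/05_survival.py
```

prints (abridged):

```
wrote cohort to results/cohort: 2000 genes x 25 samples; markers=['G0044', ...]
silhouette profile: {2: 0.675, 3: 0.439, 4: 0.428, 5: 0.426}
selected k=2; ARI against planted labels = 1.000
log-rank chi2=16.89, p=3.97e-05
Mantel-Haenszel HR (C1 vs C2) = 10.1 (95% CI 3.4-30.6); true HR = 17.0
```

The silhouette profile peaks at two clusters, the clustering reproduces the
planted C1/C2 labels exactly, and the hazard-ratio CI covers the generating
value (a 25-patient cohort estimates a true HR of 17 with wide uncertainty —
here the point estimate is 10.1 and the CI spans 3.4–30.6). The remaining
scripts cover differential expression with batch correction, the minimal
marker panel, methylation, copy number, signatures and enrichment.

The same chain is available as a CLI over a single YAML config:

```bash
meningiomics run-all --seed 1 --outdir results/pipeline
meningiomics subtype --config my_config.yaml
```

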