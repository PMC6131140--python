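"""Expression-based subgroup discovery.

Normalisation (median-of-ratios size factors), a variance-stabilising log
transform, TPM, top-variance gene selection, Poisson-deviance sample
dissimilarity, agglomerative clustering with silhouette-based choice of the
number of clusters, and PCA over the most variable transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score


class NormalizationError(ValueError):
    """No gene is expressed in every sample; size factors undefined."""


class DegenerateInputError(ValueError):
    """Input carries no usable variation (e.g. constant matrix)."""


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    values
        ``(n_genes, n_samples)`` array of counts.
    gene_ids, sample_ids
        Unique row / column identifiers.
    size_factors
        Per-sample depth-normalisation scalars ``s_j``; computed lazily by
        :func:`size_factors` when absent.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match identifier lists")
        if np.any(self.values < 0):
            raise ValueError("negative counts")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if np.any(self.size_factors <= 0):
                raise ValueError("size factors must be positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, size_factors=None) -> "CountMatrix":
        return cls(
            values=frame.to_numpy(),
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            size_factors=size_factors,
        )

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if np.any(idx < 0):
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return CountMatrix(
            self.values[idx], list(gene_ids), list(self.sample_ids), self.size_factors
        )

    def with_size_factors(self) -> "CountMatrix":
        if self.size_factors is None:
            self.size_factors = size_factors(self)
        return self


@dataclass
class TransformedMatrix:
    """Variance-stabilised (rlog-like) expression values, genes x samples."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    transform_meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample dissimilarity with zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]
    method: str = "poisson"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < -1e-12):
            raise ValueError("negative distances")
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, None)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class SubgroupPartition:
    """Sample -> cluster assignment with provenance of how it was made."""

    labels: dict[str, int]
    k: int
    linkage: str
    n_top_genes: int | None = None
    method: str = "poisson+hclust"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if len(set(self.labels.values())) > self.k:
            raise ValueError("more labels than k")

    def label_vector(self, sample_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in sample_ids])


@dataclass
class PCAResult:
    """Principal components of gene-centred expression.

    ``loadings`` is genes x components (orthonormal columns), ``scores``
    samples x components, and ``variance_explained`` the fraction of total
    variance per component (non-increasing).
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios depth normalisation.

    For each gene expressed in every sample, form the ratio of each sample's
    count to the gene's geometric mean; the sample's size factor is the
    median ratio over those genes, rescaled so the factors have geometric
    mean 1.
    """
    x = counts.values.astype(float)
    allpos = np.all(x > 0, axis=1)
    if not np.any(allpos):
        raise NormalizationError("no gene with nonzero counts in all samples")
    sub = x[allpos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    s = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return s / np.exp(np.mean(np.log(s)))


def vst_transform(counts: CountMatrix, shrink: bool = True) -> TransformedMatrix:
    """log2(normalised count + 1) with optional shrinkage to the gene mean.

    The shrinkage weight grows with the gene's method-of-moments NB
    dispersion, ``w = alpha / (alpha + 1)``, pulling noisy low-information
    genes toward their mean — an explicit, testable stand-in for regularised
    log transforms. Strictly monotone per gene in the input counts.
    """
    counts = counts.with_size_factors()
    norm = counts.values / counts.size_factors[None, :]
    y = np.log2(norm + 1.0)
    meta = {"pseudocount": 1.0, "shrinkage": shrink}
    if shrink:
        mu = norm.mean(axis=1)
        var = norm.var(axis=1, ddof=1) if counts.n_samples > 1 else np.zeros_like(mu)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(mu > 0, np.maximum((var - mu) / mu**2, 0.0), 0.0)
        w = (alpha / (alpha + 1.0))[:, None]
        y = (1.0 - w) * y + w * y.mean(axis=1, keepdims=True)
        meta["mean_shrink_weight"] = float(np.mean(w))
    return TransformedMatrix(y, list(counts.gene_ids), list(counts.sample_ids), meta)


def compute_tpm(counts: CountMatrix, gene_lengths: np.ndarray) -> pd.DataFrame:
    """Transcripts per kilobase per million reads; columns sum to 1e6."""
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != counts.n_genes:
        raise ValueError("one length per gene required")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    rate = counts.values / lengths[:, None]
    denom = rate.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(denom > 0, rate / denom * 1e6, 0.0)
    return pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids)


def top_variable_genes(matrix: TransformedMatrix, n: int) -> list[str]:
    """Ids of the ``n`` genes with largest variance; ties broken by gene id."""
    if n > len(matrix.gene_ids):
        raise ValueError("n exceeds number of genes")
    var = matrix.values.var(axis=1, ddof=1)
    order = sorted(range(len(var)), key=lambda i: (-var[i], matrix.gene_ids[i]))
    return [matrix.gene_ids[i] for i in order[:n]]


def _poisson_deviance(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Unit Poisson deviance contribution x*log(x/mu) - (x - mu), 0*log0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(x / mu), 0.0)
    return term - (x - mu)


def poisson_distance(
    counts: CountMatrix, gene_subset: list[str] | None = None
) -> DistanceMatrix:
    """Poisson-deviance dissimilarity between samples.

    For each pair (a, b) the shared per-gene rate is estimated under equal
    underlying abundance, split in proportion to the size factors:
    ``mu_ga = s_a (x_ga + x_gb) / (s_a + s_b)``. The distance is the square
    root of the summed deviances of both samples against those shared means.
    """
    counts = counts.with_size_factors()
    if gene_subset is not None:
        if len(gene_subset) == 0:
            raise ValueError("gene_subset must be nonempty")
        counts = CountMatrix(
            counts.subset_genes(gene_subset).values,
            list(gene_subset),
            list(counts.sample_ids),
            counts.size_factors,
        )
    x = counts.values.astype(float)
    s = counts.size_factors
    n = counts.n_samples
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            tot = x[:, a] + x[:, b]
            mu_a = s[a] * tot / (s[a] + s[b])
            mu_b = s[b] * tot / (s[a] + s[b])
            dev = _poisson_deviance(x[:, a], mu_a) + _poisson_deviance(x[:, b], mu_b)
            d[a, b] = d[b, a] = np.sqrt(max(dev.sum(), 0.0))
    return DistanceMatrix(d, list(counts.sample_ids), method="poisson")


def hierarchical_partition(
    dist: DistanceMatrix, k: int, linkage: str = "complete"
) -> SubgroupPartition:
    """Agglomerative clustering of a precomputed dissimilarity, cut at k.

    Tie handling is scipy's deterministic merge order; the linkage method is
    recorded in the returned partition's provenance.
    """
    n = len(dist.sample_ids)
    if k > n:
        raise ValueError("k cannot exceed the number of samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    z = scipy_linkage(dist.condensed(), method=linkage)
    flat = fcluster(z, t=k, criterion="maxclust")
    return SubgroupPartition(
        labels=dict(zip(dist.sample_ids, (int(c) for c in flat))),
        k=int(len(np.unique(flat))),
        linkage=linkage,
    )


def select_k_silhouette(
    dist: DistanceMatrix, k_range=range(2, 6), linkage: str = "complete"
) -> tuple[int, dict[int, float]]:
    """Pick the cluster number maximising mean silhouette width.

    Each candidate k is evaluated on the hierarchical partition cut at k,
    using the precomputed dissimilarity; ties go to the smallest k.
    """
    n = len(dist.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for silhouette selection")
    profile: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        part = hierarchical_partition(dist, k, linkage=linkage)
        lab = part.label_vector(dist.sample_ids)
        if len(np.unique(lab)) < 2:
            profile[k] = -1.0
            continue
        profile[k] = float(
            silhouette_score(dist.values, lab, metric="precomputed")
        )
    best = max(sorted(profile), key=lambda k: (profile[k], -k))
    return best, profile


def pca_top_variable(matrix: TransformedMatrix, n_top: int = 500) -> PCAResult:
    """PCA of samples over the ``n_top`` most variable genes.

    Genes are centred but not scaled; the sign of each component is fixed so
    the largest-magnitude loading is positive.
    """
    if n_top > len(matrix.gene_ids):
        raise ValueError("n_top exceeds number of genes")
    if len(matrix.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    genes = top_variable_genes(matrix, n_top)
    idx = pd.Index(matrix.gene_ids).get_indexer(genes)
    sub = matrix.values[idx]  # genes x samples
    if np.allclose(sub.var(axis=1), 0.0):
        raise DegenerateInputError("selected genes are constant across samples")
    centered = (sub - sub.mean(axis=1, keepdims=True)).T  # samples x genes
    u, sv, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest |loading| per component positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    comps = [f"PC{i + 1}" for i in range(len(sv))]
    loadings = pd.DataFrame(vt.T, index=genes, columns=comps)
    scores = pd.DataFrame(u * sv[None, :], index=matrix.sample_ids, columns=comps)
    var_exp = sv**2 / np.sum(sv**2)
    return PCAResult(loadings=loadings, scores=scores, variance_explained=var_exp)
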