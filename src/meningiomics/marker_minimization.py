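"""Minimal marker-panel extraction.

Candidate transcripts are the top PC1-loading genes intersected with
stringently differentially expressed genes in one or two comparisons; the
panel is then iteratively reduced (dropping the weakest PC1 contributor at
each step) to the smallest set whose unsupervised reclustering still
reproduces the C1/C2 partition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .differential_expression import DEResult
from .expression_subtyping import (
    CountMatrix,
    PCAResult,
    SubgroupPartition,
    hierarchical_partition,
    pca_top_variable,
    poisson_distance,
    vst_transform,
)


@dataclass
class MarkerCandidateSet:
    """PC1-ranked marker candidates passing all DE thresholds.

    ``table`` is ordered by descending |PC1| coefficient (ties by gene id)
    with columns pc1, log2FoldChange_a, padj_a and, when a second comparison
    gated candidacy, log2FoldChange_b / padj_b.
    """

    table: pd.DataFrame
    n_top: int
    lfc_min: float
    padj_max: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MinimalMarkerSet:
    """Result of the panel-reduction search."""

    gene_ids: list[str]
    recapitulation: bool
    reference_k: int = 2
    pca_silhouette: float | None = None
    search: str = "greedy"
    path_sizes: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def candidate_markers(
    pca: PCAResult,
    de_a: DEResult,
    de_b: DEResult | None = None,
    n_top: int = 50,
    lfc_min: float = 4.0,
    padj_max: float = 1e-4,
) -> MarkerCandidateSet:
    """Intersect top |PC1| transcripts with stringent DE sets.

    A gene qualifies if it is among the ``n_top`` genes by absolute PC1
    coefficient and has |log2FC| > ``lfc_min`` with padj < ``padj_max`` in
    the primary comparison (and in the secondary one when provided). An
    empty intersection is a valid (empty) result.
    """
    if n_top <= 0 or lfc_min < 0 or padj_max <= 0:
        raise ValueError("thresholds must be positive")
    pc1 = pca.loadings["PC1"]
    ranked = sorted(pc1.index, key=lambda g: (-abs(pc1[g]), g))[:n_top]

    def passes(de: DEResult, g: str) -> bool:
        if g not in de.table.index:
            return False
        row = de.table.loc[g]
        return (
            bool(row["tested"])
            and np.isfinite(row["padj"])
            and abs(row["log2FoldChange"]) > lfc_min
            and row["padj"] < padj_max
        )

    keep = [g for g in ranked if passes(de_a, g) and (de_b is None or passes(de_b, g))]
    data = {
        "pc1": [float(pc1[g]) for g in keep],
        "log2FoldChange_a": [float(de_a.table.loc[g, "log2FoldChange"]) for g in keep],
        "padj_a": [float(de_a.table.loc[g, "padj"]) for g in keep],
    }
    if de_b is not None:
        data["log2FoldChange_b"] = [
            float(de_b.table.loc[g, "log2FoldChange"]) for g in keep
        ]
        data["padj_b"] = [float(de_b.table.loc[g, "padj"]) for g in keep]
    table = pd.DataFrame(data, index=pd.Index(keep, name="gene"))
    return MarkerCandidateSet(table=table, n_top=n_top, lfc_min=lfc_min, padj_max=padj_max)


def _recapitulates(
    genes: list[str], counts: CountMatrix, reference: SubgroupPartition
) -> bool:
    if len(genes) < 1:
        return False
    dist = poisson_distance(counts, gene_subset=genes)
    try:
        part = hierarchical_partition(dist, k=2, linkage=reference.linkage)
    except ValueError:
        return False
    ref = reference.label_vector(dist.sample_ids)
    got = part.label_vector(dist.sample_ids)
    return adjusted_rand_score(ref, got) == 1.0


def _pca_separation(
    genes: list[str], counts: CountMatrix, reference: SubgroupPartition
) -> float | None:
    """Silhouette of the reference split in PC1-PC2 score space (reported,
    not binding)."""
    if len(genes) < 2:
        return None
    try:
        pca = pca_top_variable(
            vst_transform(counts.subset_genes(genes).with_size_factors()),
            n_top=len(genes),
        )
    except ValueError:
        return None
    scores = pca.scores.iloc[:, : min(2, pca.scores.shape[1])].to_numpy()
    labels = reference.label_vector(list(pca.scores.index))
    if len(np.unique(labels)) < 2:
        return None
    return float(silhouette_score(scores, labels))


def minimize_markers(
    candidates: MarkerCandidateSet,
    counts: CountMatrix,
    reference: SubgroupPartition,
    method: str = "greedy",
) -> MinimalMarkerSet:
    """Smallest candidate subset whose reclustering matches the reference.

    ``greedy`` drops the lowest-|PC1| candidate while the remaining prefix
    still recapitulates (ARI = 1 against the reference, labels swappable)
    and stops at the first failure, so every superset along the elimination
    path recapitulates too. ``exhaustive`` (candidate sets up to 20 genes)
    scans subsets by increasing size and returns a true minimum-size
    recapitulating subset.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    if reference.k != 2:
        raise ValueError("reference partition must have k=2")
    counts = counts.with_size_factors()
    genes = candidates.gene_ids

    if not _recapitulates(genes, counts, reference):
        return MinimalMarkerSet(
            gene_ids=list(genes),
            recapitulation=False,
            pca_silhouette=_pca_separation(genes, counts, reference),
            search=method,
            path_sizes=[len(genes)],
        )

    if method == "greedy":
        current = list(genes)
        path = [len(current)]
        while len(current) > 1 and _recapitulates(current[:-1], counts, reference):
            current = current[:-1]
            path.append(len(current))
        best = current
    elif method == "exhaustive":
        if len(genes) > 20:
            raise ValueError("exhaustive search limited to <= 20 candidates")
        best = list(genes)
        path = [len(genes)]
        found = False
        for size in range(1, len(genes) + 1):
            for subset in combinations(genes, size):
                if _recapitulates(list(subset), counts, reference):
                    best = list(subset)
                    found = True
                    break
            if found:
                break
    else:
        raise ValueError(f"unknown search method {method!r}")

    result = MinimalMarkerSet(
        gene_ids=best,
        recapitulation=True,
        pca_silhouette=_pca_separation(best, counts, reference),
        search=method,
        path_sizes=path,
    )
    assert _recapitulates(result.gene_ids, counts, reference)
    return result
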