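"""EPIC-style methylation analysis.

Probe filtering (detection p-value, SNP proximity, sex chromosomes,
promoter-and-island restriction), supervised differential-methylation
selection (one-way ANOVA at FDR < 0.01 combined with a delta-beta > 0.2
effect gate), and clustering of beta values with Manhattan distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .differential_expression import bh_adjust
from .expression_subtyping import DegenerateInputError, SubgroupPartition

VALID_CHROMS = {str(c) for c in range(1, 23)} | {"X", "Y"}


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with detection p-values."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        b = self.beta.to_numpy(float)
        if np.any((b < 0) | (b > 1)):
            raise ValueError("beta values must lie in [0, 1]")
        if self.detection_p.shape != self.beta.shape:
            raise ValueError("detection p matrix must match beta matrix shape")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation.

    ``table`` columns: chrom (1..22, X, Y), snp_maf_10bp (common SNP within
    the first 10 bp of the interrogated CpG), promoter (TSS / 5'UTR / first
    exon), island (CpG island), and optionally pos and gene.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "snp_maf_10bp", "promoter", "island"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        bad = set(self.table["chrom"].astype(str)) - VALID_CHROMS
        if bad:
            raise ValueError(f"invalid chromosomes: {sorted(bad)[:5]}")


@dataclass
class SupervisedSelection:
    """ANOVA + delta-beta selected probes.

    ``table`` (selected probes only): F, pvalue, padj, delta_beta. The full
    per-probe test table is kept in ``all_probes`` for inspection.
    """

    table: pd.DataFrame
    all_probes: pd.DataFrame
    padj_max: float
    delta_beta_min: float


def filter_probes(
    beta: BetaMatrix,
    anno: ProbeAnnotation,
    detect_p_max: float = 0.01,
    require_promoter_island: bool = True,
) -> BetaMatrix:
    """Standard EPIC probe exclusions, order-preserving.

    Drops a probe if its detection p-value exceeds ``detect_p_max`` in any
    sample, if a common SNP (MAF > 1%) lies within the first 10 bp of the
    interrogated CpG, if it maps to X or Y, or if it is not located both in
    a promoter region and a CpG island.
    """
    missing = set(beta.probe_ids) - set(anno.table.index)
    if missing:
        raise ValueError(f"annotation missing for probes: {sorted(missing)[:5]}")
    ann = anno.table.loc[beta.probe_ids]
    keep = (beta.detection_p.to_numpy() <= detect_p_max).all(axis=1)
    keep &= ~ann["snp_maf_10bp"].to_numpy(bool)
    keep &= ~ann["chrom"].astype(str).isin(["X", "Y"]).to_numpy()
    if require_promoter_island:
        keep &= ann["promoter"].to_numpy(bool) & ann["island"].to_numpy(bool)
    return BetaMatrix(beta=beta.beta.loc[keep], detection_p=beta.detection_p.loc[keep])


def _delta_beta(beta: np.ndarray, group_masks: list[np.ndarray]) -> np.ndarray:
    """Max pairwise absolute difference of group-mean beta per probe."""
    means = np.column_stack([beta[:, m].mean(axis=1) for m in group_masks])
    return means.max(axis=1) - means.min(axis=1)


def supervised_probe_selection(
    beta: BetaMatrix,
    groups: dict[str, str],
    padj_max: float = 0.01,
    delta_beta_min: float = 0.2,
) -> SupervisedSelection:
    """Per-probe one-way ANOVA across groups with a delta-beta effect gate.

    Keeps probes with BH-adjusted ANOVA p below ``padj_max`` and maximum
    pairwise group-mean beta difference above ``delta_beta_min``.
    """
    samples = beta.sample_ids
    levels = sorted(set(groups[s] for s in samples))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    masks = []
    for lv in levels:
        m = np.array([groups[s] == lv for s in samples])
        if m.sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
        masks.append(m)
    b = beta.beta.to_numpy(float)
    f_stat, pval = stats.f_oneway(*(b[:, m].T for m in masks))
    # constant probes yield nan F; they are untestable, not significant
    pval = np.where(np.isfinite(pval), pval, np.nan)
    padj = bh_adjust(pval)
    db = _delta_beta(b, masks)
    all_probes = pd.DataFrame(
        {"F": f_stat, "pvalue": pval, "padj": padj, "delta_beta": db},
        index=beta.beta.index,
    )
    sel = (all_probes["padj"] < padj_max) & (all_probes["delta_beta"] > delta_beta_min)
    sel = sel.fillna(False)
    return SupervisedSelection(
        table=all_probes[sel],
        all_probes=all_probes,
        padj_max=padj_max,
        delta_beta_min=delta_beta_min,
    )


def methylation_clustering(
    beta: BetaMatrix,
    mode: str = "unsupervised",
    probe_ids: list[str] | None = None,
    n_top: int = 75,
    k: int = 2,
    linkage: str | None = None,
) -> SubgroupPartition:
    """Cluster samples on beta values with Manhattan (L1) distances.

    ``supervised`` clusters the given differentially methylated probes with
    Ward linkage; ``unsupervised`` uses the ``n_top`` highest-variance
    probes (default 75) with complete linkage unless overridden.
    """
    if mode == "supervised":
        if probe_ids is None:
            raise ValueError("supervised mode requires probe_ids")
        sub = beta.beta.loc[probe_ids]
        linkage = linkage or "ward"
    elif mode == "unsupervised":
        var = beta.beta.var(axis=1)
        n_use = min(n_top, len(var))
        order = sorted(beta.probe_ids, key=lambda p: (-var[p], p))[:n_use]
        sub = beta.beta.loc[order]
        linkage = linkage or "complete"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 probes to cluster")
    x = sub.to_numpy(float).T  # samples x probes
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise DegenerateInputError("beta matrix constant across samples")
    d = pdist(x, metric="cityblock")
    z = scipy_linkage(d, method=linkage)
    flat = fcluster(z, t=k, criterion="maxclust")
    return SubgroupPartition(
        labels=dict(zip(beta.sample_ids, (int(c) for c in flat))),
        k=int(len(np.unique(flat))),
        linkage=linkage,
        n_top_genes=sub.shape[0],
        method=f"manhattan+{mode}",
    )
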