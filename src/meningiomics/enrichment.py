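"""Gene-set statistics: hypergeometric overlaps and functional class scoring.

The hypergeometric upper-tail test quantifies overlap between two gene
sets drawn from a common universe; functional class scoring ranks curated
gene sets (grouped into cancer hallmarks) by the mean absolute per-gene DE
statistic against a same-size random-draw permutation null, with BH
correction across sets and Fisher combination per hallmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional mapping to hallmark groups."""

    sets: dict[str, list[str]]
    hallmark_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    """Per-set scores/p-values and per-hallmark combined p-values."""

    sets: pd.DataFrame  # score, n_genes, pvalue, padj
    hallmarks: pd.DataFrame  # n_sets, pvalue
    skipped: list[str] = field(default_factory=list)


def hypergeometric_overlap(
    size_a: int, size_b: int, overlap: int, universe: int
) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, size_a, size_b)."""
    if not (0 <= overlap <= min(size_a, size_b) <= universe):
        raise ValueError("inconsistent set sizes")
    if max(size_a, size_b) > universe:
        raise ValueError("set larger than universe")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def _null_scores(
    abs_stats: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean |stat| of ``n_perm`` random draws of ``size`` genes, without
    replacement (chunked to bound memory)."""
    n = len(abs_stats)
    out = np.empty(n_perm)
    chunk = max(1, int(2e7) // max(n, 1))
    pos = 0
    while pos < n_perm:
        m = min(chunk, n_perm - pos)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        out[pos : pos + m] = abs_stats[idx].mean(axis=1)
        pos += m
    return out


def functional_class_scoring(
    gene_stats: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    min_coverage: float = 0.8,
) -> EnrichmentResult:
    """Permutation functional class scoring over a gene-set collection.

    Each set scores the mean |statistic| of its members; the p-value is the
    fraction of ``n_perm`` same-size random gene draws from the universe
    (all genes with a statistic) scoring at least as high. Sets with less
    than ``min_coverage`` of members measured are skipped and logged.
    Hallmark-level p-values combine member-set p-values with Fisher's
    method.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    if n_perm <= 0:
        raise ValueError("permutations required (n_perm > 0)")
    stats_clean = gene_stats.dropna()
    abs_stats = np.abs(stats_clean.to_numpy(float))
    universe = pd.Index(stats_clean.index)
    rng = np.random.default_rng(seed)

    rows = []
    skipped = []
    sizes_needed: dict[int, list[str]] = {}
    observed: dict[str, float] = {}
    for name, members in collection.sets.items():
        present = universe.get_indexer([m for m in members if m in universe])
        coverage = len(present) / max(len(members), 1)
        if coverage < min_coverage or len(present) == 0:
            skipped.append(name)
            logger.info("skipping set %s: coverage %.2f", name, coverage)
            continue
        observed[name] = float(abs_stats[present].mean())
        sizes_needed.setdefault(len(present), []).append(name)

    null_cache: dict[int, np.ndarray] = {}
    for size in sizes_needed:
        null_cache[size] = _null_scores(abs_stats, size, n_perm, rng)

    for size, names in sizes_needed.items():
        null = null_cache[size]
        for name in names:
            p = float(np.mean(null >= observed[name]))
            rows.append(
                {"set": name, "score": observed[name], "n_genes": size, "pvalue": p}
            )
    table = pd.DataFrame(rows).set_index("set")
    table = table.loc[[n for n in collection.sets if n in table.index]]
    table["padj"] = bh_adjust(table["pvalue"].to_numpy())

    hm_rows = []
    by_hallmark: dict[str, list[float]] = {}
    for name in table.index:
        hm = collection.hallmark_map.get(name)
        if hm is not None:
            by_hallmark.setdefault(hm, []).append(float(table.loc[name, "pvalue"]))
    for hm, ps in sorted(by_hallmark.items()):
        clipped = np.clip(ps, 1.0 / n_perm, 1.0)  # Fisher needs p > 0
        chi2 = -2.0 * np.sum(np.log(clipped))
        hm_rows.append(
            {
                "hallmark": hm,
                "n_sets": len(ps),
                "pvalue": float(stats.chi2.sf(chi2, df=2 * len(ps))),
            }
        )
    hallmarks = (
        pd.DataFrame(hm_rows).set_index("hallmark")
        if hm_rows
        else pd.DataFrame(columns=["n_sets", "pvalue"])
    )
    return EnrichmentResult(sets=table, hallmarks=hallmarks, skipped=skipped)
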