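#!/usr/bin/env python
"""Derive the minimal marker panel.

Top-500-variance PCA, intersection of the top-50 |PC1| transcripts with
the stringent DE set (|log2FC| > 4, padj < 1e-4), then greedy elimination
of the weakest PC1 contributor while unsupervised reclustering still
reproduces the C1/C2 partition exactly.
"""

from pathlib import Path

import pandas as pd

from meningiomics import io as mio
from meningiomics.expression_subtyping import (
    SubgroupPartition,
    pca_top_variable,
    vst_transform,
)
from meningiomics.differential_expression import DEResult, DesignInfo
from meningiomics.marker_minimization import candidate_markers, minimize_markers

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    counts = mio.read_counts(COHORT / "counts.tsv").with_size_factors()
    truth = mio.read_ground_truth(COHORT / "ground_truth.json")
    labels = pd.read_csv(OUT / "expression_partition.csv", index_col="sample")
    reference = SubgroupPartition(
        labels={s: int(c) for s, c in labels["cluster"].items()},
        k=2, linkage="complete",
    )
    de_table = pd.read_csv(OUT / "de_c1_vs_c2.tsv", sep="\t", index_col="gene")
    condition = {s: f"C{c}" for s, c in labels["cluster"].items()}
    de = DEResult(table=de_table, design=DesignInfo(condition=condition, reference="C2"))

    pca = pca_top_variable(vst_transform(counts), n_top=500)
    cands = candidate_markers(pca, de, n_top=50, lfc_min=4.0, padj_max=1e-4)
    print(f"{len(cands)} candidate transcripts: {cands.gene_ids}")

    minimal = minimize_markers(cands, counts, reference, method="greedy")
    cands.table.to_csv(OUT / "marker_candidates.tsv", sep="\t")
    pd.Series(minimal.gene_ids, name="gene").to_csv(OUT / "marker_panel.csv", index=False)
    print(
        f"minimal recapitulating panel ({minimal.size} transcript(s)): "
        f"{minimal.gene_ids}; subset of planted markers: "
        f"{set(minimal.gene_ids) <= set(truth.marker_ids)}"
    )


if __name__ == "__main__":
    main()
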