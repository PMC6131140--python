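#!/usr/bin/env python
"""Gene-set enrichment of the differential-expression results.

Functional class scoring (mean |Wald statistic| against a same-size random
draw null) over a synthetic hallmark-mapped collection that includes one
set containing the planted markers, plus a hypergeometric overlap test
between the stringent DE set and the planted marker set.
"""

from pathlib import Path

import pandas as pd

from meningiomics import io as mio
from meningiomics.enrichment import (
    GeneSetCollection,
    functional_class_scoring,
    hypergeometric_overlap,
)
from meningiomics.pipeline import _synthetic_gene_sets

COHORT = Path("results/cohort")
OUT = Path("results")
SEED = 20260925


def main() -> None:
    de = pd.read_csv(OUT / "de_c1_vs_c2.tsv", sep="\t", index_col="gene")
    truth = mio.read_ground_truth(COHORT / "ground_truth.json")
    stats = de["stat"].dropna()

    collection = _synthetic_gene_sets(
        list(stats.index), truth.marker_ids, n_sets=60, n_hallmarks=10, seed=SEED
    )
    res = functional_class_scoring(stats, collection, n_perm=5000, seed=SEED)
    res.sets.sort_values("pvalue").to_csv(OUT / "enrichment_sets.tsv", sep="\t")
    res.hallmarks.to_csv(OUT / "enrichment_hallmarks.tsv", sep="\t")
    top = res.sets["pvalue"].idxmin()
    print(f"top-ranked set: {top} (p={res.sets.loc[top, 'pvalue']:.2e}, "
          f"padj={res.sets.loc[top, 'padj']:.2e})")

    strict = de[(de["padj"] < 1e-4) & (de["log2FoldChange"].abs() > 4)].index
    overlap = len(set(strict) & set(truth.marker_ids))
    p = hypergeometric_overlap(
        len(strict), len(truth.marker_ids), overlap, len(stats)
    )
    print(
        f"stringent DE set ({len(strict)} genes) overlaps planted markers "
        f"({len(truth.marker_ids)}) in {overlap}; hypergeometric p = {p:.2e}"
    )


if __name__ == "__main__":
    main()
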