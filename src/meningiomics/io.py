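"""Readers and writers for the pipeline's plain-text formats.

Counts TSV (genes x samples), survival CSV, beta-value TSV with a probe
annotation TSV carrying per-sample detection p-values, SEG-like TSV with
1-based inclusive coordinates, 96-channel catalogue TSV in canonical
channel order, GMT gene-set files, and a ground-truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .copy_number import SegmentProfile
from .expression_subtyping import CountMatrix
from .methylation_pipeline import BetaMatrix, ProbeAnnotation
from .mutational_signatures import CHANNELS_96, Catalogue96
from .enrichment import GeneSetCollection
from .synthetic_cohort import GroundTruth


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(frame)


def write_survival(records: pd.DataFrame, path: str | Path) -> None:
    records[["sample", "time", "event", "group"]].to_csv(path, index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["event"] = df["event"].astype(bool)
    return df


def write_methylation(
    beta: BetaMatrix, anno: ProbeAnnotation, beta_path: str | Path, anno_path: str | Path
) -> None:
    beta.beta.to_csv(beta_path, sep="\t", index_label="probe")
    out = anno.table.copy()
    for s in beta.sample_ids:
        out[f"detection_p:{s}"] = beta.detection_p[s]
    out.to_csv(anno_path, sep="\t", index_label="probe")


def read_methylation(
    beta_path: str | Path, anno_path: str | Path
) -> tuple[BetaMatrix, ProbeAnnotation]:
    beta = pd.read_csv(beta_path, sep="\t", index_col="probe")
    raw = pd.read_csv(anno_path, sep="\t", index_col="probe")
    det_cols = [c for c in raw.columns if c.startswith("detection_p:")]
    detection = raw[det_cols].copy()
    detection.columns = [c.split(":", 1)[1] for c in det_cols]
    detection = detection[beta.columns]
    anno = raw.drop(columns=det_cols)
    anno["chrom"] = anno["chrom"].astype(str)
    return (
        BetaMatrix(beta=beta, detection_p=detection),
        ProbeAnnotation(anno),
    )


def write_segments(profiles: list[SegmentProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        for _, seg in prof.segments.iterrows():
            rows.append(
                {
                    "sample": prof.sample,
                    "chrom": seg["chrom"],
                    "start": int(seg["start"]),
                    "end": int(seg["end"]),
                    "total_cn": seg["total_cn"],
                    "ploidy": prof.ploidy,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[SegmentProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        ploidy = float(grp["ploidy"].iloc[0])
        profiles.append(
            SegmentProfile(
                sample=str(sample),
                segments=grp[["chrom", "start", "end", "total_cn"]].reset_index(drop=True),
                ploidy=ploidy,
            )
        )
    return profiles


def write_catalogue(cat: Catalogue96, path: str | Path) -> None:
    # 96 rows in canonical channel order, one column per sample
    cat.counts.T.to_csv(path, sep="\t", index_label="channel")


def read_catalogue(path: str | Path) -> Catalogue96:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    if list(df.index) != CHANNELS_96:
        raise ValueError("catalogue rows must follow the canonical 96-channel order")
    counts = df.T
    counts.index.name = None
    counts.columns.name = None
    return Catalogue96(counts=counts)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.hallmark_map.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "labels": truth.labels,
        "marker_ids": truth.marker_ids,
        "batch_factor": truth.batch_factor,
        "diff_probe_ids": truth.diff_probe_ids,
        "driver_events": [list(e) for e in truth.driver_events],
        "true_hr": truth.true_hr,
        "true_exposures": (
            truth.true_exposures.to_dict(orient="index")
            if truth.true_exposures is not None
            else None
        ),
        "control_gene_ids": truth.control_gene_ids,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    expo = payload.get("true_exposures")
    return GroundTruth(
        labels=payload.get("labels", {}),
        marker_ids=payload.get("marker_ids", []),
        batch_factor={k: int(v) for k, v in payload.get("batch_factor", {}).items()},
        diff_probe_ids=payload.get("diff_probe_ids", []),
        driver_events=[tuple(e) for e in payload.get("driver_events", [])],
        true_hr=payload.get("true_hr"),
        true_exposures=pd.DataFrame.from_dict(expo, orient="index") if expo else None,
        control_gene_ids=payload.get("control_gene_ids", []),
    )
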