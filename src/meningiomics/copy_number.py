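"""Copy-number summaries and rule-based driver calling.

Aggregate ploidy-adjusted copy-number profiles in fixed 10-kb genomic bins
(median with interquartile band across samples), plus the focal-event
driver rules: homozygous deletions over tumour suppressors, amplifications
exceeding 5 copies (diploid) or 9 copies (tetraploid) over oncogenes — both
restricted to focal (< 1 Mb) segments — and truncating point/structural
events in established tumour suppressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FOCAL_MAX_BP = 1_000_000
TRUNCATING_CONSEQUENCES = {
    "nonsense",
    "frameshift",
    "essential_splice",
    "rearrangement_breakpoint",
}
# consequence vocabulary we silently accept as non-truncating
_BENIGN_CONSEQUENCES = {
    "missense",
    "silent",
    "synonymous",
    "splice_region",
    "inframe_indel",
    "utr",
    "intronic",
}


@dataclass
class SegmentProfile:
    """One sample's total copy-number segments (1-based inclusive coords)."""

    sample: str
    segments: pd.DataFrame  # chrom, start, end, total_cn
    ploidy: float

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "total_cn"}
        if not required.issubset(self.segments.columns):
            raise ValueError(f"segments need columns {sorted(required)}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        seg = self.segments
        if (seg["start"] > seg["end"]).any():
            raise ValueError("segment end < start")
        if (seg["total_cn"] < 0).any():
            raise ValueError("negative copy number")
        for chrom, grp in seg.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments on chromosome {chrom}")


@dataclass
class AggregateProfile:
    """Per-bin median/Q1/Q3 of relative copy-number change across samples."""

    bins: pd.DataFrame  # chrom, start, end, median, q1, q3
    bin_size: int
    scale: str


@dataclass(frozen=True)
class CNVDriverCall:
    sample: str
    gene: str
    type: str  # homozygous_deletion | amplification | truncating
    focal: bool = True
    total_cn: float | None = None
    ploidy: float | None = None
    provenance: str = ""


def relative_change(total_cn: np.ndarray, ploidy: float, scale: str = "diff") -> np.ndarray:
    """Ploidy-adjusted relative copy-number change.

    ``diff`` (default) is total_cn - ploidy, so zero means no change on any
    background; ``log2`` is log2(total_cn / ploidy) with zero copies floored
    at 0.01 to keep the value finite.
    """
    cn = np.asarray(total_cn, dtype=float)
    if scale == "diff":
        return cn - ploidy
    if scale == "log2":
        return np.log2(np.maximum(cn, 0.01) / ploidy)
    raise ValueError(f"unknown scale {scale!r}")


def aggregate_profile(
    profiles: list[SegmentProfile],
    genome: dict[str, int],
    bin_size: int = 10_000,
    scale: str = "diff",
) -> AggregateProfile:
    """Median and quartile relative copy-number change in fixed bins.

    Each bin takes the value of the segment covering its midpoint (bins not
    covered by any segment count as no change, 0 on the diff scale). Bin
    statistics are computed across samples; splitting a segment into
    adjacent pieces with the same copy number changes nothing.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one sample")
    chroms = list(genome)
    frames = []
    for chrom in chroms:
        length = genome[chrom]
        starts = np.arange(1, length + 1, bin_size)
        mids = starts + (bin_size - 1) / 2.0
        values = np.zeros((len(profiles), len(starts)))
        for i, prof in enumerate(profiles):
            seg = prof.segments[prof.segments["chrom"].astype(str) == str(chrom)]
            if len(seg) == 0:
                continue
            seg = seg.sort_values("start")
            rel = relative_change(seg["total_cn"].to_numpy(), prof.ploidy, scale)
            idx = np.searchsorted(seg["start"].to_numpy(), mids, side="right") - 1
            valid = (idx >= 0) & (mids <= seg["end"].to_numpy()[np.clip(idx, 0, None)])
            values[i, valid] = rel[idx[valid]]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_size - 1, length),
                    "median": np.median(values, axis=0),
                    "q1": np.percentile(values, 25, axis=0),
                    "q3": np.percentile(values, 75, axis=0),
                }
            )
        )
    return AggregateProfile(
        bins=pd.concat(frames, ignore_index=True), bin_size=bin_size, scale=scale
    )


def _overlaps(seg_row, gene_row) -> bool:
    return (
        str(seg_row["chrom"]) == str(gene_row["chrom"])
        and seg_row["start"] <= gene_row["end"]
        and seg_row["end"] >= gene_row["start"]
    )


def call_cnv_drivers(
    profile: SegmentProfile, genes: pd.DataFrame
) -> list[CNVDriverCall]:
    """Rule-based focal CNV driver calls for one sample.

    ``genes`` columns: gene, chrom, start, end, role (TSG or oncogene).
    A homozygous deletion is a focal (< 1 Mb) zero-copy segment overlapping
    a TSG; an amplification is a focal segment over an oncogene with more
    than 5 copies on a diploid background (ploidy <= 3) or more than 9 on a
    tetraploid background.
    """
    required = {"gene", "chrom", "start", "end", "role"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    bad_roles = set(genes["role"]) - {"TSG", "oncogene"}
    if bad_roles:
        raise ValueError(f"unknown gene roles: {sorted(bad_roles)}")
    amp_threshold = 5 if profile.ploidy <= 3 else 9
    calls: list[CNVDriverCall] = []
    for _, seg in profile.segments.iterrows():
        seg_len = seg["end"] - seg["start"] + 1
        focal = seg_len < FOCAL_MAX_BP
        if not focal:
            continue
        for _, gene in genes.iterrows():
            if not _overlaps(seg, gene):
                continue
            prov = f"{seg['chrom']}:{int(seg['start'])}-{int(seg['end'])}"
            if gene["role"] == "TSG" and seg["total_cn"] == 0:
                calls.append(
                    CNVDriverCall(
                        sample=profile.sample,
                        gene=gene["gene"],
                        type="homozygous_deletion",
                        focal=True,
                        total_cn=float(seg["total_cn"]),
                        ploidy=profile.ploidy,
                        provenance=prov,
                    )
                )
            elif gene["role"] == "oncogene" and seg["total_cn"] > amp_threshold:
                calls.append(
                    CNVDriverCall(
                        sample=profile.sample,
                        gene=gene["gene"],
                        type="amplification",
                        focal=True,
                        total_cn=float(seg["total_cn"]),
                        ploidy=profile.ploidy,
                        provenance=prov,
                    )
                )
    return calls


def flag_truncating_events(
    variants: pd.DataFrame, tsg_list: list[str]
) -> list[CNVDriverCall]:
    """Flag truncating variants in established tumour suppressors.

    Truncating consequences: nonsense, frameshift, essential splice site,
    disruptive rearrangement breakpoint. Unrecognised consequence terms are
    skipped with a warning.
    """
    required = {"gene", "consequence", "sample"}
    if not required.issubset(variants.columns):
        raise ValueError(f"variant table needs columns {sorted(required)}")
    tsg = set(tsg_list)
    calls = []
    for _, row in variants.iterrows():
        cons = str(row["consequence"]).lower()
        if cons in TRUNCATING_CONSEQUENCES:
            if row["gene"] in tsg:
                calls.append(
                    CNVDriverCall(
                        sample=row["sample"],
                        gene=row["gene"],
                        type="truncating",
                        focal=True,
                        provenance=cons,
                    )
                )
        elif cons not in _BENIGN_CONSEQUENCES:
            warnings.warn(
                f"unrecognised consequence {row['consequence']!r}; variant skipped",
                stacklevel=2,
            )
    return calls
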