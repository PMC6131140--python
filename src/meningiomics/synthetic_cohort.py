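"""Synthetic multi-omic cohorts with known ground truth.

The generator emulates the data structure of the anaplastic-meningioma
study so every downstream stage is testable without controlled-access
data: two latent expression subgroups (C1/C2) with marker genes at large
fold changes, a laboratory batch effect plus stably expressed control
genes, subgroup-linked exponential survival with administrative censoring,
planted differentially methylated promoter/island probes, copy-number
segment profiles with focal drivers on diploid or tetraploid backgrounds,
and 96-channel mutation catalogues mixed from known signature profiles.

Defaults mirror the study's cohort structure: 12 C1 and 13 C2 samples, a
6-gene marker panel, a hazard ratio of 17 for C1 vs C2, and the 7-gene
housekeeping control set used for transcript-based assays in meningioma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .copy_number import SegmentProfile
from .expression_subtyping import CountMatrix
from .methylation_pipeline import BetaMatrix, ProbeAnnotation
from .mutational_signatures import CHANNELS_96, Catalogue96

#: Housekeeping transcripts treated as biologically constant across samples.
DEFAULT_CONTROL_GENES = ["RPL37A", "EIF2B1", "CASC3", "IPO8", "MRPL19", "PGK1", "POP4"]

#: Synthetic genome: chromosome -> length (bp). Coordinates of the driver
#: genes below are placed on this genome and are NOT real genomic positions.
DEFAULT_GENOME = {
    "1": 200_000_000,
    "2": 180_000_000,
    "3": 160_000_000,
    "4": 140_000_000,
    "5": 120_000_000,
    "6": 100_000_000,
}

#: Synthetic placement of recurrently altered meningioma genes.
DEFAULT_GENE_TABLE = pd.DataFrame(
    [
        {"gene": "CDKN2A", "chrom": "1", "start": 50_000_000, "end": 50_030_000, "role": "TSG"},
        {"gene": "NF2", "chrom": "2", "start": 30_000_000, "end": 30_090_000, "role": "TSG"},
        {"gene": "SMARCB1", "chrom": "3", "start": 80_000_000, "end": 80_050_000, "role": "TSG"},
        {"gene": "MYCN", "chrom": "4", "start": 60_000_000, "end": 60_006_000, "role": "oncogene"},
        {"gene": "CDK4", "chrom": "5", "start": 40_000_000, "end": 40_005_000, "role": "oncogene"},
    ]
)


class ConfigurationError(ValueError):
    """The cohort configuration is internally inconsistent."""


@dataclass
class DriverSpec:
    """A planted focal copy-number driver event."""

    gene: str
    type: str  # homozygous_deletion | amplification
    n_samples: int = 3
    samples: list[str] | None = None


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Expression: negative-binomial counts with Var = mu + alpha mu^2 (global
    ``dispersion`` alpha, optionally per-gene), ``n_markers`` genes upshifted
    by ``marker_lfc`` log2 units in C1, and an optional batch effect of
    ``batch_lfc`` log2 units (random sign) on a ``batch_frac`` fraction of
    genes. Control genes never carry the subgroup effect; they carry the
    batch effect only when ``batch_affects_controls`` is set (technical
    variation hits housekeeping genes too — the premise of control-gene
    batch correction).

    Survival: exponential times at ``surv_baseline_rate`` events/day for C2
    and ``surv_baseline_rate * surv_hr`` for C1, administratively censored
    at ``censor_time`` days.

    Methylation: Gaussian noise (sd ``m_sigma``) on the logit (M-value)
    scale; ``n_diff_probes`` probes with a planted group beta difference of
    ``delta_beta_true``, all on autosomal promoter/island CpGs that pass
    every filter.

    Copy number: neutral diploid/tetraploid backgrounds with occasional
    whole-chromosome arm changes and planted focal (< 1 Mb) drivers.

    Signatures: Poisson counts around exposures x profiles over the
    canonical 96 trinucleotide channels.
    """

    # cohort structure
    n_c1: int = 12
    n_c2: int = 13
    # expression
    n_genes: int = 2000
    n_markers: int = 6
    marker_lfc: float = 5.0
    dispersion: float | np.ndarray = 0.1
    batch_lfc: float = 0.0
    batch_frac: float = 0.5
    batch_affects_controls: bool = False
    batch_assignment: dict[str, int] | None = None
    batch_confound: float = 0.0  # P(batch follows subgroup) beyond coin flip
    control_genes: list[str] = field(default_factory=lambda: list(DEFAULT_CONTROL_GENES))
    # survival
    surv_baseline_rate: float = 5e-4
    surv_hr: float = 17.0
    censor_time: float = 1825.0
    # methylation
    n_probes: int = 2000
    n_diff_probes: int = 50
    delta_beta_true: float = 0.3
    m_sigma: float = 0.3
    # copy number
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    gene_table: pd.DataFrame = field(default_factory=lambda: DEFAULT_GENE_TABLE.copy())
    drivers: list[DriverSpec] = field(
        default_factory=lambda: [
            DriverSpec("CDKN2A", "homozygous_deletion", n_samples=5),
            DriverSpec("MYCN", "amplification", n_samples=3),
        ]
    )
    tetraploid_fraction: float = 0.2
    broad_change_prob: float = 0.15
    segments_spec: dict[str, tuple[list[tuple], float]] | None = None
    # signatures
    signature_profiles: np.ndarray | None = None
    exposure_matrix_true: np.ndarray | None = None
    # reproducibility
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_c1 + self.n_c2

    @property
    def sample_ids(self) -> list[str]:
        return [f"AM{i + 1:02d}" for i in range(self.n_samples)]

    def validate(self) -> None:
        if min(self.n_c1, self.n_c2, self.n_genes, self.n_markers) < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_c1 + self.n_c2 < 4:
            raise ConfigurationError("need at least 4 samples")
        if self.n_markers > self.n_genes - len(self.control_genes):
            raise ConfigurationError("more markers than available genes")
        if self.n_diff_probes > self.n_probes:
            raise ConfigurationError("more differential probes than probes")
        if not 0.0 <= self.delta_beta_true < 1.0:
            raise ConfigurationError("delta_beta_true must lie in [0, 1)")
        if self.delta_beta_true > 0 and self.delta_beta_true + 0.05 > 0.95:
            raise ConfigurationError("delta_beta_true pushes group means outside (0, 1)")
        if self.surv_baseline_rate <= 0 or self.surv_hr <= 0:
            raise ConfigurationError("survival rates must be positive")
        if self.censor_time < 0:
            raise ConfigurationError("censor_time must be >= 0")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ConfigurationError("dispersion must be non-negative")
        if self.signature_profiles is not None:
            p = np.asarray(self.signature_profiles, float)
            if p.shape[1] != 96 or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigurationError("signature profiles must be 96-long and sum to 1")
        if self.exposure_matrix_true is not None:
            e = np.asarray(self.exposure_matrix_true, float)
            if np.any(e < 0):
                raise ConfigurationError("exposures must be non-negative")
            if self.signature_profiles is not None and e.shape[1] != np.asarray(
                self.signature_profiles
            ).shape[0]:
                raise ConfigurationError("exposures not conformable with profiles")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream scoring."""

    labels: dict[str, str] = field(default_factory=dict)
    marker_ids: list[str] = field(default_factory=list)
    batch_factor: dict[str, int] = field(default_factory=dict)
    diff_probe_ids: list[str] = field(default_factory=list)
    driver_events: list[tuple[str, str, str]] = field(default_factory=list)
    true_hr: float | None = None
    true_exposures: pd.DataFrame | None = None
    control_gene_ids: list[str] = field(default_factory=list)


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    # per-stage child seed so each omic layer is independently reproducible
    return np.random.default_rng([config.seed, stage])


def subgroup_labels(config: CohortConfig) -> dict[str, str]:
    """Sample -> C1/C2 assignment (first ``n_c1`` samples are C1)."""
    ids = config.sample_ids
    return {s: ("C1" if i < config.n_c1 else "C2") for i, s in enumerate(ids)}


def _batch_assignment(
    config: CohortConfig, labels: dict[str, str], rng: np.random.Generator
) -> dict[str, int]:
    if config.batch_assignment is not None:
        return dict(config.batch_assignment)
    out = {}
    for s in config.sample_ids:
        if rng.random() < config.batch_confound:
            out[s] = 1 if labels[s] == "C1" else 0
        else:
            out[s] = int(rng.random() < 0.5)
    return out


def simulate_expression(config: CohortConfig) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial counts with planted subgroup markers and batch.

    Mean model per gene g, sample j:
    ``mu_gj = s_j q_g 2^(marker_lfc [g marker and j in C1]) 2^(b_g batch_j)``
    with library scale ``s_j``, baseline ``q_g`` and gene-wise batch
    coefficient ``b_g`` in {0, +-batch_lfc}. Deterministic under the config
    seed.
    """
    config.validate()
    rng = _rng(config, 1)
    labels = subgroup_labels(config)
    batch = _batch_assignment(config, labels, rng)

    controls = list(config.control_genes)
    n_free = config.n_genes - len(controls)
    gene_ids = [f"G{i + 1:04d}" for i in range(n_free)] + controls
    marker_ids = sorted(
        rng.choice(n_free, size=config.n_markers, replace=False).tolist()
    )
    marker_ids = [gene_ids[i] for i in marker_ids]

    q = rng.lognormal(mean=np.log(50.0), sigma=1.3, size=config.n_genes)
    q[n_free:] = rng.lognormal(mean=np.log(200.0), sigma=0.3, size=len(controls))
    s = rng.lognormal(mean=0.0, sigma=0.15, size=config.n_samples)
    s /= np.exp(np.mean(np.log(s)))

    is_marker = np.isin(gene_ids, marker_ids)
    is_control = np.zeros(config.n_genes, bool)
    is_control[n_free:] = True

    bcoef = np.zeros(config.n_genes)
    if config.batch_lfc != 0.0:
        eligible = (
            np.ones(config.n_genes, bool)
            if config.batch_affects_controls
            else ~is_control
        )
        affected = eligible & (rng.random(config.n_genes) < config.batch_frac)
        if config.batch_affects_controls:
            affected |= is_control  # controls always carry the technical effect
        signs = rng.choice([-1.0, 1.0], size=config.n_genes)
        bcoef = np.where(affected, signs * config.batch_lfc, 0.0)

    c1 = np.array([labels[smp] == "C1" for smp in config.sample_ids])
    batch_vec = np.array([batch[smp] for smp in config.sample_ids], float)
    log2_mu = (
        np.log2(q)[:, None]
        + np.log2(s)[None, :]
        + config.marker_lfc * (is_marker[:, None] & c1[None, :])
        + bcoef[:, None] * batch_vec[None, :]
    )
    mu = np.exp2(log2_mu)

    alpha = np.broadcast_to(np.asarray(config.dispersion, float), (config.n_genes,))
    counts = np.empty((config.n_genes, config.n_samples), dtype=np.int64)
    for g in range(config.n_genes):
        if alpha[g] <= 1e-12:
            counts[g] = rng.poisson(mu[g])
        else:
            r = 1.0 / alpha[g]
            p = r / (r + mu[g])
            counts[g] = rng.negative_binomial(r, p)

    cm = CountMatrix(counts, gene_ids, config.sample_ids)
    truth = GroundTruth(
        labels=labels,
        marker_ids=marker_ids,
        batch_factor=batch,
        true_hr=config.surv_hr,
        control_gene_ids=controls,
    )
    return cm, truth


def simulate_survival(
    config: CohortConfig, labels: dict[str, str] | None = None
) -> pd.DataFrame:
    """Exponential survival with administrative censoring.

    C2 events arrive at ``surv_baseline_rate`` per day and C1 events
    ``surv_hr`` times faster; everyone still alive at ``censor_time`` is
    censored there. ``censor_time = 0`` censors every record at time 0.
    """
    config.validate()
    rng = _rng(config, 2)
    labels = labels or subgroup_labels(config)
    missing = [s for s in config.sample_ids if s not in labels]
    if missing:
        raise ConfigurationError(f"labels missing for samples: {missing[:5]}")
    rows = []
    for s in config.sample_ids:
        rate = config.surv_baseline_rate * (
            config.surv_hr if labels[s] == "C1" else 1.0
        )
        t = rng.exponential(1.0 / rate)
        event = t < config.censor_time
        rows.append(
            {
                "sample": s,
                "time": float(min(t, config.censor_time)),
                "event": bool(event),
                "group": labels[s],
            }
        )
    return pd.DataFrame(rows)


def simulate_methylation(
    config: CohortConfig, labels: dict[str, str] | None = None
) -> tuple[BetaMatrix, ProbeAnnotation, GroundTruth]:
    """Beta values via a logistic transform of Gaussian M-values.

    Planted differential probes target a group-mean beta difference of
    ``delta_beta_true`` and always sit on autosomal promoter/island CpGs
    passing detection and SNP filters, so they survive standard probe
    filtering. Non-planted probes get realistic annotation: ~5% on X/Y,
    3% SNP-adjacent, 40% promoter, 30% island, and occasional detection
    failures.
    """
    config.validate()
    rng = _rng(config, 3)
    labels = labels or subgroup_labels(config)
    samples = config.sample_ids
    n_p, n_s = config.n_probes, config.n_samples
    probe_ids = [f"cg{i + 1:08d}" for i in range(n_p)]

    diff_idx = np.sort(rng.choice(n_p, size=config.n_diff_probes, replace=False))
    is_diff = np.zeros(n_p, bool)
    is_diff[diff_idx] = True

    chrom = rng.choice([str(c) for c in range(1, 23)], size=n_p)
    sex = (~is_diff) & (rng.random(n_p) < 0.05)
    chrom[sex] = rng.choice(["X", "Y"], size=int(sex.sum()))
    snp = (~is_diff) & (rng.random(n_p) < 0.03)
    promoter = np.where(is_diff, True, rng.random(n_p) < 0.4)
    island = np.where(is_diff, True, rng.random(n_p) < 0.3)

    # baseline betas: bimodal like real CpGs
    low = rng.beta(2, 8, size=n_p)
    high = rng.beta(8, 2, size=n_p)
    base = np.where(rng.random(n_p) < 0.5, low, high)
    base = np.clip(base, 0.03, 0.97)

    c1 = np.array([labels[s] == "C1" for s in samples])
    mean_beta = np.tile(base[:, None], (1, n_s))
    if config.delta_beta_true > 0 and config.n_diff_probes > 0:
        lo = rng.uniform(0.05, 0.95 - config.delta_beta_true, size=config.n_diff_probes)
        hi = lo + config.delta_beta_true
        up_in_c1 = rng.random(config.n_diff_probes) < 0.5
        g1 = np.where(up_in_c1, hi, lo)
        g2 = np.where(up_in_c1, lo, hi)
        mean_beta[diff_idx, :] = np.where(c1[None, :], g1[:, None], g2[:, None])

    m = logit(mean_beta) + rng.normal(0.0, config.m_sigma, size=(n_p, n_s))
    beta = pd.DataFrame(expit(m), index=probe_ids, columns=samples)

    det = rng.uniform(1e-4, 8e-3, size=(n_p, n_s))
    fail = (~is_diff) & (rng.random(n_p) < 0.02)
    for i in np.where(fail)[0]:
        det[i, rng.integers(0, n_s)] = rng.uniform(0.02, 0.2)
    detection = pd.DataFrame(det, index=probe_ids, columns=samples)

    anno = ProbeAnnotation(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": (np.arange(n_p) + 1) * 1000,
                "snp_maf_10bp": snp,
                "promoter": promoter,
                "island": island,
            },
            index=probe_ids,
        )
    )
    truth = GroundTruth(
        labels=labels, diff_probe_ids=[probe_ids[i] for i in diff_idx]
    )
    return BetaMatrix(beta=beta, detection_p=detection), anno, truth


def _plant_focal(
    segments: list[dict],
    gene: pd.Series,
    cn: int,
    rng: np.random.Generator,
    genome: dict[str, int],
) -> list[dict]:
    """Carve a focal window with copy number ``cn`` around ``gene`` out of
    the covering segment."""
    glen = gene["end"] - gene["start"] + 1
    width = int(rng.uniform(max(glen + 10_000, 200_000), 900_000))
    start = max(1, gene["start"] - int(rng.uniform(0, width - glen)))
    end = min(genome[str(gene["chrom"])], start + width - 1)
    out = []
    for seg in segments:
        if seg["chrom"] != str(gene["chrom"]) or seg["end"] < start or seg["start"] > end:
            out.append(seg)
            continue
        if seg["start"] < start:
            out.append({**seg, "end": start - 1})
        out.append({"chrom": seg["chrom"], "start": max(seg["start"], start),
                    "end": min(seg["end"], end), "total_cn": cn})
        if seg["end"] > end:
            out.append({**seg, "start": end + 1})
    return out


def simulate_segments(config: CohortConfig) -> tuple[list[SegmentProfile], GroundTruth]:
    """Copy-number segment profiles with planted focal drivers.

    Backgrounds are neutral at the sample's ploidy (diploid or tetraploid),
    with occasional whole-chromosome single-copy changes; each configured
    driver plants a focal (< 1 Mb) zero-copy (homozygous deletion) or
    high-copy (amplification, above the diploid/tetraploid rule threshold)
    window over its gene in a random subset of samples.
    """
    config.validate()
    rng = _rng(config, 4)
    samples = config.sample_ids
    genes = config.gene_table.set_index("gene")

    if config.segments_spec is not None:
        profiles = [
            SegmentProfile(
                sample=s,
                segments=pd.DataFrame(
                    spec[0], columns=["chrom", "start", "end", "total_cn"]
                ),
                ploidy=spec[1],
            )
            for s, spec in config.segments_spec.items()
        ]
        return profiles, GroundTruth()

    ploidies = {
        s: (4.0 if rng.random() < config.tetraploid_fraction else 2.0) for s in samples
    }
    carriers: dict[str, list[str]] = {}
    events: list[tuple[str, str, str]] = []
    for drv in config.drivers:
        if drv.gene not in genes.index:
            raise ConfigurationError(f"driver gene {drv.gene!r} not in gene table")
        chosen = (
            list(drv.samples)
            if drv.samples is not None
            else [samples[i] for i in rng.choice(len(samples), drv.n_samples, replace=False)]
        )
        carriers[drv.gene] = chosen
        events.extend((s, drv.gene, drv.type) for s in chosen)

    profiles = []
    for s in samples:
        ploidy = ploidies[s]
        segs: list[dict] = []
        for chrom, length in config.genome.items():
            cn = ploidy
            if rng.random() < config.broad_change_prob:
                cn = ploidy + rng.choice([-1, 1])
            segs.append({"chrom": chrom, "start": 1, "end": length, "total_cn": cn})
        for drv in config.drivers:
            if s not in carriers[drv.gene]:
                continue
            gene = genes.loc[drv.gene]
            if drv.type == "homozygous_deletion":
                cn = 0
            elif drv.type == "amplification":
                cn = int(rng.choice([6, 7, 8] if ploidy <= 3 else [10, 11, 12]))
            else:
                raise ConfigurationError(f"unknown driver type {drv.type!r}")
            gene = gene.copy()
            gene["chrom"] = str(gene["chrom"])
            segs = _plant_focal(segs, gene, cn, rng, config.genome)
        seg_df = pd.DataFrame(segs, columns=["chrom", "start", "end", "total_cn"])
        profiles.append(SegmentProfile(sample=s, segments=seg_df, ploidy=ploidy))

    truth = GroundTruth(driver_events=events)
    return profiles, truth


def make_default_signatures(k: int = 2) -> np.ndarray:
    """Simple well-separated signature profiles with disjoint support.

    Signature 1 is flat over the 16 C>T channels (deamination-like),
    signature 2 over the 16 C>A channels (oxidative-damage-like), and
    further signatures over subsequent substitution classes.
    """
    if k > 6:
        raise ValueError("at most 6 disjoint-support default signatures")
    classes = ["C>T", "C>A", "T>C", "C>G", "T>A", "T>G"]
    profiles = np.zeros((k, 96))
    for i in range(k):
        mask = [classes[i] in ch for ch in CHANNELS_96]
        profiles[i, mask] = 1.0 / 16.0
    return profiles


def simulate_catalogues(
    config: CohortConfig,
) -> tuple[Catalogue96, GroundTruth]:
    """Poisson 96-channel catalogues around exposures x signature profiles."""
    config.validate()
    rng = _rng(config, 5)
    samples = config.sample_ids
    profiles = (
        np.asarray(config.signature_profiles, float)
        if config.signature_profiles is not None
        else make_default_signatures(2)
    )
    k = profiles.shape[0]
    if config.exposure_matrix_true is not None:
        expo = np.asarray(config.exposure_matrix_true, float)
        if expo.shape[0] != len(samples):
            raise ConfigurationError("one exposure row per sample required")
    else:
        total = rng.uniform(500, 3000, size=len(samples))
        w = rng.uniform(0.1, 0.9, size=(len(samples), k))
        w /= w.sum(axis=1, keepdims=True)
        expo = total[:, None] * w
    lam = expo @ profiles
    counts = rng.poisson(lam)
    cat = Catalogue96(
        counts=pd.DataFrame(counts, index=samples, columns=CHANNELS_96)
    )
    truth = GroundTruth(
        true_exposures=pd.DataFrame(
            expo, index=samples, columns=[f"S{i + 1}" for i in range(k)]
        )
    )
    return cat, truth


@dataclass
class Cohort:
    """A fully simulated multi-omic cohort with merged ground truth."""

    counts: CountMatrix
    survival: pd.DataFrame
    beta: BetaMatrix
    probe_annotation: ProbeAnnotation
    segments: list[SegmentProfile]
    catalogue: Catalogue96
    truth: GroundTruth
    config: CohortConfig


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Run every generator under one config and merge the ground truth."""
    counts, t_expr = simulate_expression(config)
    survival = simulate_survival(config, t_expr.labels)
    beta, anno, t_meth = simulate_methylation(config, t_expr.labels)
    segments, t_seg = simulate_segments(config)
    catalogue, t_sig = simulate_catalogues(config)
    truth = GroundTruth(
        labels=t_expr.labels,
        marker_ids=t_expr.marker_ids,
        batch_factor=t_expr.batch_factor,
        diff_probe_ids=t_meth.diff_probe_ids,
        driver_events=t_seg.driver_events,
        true_hr=config.surv_hr,
        true_exposures=t_sig.true_exposures,
        control_gene_ids=t_expr.control_gene_ids,
    )
    return Cohort(
        counts=counts,
        survival=survival,
        beta=beta,
        probe_annotation=anno,
        segments=segments,
        catalogue=catalogue,
        truth=truth,
        config=config,
    )
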