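"""Pipeline orchestration: simulate -> subtype -> DE -> markers -> survival
-> methylation -> CNV -> signatures -> enrichment.

A single YAML config drives every stage; all randomness flows from one
root seed through stable per-stage derived seeds, so re-running any stage
in isolation reproduces its output. Each stage's outputs are written to
the output directory and summarised in a JSON report whose content
(runtime excluded) is identical across reruns of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from . import io as mio
from .copy_number import aggregate_profile, call_cnv_drivers
from .differential_expression import (
    DesignInfo,
    estimate_control_gene_factor,
    estimate_hidden_factors,
    nb_wald_de,
)
from .enrichment import GeneSetCollection, functional_class_scoring
from .expression_subtyping import (
    hierarchical_partition,
    pca_top_variable,
    poisson_distance,
    select_k_silhouette,
    top_variable_genes,
    vst_transform,
)
from .marker_minimization import candidate_markers, minimize_markers
from .methylation_pipeline import (
    filter_probes,
    methylation_clustering,
    supervised_probe_selection,
)
from .mutational_signatures import extract_signatures, match_signatures
from .survival_analysis import logrank_test, mh_hazard_ratio
from .synthetic_cohort import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "subtype",
    "de",
    "markers",
    "survival",
    "methylation",
    "cnv",
    "signatures",
    "enrich",
]
STAGE_DEPS = {
    "simulate": [],
    "subtype": ["simulate"],
    "de": ["subtype"],
    "markers": ["de"],
    "survival": ["subtype"],
    "methylation": ["subtype"],
    "cnv": ["simulate"],
    "signatures": ["simulate"],
    "enrich": ["de"],
}

_STAGE_DEFAULTS = {
    "subtype": {"n_top_genes": 250, "linkage": "complete", "k_min": 2, "k_max": 5},
    "de": {"padj_max": 0.01, "min_base_mean": 1.0, "n_hidden": 2, "use_covariates": True},
    "markers": {"n_top": 50, "lfc_min": 4.0, "padj_max": 1e-4, "pca_n_top": 500,
                "search": "greedy"},
    "survival": {},
    "methylation": {"padj_max": 0.01, "delta_beta_min": 0.2, "n_top_unsupervised": 75},
    "cnv": {"bin_size": 10000, "scale": "diff"},
    "signatures": {"k": 2, "n_restarts": 20},
    "enrich": {"n_perm": 2000, "n_sets": 60, "n_hallmarks": 10},
}


class PlanningError(RuntimeError):
    """An enabled stage is missing one of its upstream dependencies."""


class ConfigSchemaError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulate: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def stage_params(self, stage: str) -> dict:
        out = dict(_STAGE_DEFAULTS.get(stage, {}))
        out.update(self.params.get(stage, {}))
        return out


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the root seed."""
    return (zlib.crc32(stage.encode()) ^ (root_seed * 2654435761)) % (2**31 - 1)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known_top = {"seed", "outdir", "stages"} | set(_STAGE_DEFAULTS) | {"simulate"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigSchemaError(f"unknown config keys: {sorted(unknown)}")
    sim = raw.get("simulate", {}) or {}
    sim_fields = {f.name for f in dc_fields(CohortConfig)}
    bad = set(sim) - sim_fields
    if bad:
        raise ConfigSchemaError(f"unknown simulate keys: {sorted(bad)}")
    params = {}
    for stage, defaults in _STAGE_DEFAULTS.items():
        if stage in raw:
            section = raw[stage] or {}
            bad = set(section) - set(defaults)
            if bad:
                raise ConfigSchemaError(f"unknown keys in {stage!r}: {sorted(bad)}")
            params[stage] = section
    stages = raw.get("stages", list(STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise ConfigSchemaError(f"unknown stages: {sorted(bad)}")
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "results/pipeline")),
        stages=list(stages),
        simulate=sim,
        params=params,
    )


def _plan(stages: list[str]) -> list[str]:
    enabled = set(stages)
    for stage in enabled:
        for dep in STAGE_DEPS[stage]:
            if dep not in enabled:
                raise PlanningError(
                    f"stage {stage!r} requires {dep!r}, which is not enabled"
                )
    return [s for s in STAGES if s in enabled]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synthetic_gene_sets(
    gene_ids: list[str], marker_ids: list[str], n_sets: int, n_hallmarks: int, seed: int
) -> GeneSetCollection:
    """Random gene sets mapped to hallmark groups, plus one set holding the
    planted markers (synthetic stand-in for a curated hallmark collection)."""
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    hallmark_map: dict[str, str] = {}
    hallmarks = [f"hallmark_{i + 1}" for i in range(n_hallmarks)]
    pool = [g for g in gene_ids if g not in set(marker_ids)]
    for i in range(n_sets):
        size = int(rng.integers(10, 50))
        members = [pool[j] for j in rng.choice(len(pool), size, replace=False)]
        name = f"set_{i + 1:03d}"
        sets[name] = members
        hallmark_map[name] = hallmarks[i % n_hallmarks]
    if marker_ids:
        extra = [pool[j] for j in rng.choice(len(pool), 10, replace=False)]
        sets["planted_marker_set"] = list(marker_ids) + extra
        hallmark_map["planted_marker_set"] = hallmarks[0]
    return GeneSetCollection(sets=sets, hallmark_map=hallmark_map)


def _name_clusters(part, sample_ids: list[str], truth_labels: dict) -> dict[str, str]:
    """Name discovered clusters C1/C2/...

    With ground-truth labels available (simulated cohorts) each cluster
    takes the name of its majority true label so downstream comparisons
    (hazard ratio orientation, marker fold-change signs) line up with the
    planted truth; collisions and the no-truth case fall back to cluster-id
    order.
    """
    ids = sorted(set(part.labels.values()))
    mapping = {cid: f"C{i + 1}" for i, cid in enumerate(ids)}
    if truth_labels:
        candidate = {}
        for cid in ids:
            members = [s for s in sample_ids if part.labels[s] == cid]
            majority = pd.Series([truth_labels[s] for s in members]).mode()
            candidate[cid] = str(majority.iloc[0])
        if len(set(candidate.values())) == len(ids):
            mapping = candidate
    return {s: mapping[part.labels[s]] for s in sample_ids}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the report dict (also written to ``<outdir>/report.json``).
    Failures in one omics branch are logged and do not abort independent
    branches.
    """
    order = _plan(config.stages)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": order,
        "stage_params": {s: config.stage_params(s) for s in order if s != "simulate"},
        "input_hashes": {},
        "outputs": {},
        "errors": {},
        "runtime_s": {},
    }
    state: dict = {}
    for stage in order:
        t0 = time.time()
        try:
            _run_stage(stage, config, state, report, outdir)
        except Exception as exc:  # stage isolation
            logger.exception("stage %s failed", stage)
            report["errors"][stage] = f"{type(exc).__name__}: {exc}"
            state.setdefault("failed", set()).add(stage)
        report["runtime_s"][stage] = round(time.time() - t0, 3)
    content = {k: v for k, v in report.items() if k != "runtime_s"}
    report["content_hash"] = hashlib.sha256(
        json.dumps(content, sort_keys=True, default=str).encode()
    ).hexdigest()
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _deps_ok(stage: str, state: dict) -> bool:
    failed = state.get("failed", set())
    return not any(d in failed for d in STAGE_DEPS[stage])


def _run_stage(
    stage: str, config: PipelineConfig, state: dict, report: dict, outdir: Path
) -> None:
    if not _deps_ok(stage, state):
        raise RuntimeError("upstream dependency failed")
    params = config.stage_params(stage)

    if stage == "simulate":
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
        cohort = simulate_cohort(CohortConfig(**sim_kwargs))
        state["cohort"] = cohort
        mio.write_counts(cohort.counts, outdir / "counts.tsv")
        mio.write_survival(cohort.survival, outdir / "survival.csv")
        mio.write_methylation(
            cohort.beta, cohort.probe_annotation,
            outdir / "beta.tsv", outdir / "probe_annotation.tsv",
        )
        mio.write_segments(cohort.segments, outdir / "segments.tsv")
        mio.write_catalogue(cohort.catalogue, outdir / "catalogue.tsv")
        mio.write_ground_truth(cohort.truth, outdir / "ground_truth.json")
        for f in ["counts.tsv", "survival.csv", "beta.tsv", "probe_annotation.tsv",
                  "segments.tsv", "catalogue.tsv"]:
            report["input_hashes"][f] = _sha256(outdir / f)
        report["outputs"]["simulate"] = {
            "n_samples": cohort.counts.n_samples,
            "n_genes": cohort.counts.n_genes,
        }
        return

    cohort = state["cohort"]

    if stage == "subtype":
        counts = cohort.counts.with_size_factors()
        transformed = vst_transform(counts)
        top = top_variable_genes(transformed, params["n_top_genes"])
        dist = poisson_distance(counts, gene_subset=top)
        k_star, profile = select_k_silhouette(
            dist, range(params["k_min"], params["k_max"] + 1), linkage=params["linkage"]
        )
        part = hierarchical_partition(dist, k_star, linkage=params["linkage"])
        part.n_top_genes = params["n_top_genes"]
        named = _name_clusters(part, counts.sample_ids, cohort.truth.labels)
        state.update(partition=part, partition_named=named, dist=dist,
                     transformed=transformed)
        ari = None
        if cohort.truth.labels:
            truth_vec = [cohort.truth.labels[s] for s in counts.sample_ids]
            ari = float(adjusted_rand_score(
                truth_vec, part.label_vector(counts.sample_ids)))
        pd.Series(named).rename("cluster").to_csv(outdir / "partition.csv",
                                                  index_label="sample")
        report["outputs"]["subtype"] = {
            "k_selected": k_star,
            "silhouette_profile": {int(k): round(v, 4) for k, v in profile.items()},
            "ari_vs_truth": ari,
        }
        return

    if stage == "de":
        counts = cohort.counts.with_size_factors()
        condition = state["partition_named"]
        covariates = None
        if params["use_covariates"]:
            ctrl = estimate_control_gene_factor(
                counts, cohort.truth.control_gene_ids or cohort.config.control_genes
            )
            # hidden factors are kept orthogonal to the comparison of interest
            # as well, so they cannot absorb the subgroup effect
            cond_vec = pd.DataFrame(
                {"condition": [1.0 if condition[s] == "C1" else 0.0
                               for s in counts.sample_ids]},
                index=counts.sample_ids,
            )
            hidden = estimate_hidden_factors(
                counts, pd.concat([ctrl, cond_vec], axis=1), n=params["n_hidden"]
            )
            covariates = pd.concat([ctrl, hidden], axis=1)
        design = DesignInfo(
            condition=condition,
            reference="C2" if "C2" in set(condition.values()) else
            sorted(set(condition.values()))[-1],
            known_covariates=covariates,
            control_genes=list(cohort.truth.control_gene_ids),
            n_hidden=params["n_hidden"],
        )
        result = nb_wald_de(counts, design, min_base_mean=params["min_base_mean"])
        state["de"] = result
        result.table.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene")
        n_sig = int((result.table["padj"] < params["padj_max"]).sum())
        report["outputs"]["de"] = {
            "n_significant": n_sig,
            "padj_max": params["padj_max"],
            "n_not_converged": result.n_not_converged,
        }
        return

    if stage == "markers":
        counts = cohort.counts.with_size_factors()
        pca = pca_top_variable(
            state["transformed"], n_top=min(params["pca_n_top"], counts.n_genes)
        )
        cands = candidate_markers(
            pca, state["de"], n_top=params["n_top"],
            lfc_min=params["lfc_min"], padj_max=params["padj_max"],
        )
        report_entry = {"n_candidates": len(cands)}
        if len(cands) > 0:
            minimal = minimize_markers(
                cands, counts, state["partition"], method=params["search"]
            )
            state["markers"] = minimal
            report_entry.update(
                marker_panel=minimal.gene_ids,
                panel_size=minimal.size,
                recapitulation=minimal.recapitulation,
                pca_silhouette=minimal.pca_silhouette,
            )
            pd.Series(minimal.gene_ids).to_csv(
                outdir / "marker_panel.csv", index=False, header=["gene"]
            )
        report["outputs"]["markers"] = report_entry
        return

    if stage == "survival":
        records = cohort.survival.copy()
        named = state["partition_named"]
        records["group"] = records["sample"].map(named)
        group1 = "C1" if "C1" in set(records["group"]) else sorted(set(records["group"]))[0]
        chi2, p = logrank_test(records, group1=group1)
        hr = mh_hazard_ratio(records, group1=group1)
        report["outputs"]["survival"] = {
            "group1": group1,
            "hr": hr.hr, "ci_low": hr.ci_low, "ci_high": hr.ci_high,
            "logrank_chi2": chi2, "logrank_p": p,
            "true_hr": cohort.truth.true_hr,
            "ci_covers_true_hr": (
                None if cohort.truth.true_hr is None
                else bool(hr.ci_low <= cohort.truth.true_hr <= hr.ci_high)
            ),
        }
        return

    if stage == "methylation":
        filtered = filter_probes(cohort.beta, cohort.probe_annotation)
        groups = state["partition_named"]
        sel = supervised_probe_selection(
            filtered, groups,
            padj_max=params["padj_max"], delta_beta_min=params["delta_beta_min"],
        )
        out = {"n_filtered_probes": len(filtered.probe_ids),
               "n_selected_probes": len(sel.table)}
        sel.table.to_csv(outdir / "selected_probes.tsv", sep="\t", index_label="probe")
        if len(sel.table) >= 2:
            sup_part = methylation_clustering(
                filtered, mode="supervised", probe_ids=list(sel.table.index)
            )
            expr_vec = state["partition"].label_vector(filtered.sample_ids)
            out["ari_supervised_vs_expression"] = float(
                adjusted_rand_score(expr_vec, sup_part.label_vector(filtered.sample_ids))
            )
        try:
            unsup = methylation_clustering(
                filtered, mode="unsupervised", n_top=params["n_top_unsupervised"]
            )
            expr_vec = state["partition"].label_vector(filtered.sample_ids)
            out["ari_unsupervised_vs_expression"] = float(
                adjusted_rand_score(expr_vec, unsup.label_vector(filtered.sample_ids))
            )
        except ValueError as exc:
            out["unsupervised_error"] = str(exc)
        report["outputs"]["methylation"] = out
        return

    if stage == "cnv":
        profile = aggregate_profile(
            cohort.segments, cohort.config.genome,
            bin_size=params["bin_size"], scale=params["scale"],
        )
        profile.bins.to_csv(outdir / "aggregate_cn.tsv", sep="\t", index=False)
        calls = []
        for prof in cohort.segments:
            calls.extend(call_cnv_drivers(prof, cohort.config.gene_table))
        called = {(c.sample, c.gene, c.type) for c in calls}
        truth_set = set(cohort.truth.driver_events)
        tp = len(called & truth_set)
        report["outputs"]["cnv"] = {
            "n_driver_calls": len(called),
            "precision_vs_truth": (tp / len(called)) if called else None,
            "recall_vs_truth": (tp / len(truth_set)) if truth_set else None,
        }
        pd.DataFrame([c.__dict__ for c in calls]).to_csv(
            outdir / "driver_calls.tsv", sep="\t", index=False
        )
        return

    if stage == "signatures":
        res = extract_signatures(
            cohort.catalogue, k=params["k"], n_restarts=params["n_restarts"],
            seed=stage_seed(config.seed, "signatures"),
        )
        res.signatures.to_csv(outdir / "signatures.tsv", sep="\t")
        res.exposures.to_csv(outdir / "exposures.tsv", sep="\t")
        out = {"k": params["k"],
               "stability": [round(float(s), 4) for s in res.stability],
               "reconstruction_kl": res.reconstruction_kl}
        cfg = cohort.config
        from .synthetic_cohort import make_default_signatures
        true_profiles = (
            np.asarray(cfg.signature_profiles, float)
            if cfg.signature_profiles is not None else make_default_signatures(2)
        )
        if true_profiles.shape[0] == params["k"]:
            _, cos = match_signatures(true_profiles, res.signatures.to_numpy())
            out["cosine_to_truth"] = [round(float(c), 4) for c in cos]
        report["outputs"]["signatures"] = out
        return

    if stage == "enrich":
        de = state["de"]
        stats_series = de.table["stat"].dropna()
        collection = _synthetic_gene_sets(
            list(stats_series.index), cohort.truth.marker_ids,
            n_sets=params["n_sets"], n_hallmarks=params["n_hallmarks"],
            seed=stage_seed(config.seed, "enrich"),
        )
        res = functional_class_scoring(
            stats_series, collection, n_perm=params["n_perm"],
            seed=stage_seed(config.seed, "enrich_perm"),
        )
        res.sets.to_csv(outdir / "enrichment.tsv", sep="\t")
        top_set = res.sets["pvalue"].idxmin()
        report["outputs"]["enrich"] = {
            "n_sets_tested": len(res.sets),
            "top_set": str(top_set),
            "top_set_p": float(res.sets.loc[top_set, "pvalue"]),
            "n_skipped": len(res.skipped),
        }
        return

    raise ValueError(f"unknown stage {stage!r}")
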