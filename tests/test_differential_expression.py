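"""NB Wald DE, unwanted-variation factors and BH adjustment."""

import numpy as np
import pandas as pd
import pytest

from meningiomics.differential_expression import (
    DesignInfo,
    EstimationError,
    bh_adjust,
    estimate_control_gene_factor,
    estimate_hidden_factors,
    nb_wald_de,
)
from meningiomics.expression_subtyping import CountMatrix
from meningiomics.synthetic_cohort import CohortConfig, simulate_expression


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Definitional BH: padj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * p[i] / rank))
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert np.allclose(bh_adjust([0.2]), [0.2])

    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_permutation_equivariance(self):
        p = np.array([0.3, 0.01, 0.8, 0.05, 0.05])
        perm = [2, 0, 4, 1, 3]
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_definitional_formula_on_grid_vectors(self):
        rng = np.random.default_rng(17)
        grid = np.round(np.arange(0, 1.01, 0.01), 2)
        for _ in range(300):
            n = rng.integers(1, 7)
            p = rng.choice(grid, size=n)
            assert np.allclose(bh_adjust(p), brute_force_bh(p)), p

    def test_nan_passthrough_and_reduced_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # m=2 for the tested values
        assert np.allclose(out[[0, 2]], brute_force_bh(np.array([0.01, 0.04])))


class TestControlGeneFactor:
    def test_unit_variance_contract(self, default_cohort):
        _, counts, truth = default_cohort
        f = estimate_control_gene_factor(counts, truth.control_gene_ids)
        assert np.isclose(f["W1"].std(ddof=0), 1.0)

    def test_recovers_batch_when_controls_carry_it(self):
        cfg = CohortConfig(seed=21, batch_lfc=2.0, batch_affects_controls=True)
        counts, truth = simulate_expression(cfg)
        f = estimate_control_gene_factor(counts, truth.control_gene_ids)
        batch = pd.Series(truth.batch_factor)[counts.sample_ids].to_numpy(float)
        assert abs(np.corrcoef(f["W1"], batch)[0, 1]) > 0.9

    def test_null_batch_gives_weak_correlation(self):
        cors = []
        for seed in range(5):
            cfg = CohortConfig(seed=seed, batch_lfc=0.0)
            counts, truth = simulate_expression(cfg)
            f = estimate_control_gene_factor(counts, truth.control_gene_ids)
            batch = pd.Series(truth.batch_factor)[counts.sample_ids].to_numpy(float)
            if batch.std() > 0:
                cors.append(abs(np.corrcoef(f["W1"], batch)[0, 1]))
        assert np.mean(cors) < 0.5  # indistinguishable from random labels

    def test_all_zero_controls_error(self):
        cm = CountMatrix(
            np.vstack([np.zeros((3, 4), int), np.ones((2, 4), int) * 5]),
            ["c1", "c2", "c3", "g1", "g2"],
            list("abcd"),
        )
        with pytest.raises(EstimationError):
            estimate_control_gene_factor(cm, ["c1", "c2", "c3"])


class TestHiddenFactors:
    def test_orthogonal_to_known_factors(self, default_cohort):
        _, counts, truth = default_cohort
        ctrl = estimate_control_gene_factor(counts, truth.control_gene_ids)
        hidden = estimate_hidden_factors(counts, ctrl, n=3)
        dots = hidden.to_numpy().T @ ctrl.to_numpy()
        assert np.max(np.abs(dots)) <= 1e-8

    def test_recovers_planted_structured_axis(self):
        cfg = CohortConfig(seed=31, batch_lfc=2.0, batch_affects_controls=True)
        counts, truth = simulate_expression(cfg)
        # plant a second structured axis independent of batch
        rng = np.random.default_rng(99)
        axis = rng.normal(size=counts.n_samples)
        affected = rng.random(counts.n_genes) < 0.3
        mult = np.exp2(np.outer(affected * 1.5, axis))
        counts2 = CountMatrix(
            np.round(counts.values * mult).astype(int),
            counts.gene_ids, counts.sample_ids,
        )
        ctrl = estimate_control_gene_factor(counts2, truth.control_gene_ids)
        hidden = estimate_hidden_factors(counts2, ctrl, n=3)
        best = max(
            abs(np.corrcoef(hidden[c], axis)[0, 1]) for c in hidden.columns
        )
        assert best > 0.9

    def test_n_zero_gives_empty_frame(self, default_cohort):
        _, counts, _ = default_cohort
        hidden = estimate_hidden_factors(counts, None, n=0)
        assert hidden.shape == (counts.n_samples, 0)

    def test_too_many_factors_rejected(self, default_cohort):
        _, counts, _ = default_cohort
        with pytest.raises(EstimationError):
            estimate_hidden_factors(counts, None, n=counts.n_samples)


class TestNbWaldDe:
    def test_all_zero_gene_untested(self, default_cohort):
        _, counts, truth = default_cohort
        vals = counts.values.copy()
        vals[0] = 0
        cm = CountMatrix(vals, counts.gene_ids, counts.sample_ids)
        res = nb_wald_de(cm, DesignInfo(condition=truth.labels, reference="C2"))
        row = res.table.iloc[0]
        assert row["log2FoldChange"] == 0.0
        assert np.isnan(row["pvalue"]) and not row["tested"]

    def test_lfc_approaches_log_mean_ratio_at_low_dispersion(self):
        rng = np.random.default_rng(4)
        n = 60
        mu = np.exp(rng.uniform(np.log(50), np.log(500), size=200))
        ratio = np.exp2(rng.uniform(-2, 2, size=200))
        alpha = 1e-4
        r = 1 / alpha
        cond = np.repeat([0, 1], n // 2)
        m = mu[:, None] * np.where(cond[None, :] == 1, ratio[:, None], 1.0)
        y = rng.negative_binomial(r, r / (r + m))
        cm = CountMatrix(
            y, [f"g{i}" for i in range(200)], [f"s{j}" for j in range(n)],
            size_factors=np.ones(n),
        )
        labels = {f"s{j}": ("B" if cond[j] else "A") for j in range(n)}
        res = nb_wald_de(cm, DesignInfo(condition=labels, reference="A"))
        err = np.abs(res.table["log2FoldChange"].to_numpy() - np.log2(ratio))
        assert np.median(err) < 0.05

    def test_planted_markers_reach_stringent_thresholds(self, default_cohort):
        _, counts, truth = default_cohort
        res = nb_wald_de(counts, DesignInfo(condition=truth.labels, reference="C2"))
        markers = res.table.loc[truth.marker_ids]
        assert (markers["padj"] < 1e-4).all()
        assert (markers["log2FoldChange"].abs() > 4).all()
        others = res.table.drop(truth.marker_ids)
        fp = ((others["padj"] < 1e-4) & (others["log2FoldChange"].abs() > 4)).sum()
        assert fp <= 1

    def test_null_type_one_error_roughly_nominal(self):
        fracs = []
        for seed in range(3):
            cfg = CohortConfig(seed=seed, marker_lfc=0.0, n_markers=0)
            counts, truth = simulate_expression(cfg)
            res = nb_wald_de(counts, DesignInfo(condition=truth.labels, reference="C2"))
            p = res.table["pvalue"].dropna()
            fracs.append(float((p < 0.05).mean()))
        assert 0.03 < np.mean(fracs) < 0.07

    def test_covariates_remove_confounded_batch_calls(self):
        cfg = CohortConfig(
            seed=3, batch_lfc=2.0, batch_affects_controls=True, batch_confound=0.6
        )
        counts, truth = simulate_expression(cfg)
        base = DesignInfo(condition=truth.labels, reference="C2")
        r0 = nb_wald_de(counts, base)
        ctrl = estimate_control_gene_factor(counts, truth.control_gene_ids)
        cond = pd.DataFrame(
            {"cond": [1.0 if truth.labels[s] == "C1" else 0.0 for s in counts.sample_ids]},
            index=counts.sample_ids,
        )
        hidden = estimate_hidden_factors(counts, pd.concat([ctrl, cond], axis=1), n=2)
        r1 = nb_wald_de(
            counts,
            DesignInfo(
                condition=truth.labels, reference="C2",
                known_covariates=pd.concat([ctrl, hidden], axis=1),
            ),
        )
        n0 = (r0.table["padj"] < 0.01).sum()
        n1 = (r1.table["padj"] < 0.01).sum()
        assert n1 < n0
        assert (r1.table.loc[truth.marker_ids, "padj"] < 0.01).all()

    def test_design_validation(self, default_cohort):
        _, counts, truth = default_cohort
        one_level = {s: "C1" for s in counts.sample_ids}
        with pytest.raises(ValueError):
            nb_wald_de(counts, DesignInfo(condition=one_level, reference="C1"))
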