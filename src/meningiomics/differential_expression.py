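"""Negative-binomial Wald differential expression with batch correction.

The model mirrors the count-regression approach of DESeq-style tools: per
gene a negative-binomial log-linear regression of counts on condition plus
nuisance covariates, with size-factor offsets, method-of-moments dispersion
shrunk toward a mean-dispersion trend, and Wald tests on the condition
coefficient. Unwanted variation is captured by a control-gene factor (genes
assumed biologically constant, so their covariation is technical) and by
hidden factors — principal components of expression residuals orthogonal to
the known covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_subtyping import CountMatrix

_LN2 = np.log(2.0)


class EstimationError(ValueError):
    pass


@dataclass
class DesignInfo:
    """Design for a two-group comparison with nuisance covariates.

    ``condition`` maps sample id -> group label (exactly two levels, each
    with >= 2 samples); ``reference`` names the baseline level so positive
    log2 fold changes mean higher expression in the non-reference group.
    """

    condition: dict[str, str]
    reference: str
    known_covariates: pd.DataFrame | None = None
    control_genes: list[str] = field(default_factory=list)
    n_hidden: int = 0

    def validate(self, sample_ids: list[str]) -> None:
        missing = [s for s in sample_ids if s not in self.condition]
        if missing:
            raise ValueError(f"condition missing for samples: {missing[:5]}")
        levels = sorted(set(self.condition[s] for s in sample_ids))
        if len(levels) != 2:
            raise ValueError("condition must have exactly two levels")
        if self.reference not in levels:
            raise ValueError("reference is not a condition level")
        counts = {lv: sum(self.condition[s] == lv for s in sample_ids) for lv in levels}
        if min(counts.values()) < 2:
            raise ValueError("each condition level needs >= 2 samples")


@dataclass
class DEResult:
    """Per-gene Wald test results.

    ``table`` columns: baseMean, log2FoldChange, lfcSE, stat, pvalue, padj,
    dispersion, tested, converged. ``n_not_converged`` counts genes whose
    IRLS fit did not converge (their p-values are missing and excluded from
    the BH denominator).
    """

    table: pd.DataFrame
    design: DesignInfo
    n_not_converged: int = 0

    def significant(self, padj_max: float = 0.01, lfc_min: float = 0.0) -> pd.Index:
        t = self.table
        keep = (t["padj"] < padj_max) & (t["log2FoldChange"].abs() > lfc_min)
        return t.index[keep.fillna(False)]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs are passed through untested.

    The BH denominator m is the number of non-missing p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _log_norm(counts: CountMatrix) -> np.ndarray:
    counts = counts.with_size_factors()
    return np.log2(counts.values / counts.size_factors[None, :] + 1.0)


def _unit_scale(f: np.ndarray) -> np.ndarray:
    sd = f.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    f = f / sd[None, :]
    # deterministic sign: largest |entry| positive
    flip = np.sign(f[np.argmax(np.abs(f), axis=0), np.arange(f.shape[1])])
    flip[flip == 0] = 1.0
    return f * flip[None, :]


def estimate_control_gene_factor(
    counts: CountMatrix, control_genes: list[str], k: int = 1
) -> pd.DataFrame:
    """Unwanted-variation factor(s) from control genes (RUV-style).

    Control genes are assumed to have constant biological expression, so the
    leading singular structure of their centred log-normalised submatrix
    reflects technical variation shared across samples (e.g. laboratory
    batch). Returns per-sample scores scaled to unit variance.
    """
    present = [g for g in control_genes if g in counts.gene_ids]
    if len(present) < k + 1:
        raise EstimationError("need at least k+1 control genes present in the matrix")
    idx = pd.Index(counts.gene_ids).get_indexer(present)
    sub = _log_norm(counts)[idx]
    if np.allclose(sub, 0.0) or np.allclose(sub.var(axis=1).sum(), 0.0):
        raise EstimationError("control genes carry no signal (all zero/constant)")
    centered = sub - sub.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    scores = _unit_scale(vt[:k].T)
    cols = [f"W{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=counts.sample_ids, columns=cols)


def estimate_hidden_factors(
    counts: CountMatrix, known_factors: pd.DataFrame | None, n: int = 13
) -> pd.DataFrame:
    """Hidden expression factors orthogonal to the known covariates.

    Principal components of log-normalised expression after projecting out
    the intercept and ``known_factors`` from every gene, in sample space.
    By construction the returned scores have zero dot product with each
    known factor column.
    """
    y = _log_norm(counts)  # genes x samples
    n_samp = counts.n_samples
    d = np.ones((n_samp, 1))
    if known_factors is not None and known_factors.shape[1] > 0:
        kf = known_factors.loc[counts.sample_ids].to_numpy(dtype=float)
        d = np.hstack([d, kf])
    rank = np.linalg.matrix_rank(d)
    if n > n_samp - rank - 1:
        raise EstimationError(
            f"n={n} hidden factors exceed residual degrees of freedom "
            f"({n_samp - rank - 1})"
        )
    cols = [f"H{i + 1}" for i in range(n)]
    if n == 0:
        return pd.DataFrame(index=counts.sample_ids, columns=cols, dtype=float)
    proj = d @ np.linalg.pinv(d.T @ d) @ d.T
    resid = y - y @ proj
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    scores = _unit_scale(vt[:n].T)
    # re-orthogonalise against the known design to kill numerical leakage
    scores = scores - proj @ scores
    scores = _unit_scale(scores)
    return pd.DataFrame(scores, index=counts.sample_ids, columns=cols)


def _dispersion_estimates(
    norm: np.ndarray, tested: np.ndarray, shrink_weight: float = 0.5
) -> np.ndarray:
    """Method-of-moments dispersions shrunk toward an a/mu + b trend."""
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (var - mu) / mu**2, np.nan)
    raw = np.clip(raw, 1e-8, 10.0)
    fit_mask = tested & np.isfinite(raw) & (raw > 1e-6) & (mu > 0)
    alpha_trend = np.full_like(mu, 0.1)
    if fit_mask.sum() >= 10:
        a_mat = np.column_stack([1.0 / mu[fit_mask], np.ones(fit_mask.sum())])
        coef, *_ = np.linalg.lstsq(a_mat, raw[fit_mask], rcond=None)
        a, b = np.maximum(coef, 0.0)
        if a + b > 0:
            with np.errstate(divide="ignore"):
                alpha_trend = np.where(mu > 0, a / np.maximum(mu, 1e-8) + b, b)
            alpha_trend = np.clip(alpha_trend, 1e-8, 10.0)
    log_shrunk = (1 - shrink_weight) * np.log(raw) + shrink_weight * np.log(
        np.maximum(alpha_trend, 1e-8)
    )
    alpha = np.exp(log_shrunk)
    alpha[~np.isfinite(alpha)] = 0.1
    return np.clip(alpha, 1e-8, 10.0)


def _irls_nb(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 1e-6,
):
    """Vectorised IRLS for per-gene NB log-link regression.

    ``y`` is genes x samples, ``x`` the shared samples x p design, ``alpha``
    per-gene dispersions. Returns (beta, cov, converged).
    """
    n_genes, n_samp = y.shape
    p = x.shape[1]
    z0 = np.log((y + 0.5) / np.exp(offset)[None, :])
    beta, *_ = np.linalg.lstsq(x, z0.T, rcond=None)
    beta = beta.T  # genes x p
    converged = np.zeros(n_genes, dtype=bool)
    active = np.ones(n_genes, dtype=bool)
    ridge_mat = ridge * np.eye(p)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = beta[idx] @ x.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[idx, None] * mu)
        z = (eta - offset[None, :]) + (y[idx] - mu) / mu
        xtwx = np.einsum("ni,gn,nj->gij", x, w, x) + ridge_mat[None, :, :]
        xtwz = np.einsum("ni,gn,gn->gi", x, w, z)
        new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.max(np.abs(new - beta[idx]), axis=1)
        beta[idx] = new
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # covariance at the final fit
    eta = np.clip(beta @ x.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("ni,gn,nj->gij", x, w, x) + ridge * np.eye(p)[None, :, :]
    cov = np.linalg.inv(xtwx)
    return beta, cov, converged


def nb_wald_de(
    counts: CountMatrix,
    design: DesignInfo,
    min_base_mean: float = 1.0,
    max_iter: int = 50,
) -> DEResult:
    """Per-gene negative-binomial Wald test of the condition effect.

    Genes with normalised base mean below ``min_base_mean`` are excluded
    from testing (reported untested); non-convergent fits get missing
    p-values and do not enter the BH denominator.
    """
    counts = counts.with_size_factors()
    design.validate(counts.sample_ids)
    cond = np.array(
        [1.0 if design.condition[s] != design.reference else 0.0 for s in counts.sample_ids]
    )
    cols = [np.ones(counts.n_samples), cond]
    if design.known_covariates is not None and design.known_covariates.shape[1] > 0:
        kf = design.known_covariates.loc[counts.sample_ids].to_numpy(dtype=float)
        cols.extend(kf.T)
    x = np.column_stack(cols)
    offset = np.log(counts.size_factors)
    yv = counts.values.astype(float)
    norm = yv / counts.size_factors[None, :]
    base_mean = norm.mean(axis=1)
    tested = base_mean >= min_base_mean
    alpha = _dispersion_estimates(norm, tested)

    n_genes = counts.n_genes
    log2fc = np.zeros(n_genes)
    lfc_se = np.full(n_genes, np.nan)
    stat = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    conv_flag = np.zeros(n_genes, dtype=bool)

    if tested.any():
        beta, cov, conv = _irls_nb(
            yv[tested], x, offset, alpha[tested], max_iter=max_iter
        )
        se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
        z = np.where(se > 0, beta[:, 1] / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        log2fc[tested] = beta[:, 1] / _LN2
        lfc_se[tested] = se / _LN2
        stat[tested] = z
        pval[tested] = np.where(conv, p, np.nan)
        conv_flag[tested] = conv

    padj = bh_adjust(pval)
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": lfc_se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "dispersion": alpha,
            "tested": tested,
            "converged": conv_flag,
        },
        index=counts.gene_ids,
    )
    n_nc = int((tested & ~conv_flag).sum())
    return DEResult(table=table, design=design, n_not_converged=n_nc)
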