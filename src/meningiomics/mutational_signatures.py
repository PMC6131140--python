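"""Mutational-signature extraction from 96-channel catalogues.

Non-negative matrix factorisation (multiplicative updates minimising the
generalised Kullback-Leibler divergence) with multiple random restarts;
signature stability is the mean cosine similarity of Hungarian-matched
signatures across restarts. Exposures to a fixed reference set are fitted
per sample by non-negative least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = ["A", "C", "G", "T"]

#: Canonical 96-channel order: substitution class major, 5' then 3' context.
CHANNELS_96 = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
]


@dataclass
class Catalogue96:
    """Samples x 96 trinucleotide mutation counts in canonical order."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != CHANNELS_96:
            raise ValueError("catalogue columns must be the canonical 96 channels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative mutation counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class SignatureSet:
    """Extracted signatures, per-restart stability, and exposures."""

    signatures: pd.DataFrame  # k x 96, rows sum to 1
    exposures: pd.DataFrame  # samples x k, non-negative
    stability: np.ndarray  # per-signature mean matched cosine across restarts
    reconstruction_kl: float

    def __post_init__(self) -> None:
        sums = self.signatures.to_numpy().sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("signatures must sum to 1")
        if (self.exposures.to_numpy() < -1e-12).any():
            raise ValueError("negative exposures")


def generalized_kl(x: np.ndarray, y: np.ndarray) -> float:
    """D(x || y) = sum x log(x/y) - x + y with the 0 log 0 convention."""
    x = np.asarray(x, float)
    y = np.maximum(np.asarray(y, float), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(x / y), 0.0)
    return float(np.sum(term - x + y))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_signatures(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of signature rows by cosine similarity.

    Returns (permutation of b's rows matched to a, matched cosines).
    """
    k = a.shape[0]
    sim = np.array([[cosine_similarity(a[i], b[j]) for j in range(k)] for i in range(k)])
    rows, cols = linear_sum_assignment(-sim)
    return cols[np.argsort(rows)], sim[rows, cols][np.argsort(rows)]


def _fit_once(x: np.ndarray, k: int, seed: int):
    model = NMF(
        n_components=k,
        solver="mu",
        beta_loss="kullback-leibler",
        init="random",
        random_state=seed,
        max_iter=2000,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        w = model.fit_transform(x)  # samples x k
    h = model.components_  # k x 96
    return w, h, generalized_kl(x, w @ h)


def extract_signatures(
    catalogue: Catalogue96, k: int, n_restarts: int = 50, seed: int = 0
) -> SignatureSet:
    """Multi-restart KL-NMF signature extraction.

    The best restart (lowest generalised KL) provides the signatures;
    stability per signature is the mean cosine similarity with its
    Hungarian-matched counterpart over all other restarts. Signatures are
    L1-normalised with the scale moved into the exposures, so exposures are
    expected mutation counts per signature.
    """
    x = catalogue.counts.to_numpy(float)
    if k > min(x.shape[0], 96):
        raise ValueError("k exceeds the number of samples or channels")
    if x.sum() <= 0:
        raise ValueError("empty catalogue")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    fits = [_fit_once(x, k, int(s)) for s in seeds]
    best_idx = int(np.argmin([f[2] for f in fits]))
    w_best, h_best, kl_best = fits[best_idx]

    scale = h_best.sum(axis=1)
    scale[scale == 0] = 1.0
    sig = h_best / scale[:, None]
    expo = w_best * scale[None, :]

    matched = []
    for i, (w, h, _) in enumerate(fits):
        if i == best_idx:
            continue
        hs = h / np.maximum(h.sum(axis=1, keepdims=True), 1e-12)
        _, cos = match_signatures(sig, hs)
        matched.append(cos)
    stability = (
        np.mean(matched, axis=0) if matched else np.ones(k)
    )

    names = [f"S{i + 1}" for i in range(k)]
    return SignatureSet(
        signatures=pd.DataFrame(sig, index=names, columns=CHANNELS_96),
        exposures=pd.DataFrame(expo, index=catalogue.sample_ids, columns=names),
        stability=np.asarray(stability, float),
        reconstruction_kl=kl_best,
    )


def attribute_exposures(
    catalogue: Catalogue96, reference_signatures: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample non-negative least-squares fit onto fixed signatures."""
    sig = reference_signatures.to_numpy(float)
    if not np.allclose(sig.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("reference signatures must sum to 1")
    a = sig.T  # 96 x k
    out = np.vstack(
        [nnls(a, row)[0] for row in catalogue.counts.to_numpy(float)]
    )
    return pd.DataFrame(
        out, index=catalogue.sample_ids, columns=list(reference_signatures.index)
    )


def select_k(
    catalogue: Catalogue96,
    k_range=range(1, 5),
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Stability/fit trade-off for the number of signatures.

    For each k the score is mean stability minus the reconstruction KL
    relative to the k=1 fit; the k with the highest score wins (ties to the
    smaller k).
    """
    rows = []
    kl1 = None
    for k in k_range:
        res = extract_signatures(catalogue, k, n_restarts=n_restarts, seed=seed + k)
        if kl1 is None:
            kl1 = max(res.reconstruction_kl, 1e-12)
        rows.append(
            {
                "k": k,
                "stability": float(np.mean(res.stability)),
                "kl": res.reconstruction_kl,
                "score": float(np.mean(res.stability)) - res.reconstruction_kl / kl1,
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    best = int(table["score"].idxmax())
    return best, table
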