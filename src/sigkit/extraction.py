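"""De novo signature extraction by replicated KL-NMF.

The catalog is first column-capped so hypermutators cannot dominate the
objective, then factorized repeatedly (optionally on Poisson bootstrap
resamples) at each candidate rank with multiplicative updates minimizing
the generalized Kullback-Leibler divergence.  Pooled replicate signatures
are clustered by replicate-matched consensus clustering under cosine
distance; cluster tightness (mean silhouette) scores the stability of
each rank, and consensus activities are refit by nonnegative least
squares against the raw catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.metrics import silhouette_score

from .contexts import CatalogMatrix

logger = logging.getLogger(__name__)

_EPS = np.finfo(np.float64).eps


@dataclass
class ExtractionConfig:
    """Knobs of the replicated extraction.

    ``normalization_cap`` is the per-sample mutation total above which a
    column is rescaled (10,000 by default, limiting hypermutator
    leverage).  ``resample`` toggles Poisson bootstrap of the catalog per
    replicate.
    """

    k_min: int = 2
    k_max: int = 8
    replicates_per_k: int = 20
    normalization_cap: float = 10_000.0
    max_iterations: int = 10_000
    relative_tolerance: float = 1e-9
    seed: int = 0
    resample: bool = True
    stability_floor: float = 0.8
    error_slack: float = 0.05

    def __post_init__(self):
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")
        if self.normalization_cap <= 0:
            raise ValueError("normalization_cap must be positive")


@dataclass
class DeNovoSolution:
    """Consensus factorization over the selected rank."""

    signatures: pd.DataFrame  # categories x k, columns sum to 1
    activities: pd.DataFrame  # k x samples, nonnegative counts
    selected_k: int
    per_k_stability: dict[int, float]
    per_k_error: dict[int, float]
    reconstruction_cosine: pd.Series  # per sample
    per_k_solutions: dict[int, tuple[pd.DataFrame, pd.DataFrame]] = field(repr=False, default_factory=dict)


def normalize_catalog(catalog: CatalogMatrix, cap: float) -> CatalogMatrix:
    """Rescale columns whose total exceeds ``cap`` down to exactly ``cap``."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    totals = catalog.counts.sum(axis=0)
    scale = np.minimum(1.0, cap / totals.replace(0, np.nan)).fillna(1.0)
    counts = catalog.counts.astype(float).mul(scale, axis=1)
    return CatalogMatrix(catalog.schema, counts, dict(catalog.unclassified))


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    Vp = np.maximum(V, _EPS)
    return float(np.sum(np.where(V > 0, V * np.log(Vp / WH) - V, 0.0) + WH))


def nmf_factorize(
    catalog: CatalogMatrix | np.ndarray,
    k: int,
    seed: int,
    config: ExtractionConfig | None = None,
    track_divergence: bool = False,
):
    """One KL-NMF run with multiplicative updates.

    Returns column-normalized signatures (categories x k), compensatingly
    rescaled activities (k x samples), and the final divergence (plus the
    per-iteration divergence sequence when ``track_divergence``).
    """
    config = config or ExtractionConfig()
    V = catalog.counts.to_numpy(dtype=float) if isinstance(catalog, CatalogMatrix) else np.asarray(catalog, dtype=float)
    if V.sum() <= 0:
        raise ValueError("all-zero catalog cannot be factorized")
    if k < 1:
        raise ValueError("k must be >= 1")
    m, n = V.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(m, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n)) * scale

    history = []
    prev = np.inf
    ones = np.ones_like(V)
    for _ in range(config.max_iterations):
        WH = np.maximum(W @ H, _EPS)
        W *= (V / WH) @ H.T / np.maximum(ones @ H.T, _EPS)
        W = np.maximum(W, _EPS)
        WH = np.maximum(W @ H, _EPS)
        H *= W.T @ (V / WH) / np.maximum(W.T @ ones, _EPS)
        H = np.maximum(H, _EPS)
        d = _kl_divergence(V, W @ H)
        if track_divergence:
            history.append(d)
        if np.isfinite(prev) and prev - d < config.relative_tolerance * max(prev, _EPS):
            break
        prev = d

    col = W.sum(axis=0)
    W = W / col
    H = H * col[:, None]
    d = _kl_divergence(V, W @ H)
    if track_divergence:
        return W, H, d, history
    return W, H, d


# ---------------------------------------------------------------------------
# consensus clustering


def _cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / np.maximum(norms, _EPS)
    D = 1.0 - Xn @ Xn.T
    np.clip(D, 0.0, 2.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


def _matched_cluster_labels(Ws: list[np.ndarray], k: int, max_iter: int = 50) -> np.ndarray:
    """Replicate-matched consensus clustering of pooled signatures.

    Each replicate contributes exactly one signature per cluster: replicate
    columns are Hungarian-matched (cosine distance) to the running
    consensus centroids, which are then re-averaged until stable.  The
    constraint stops a too-large rank from looking stable by splitting one
    tight cluster into two — the spurious extra signature must then form
    its own, visibly diffuse, cluster.
    """
    from scipy.optimize import linear_sum_assignment

    mats = []
    for W in Ws:
        Wn = W / np.maximum(np.linalg.norm(W, axis=0), _EPS)
        mats.append(Wn)
    centroids = mats[0].copy()
    assignments = [np.arange(k) for _ in mats]
    for _ in range(max_iter):
        cn = centroids / np.maximum(np.linalg.norm(centroids, axis=0), _EPS)
        new_assignments = []
        for Wn in mats:
            cost = 1.0 - Wn.T @ cn  # replicate-signature x cluster
            rows, cols = linear_sum_assignment(cost)
            perm = np.empty(k, dtype=int)
            perm[rows] = cols
            new_assignments.append(perm)
        acc = np.zeros_like(centroids)
        for Wn, perm in zip(mats, new_assignments):
            for j in range(k):
                acc[:, perm[j]] += Wn[:, j]
        centroids = acc / len(mats)
        if all(np.array_equal(a, b) for a, b in zip(assignments, new_assignments)):
            break
        assignments = new_assignments
    return np.concatenate(assignments)


def _nnls_activities(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    H = np.zeros((W.shape[1], V.shape[1]))
    for j in range(V.shape[1]):
        H[:, j], _ = nnls(W, V[:, j])
    return H


def _cosine_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    num = (A * B).sum(axis=0)
    den = np.linalg.norm(A, axis=0) * np.linalg.norm(B, axis=0)
    return num / np.maximum(den, _EPS)


def extract_denovo(catalog: CatalogMatrix, config: ExtractionConfig) -> DeNovoSolution:
    """Replicated extraction with consensus clustering and rank selection."""
    if config.replicates_per_k < 2 and config.resample:
        raise ValueError("resampled extraction needs replicates_per_k >= 2")
    if config.k_max >= catalog.n_samples:
        raise ValueError("k_max must be below the number of samples")

    norm = normalize_catalog(catalog, config.normalization_cap)
    Vn = norm.counts.to_numpy(dtype=float)
    Vraw = catalog.counts.to_numpy(dtype=float)

    per_k_stability: dict[int, float] = {}
    per_k_error: dict[int, float] = {}
    per_k_solutions: dict[int, tuple[pd.DataFrame, pd.DataFrame]] = {}

    for k in range(config.k_min, config.k_max + 1):
        pooled = []
        errors = []
        for rep in range(config.replicates_per_k):
            rep_seed = config.seed + rep
            if config.resample:
                rng = np.random.default_rng([config.seed, k, rep])
                Vrep = rng.poisson(Vn).astype(float)
                if Vrep.sum() == 0:
                    Vrep = Vn
            else:
                Vrep = Vn
            W, H, d = nmf_factorize(Vrep, k, rep_seed, config)
            pooled.append(W)
            errors.append(d)
        X = np.hstack(pooled).T  # (k * reps) x categories
        if k == 1 or len(pooled) == 1:
            # one cluster, or one point per cluster: silhouette undefined
            labels = np.tile(np.arange(k), len(pooled))
            stability = 1.0
        else:
            labels = _matched_cluster_labels(pooled, k)
            D = _cosine_distance_matrix(X)
            if len(np.unique(labels)) < 2:
                stability = 0.0
            else:
                stability = float(silhouette_score(D, labels, metric="precomputed"))
        centroids = np.vstack([
            X[labels == j].mean(axis=0) if np.any(labels == j) else np.zeros(X.shape[1])
            for j in range(k)
        ]).T
        centroids = np.maximum(centroids, 0.0)
        centroids /= np.maximum(centroids.sum(axis=0), _EPS)
        per_k_stability[k] = stability
        per_k_error[k] = float(np.mean(errors))

        Hc = _nnls_activities(Vraw, centroids)
        sig_names = [f"Sig{k}_{j + 1}" for j in range(k)]
        per_k_solutions[k] = (
            pd.DataFrame(centroids, index=catalog.counts.index, columns=sig_names),
            pd.DataFrame(Hc, index=sig_names, columns=catalog.sample_ids),
        )

    selected = select_rank(
        per_k_stability,
        per_k_error,
        stability_floor=config.stability_floor,
        error_slack=config.error_slack,
    )
    W_sel, H_sel = per_k_solutions[selected]
    recon = W_sel.to_numpy() @ H_sel.to_numpy()
    cosines = pd.Series(
        _cosine_cols(Vraw, recon), index=catalog.sample_ids, name="reconstruction_cosine"
    )
    return DeNovoSolution(
        signatures=W_sel,
        activities=H_sel,
        selected_k=selected,
        per_k_stability=per_k_stability,
        per_k_error=per_k_error,
        reconstruction_cosine=cosines,
        per_k_solutions=per_k_solutions,
    )


def select_rank(
    per_k_stability: dict[int, float],
    per_k_error: dict[int, float],
    stability_floor: float = 0.8,
    error_slack: float = 0.05,
) -> int:
    """Largest stable rank whose error is near-optimal among stable ranks.

    A rank qualifies when its mean silhouette is at least
    ``stability_floor``; among qualifying ranks the largest one with error
    within ``error_slack`` (relative) of the best qualifying error wins.
    If nothing qualifies the most stable rank is returned with a warning.
    """
    if set(per_k_stability) != set(per_k_error):
        raise ValueError("stability and error maps must share the same ranks")
    qualifying = [k for k, s in per_k_stability.items() if s >= stability_floor]
    if not qualifying:
        best = max(per_k_stability, key=lambda k: (per_k_stability[k], -k))
        logger.warning(
            "no rank reached stability %.2f; falling back to most stable k=%d",
            stability_floor,
            best,
        )
        return best
    best_err = min(per_k_error[k] for k in qualifying)
    ok = [k for k in qualifying if per_k_error[k] <= best_err * (1.0 + error_slack)]
    return max(ok)
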