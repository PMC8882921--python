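"""Polarity-invariant modified k-means over scalp topographies.

The modified k-means ignores map polarity: a map and its sign-flipped copy
belong to the same state because inverted scalp potentials reflect the same
synchronized neuronal configuration. Assignment therefore maximizes the
*squared* spatial correlation R^2, and the centroid update replaces the mean
with the dominant eigenvector of the scatter matrix of the assigned
(centered, unit-norm) maps — the direction maximizing sum of squared
projections regardless of sign.

Also here: cluster-number selection over a K range (Pascual-Marqui
cross-validation criterion or a GEV-gain elbow) and optimal one-to-one
template matching between two sets (exhaustive over permutations, sign
aligned).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import TopographyMap, stack_maps
from .exceptions import (
    ConfigError,
    DegenerateClusteringError,
    InvalidInputError,
)

__all__ = [
    "ClusteringParams",
    "MicrostateSet",
    "TemplateMatch",
    "modified_kmeans",
    "select_cluster_number",
    "match_templates",
]


@dataclass
class ClusteringParams:
    """Knobs of the modified k-means and of cluster-number selection.

    max_iterations bounds the iterations of each first-step restart;
    final_max_iterations is the analogous bound used by the strategies for
    their last clustering step. restarts counts independent random
    initializations per fit (best total explained variance kept). With
    k_fixed set (default 4, the canonical microstate count) only that K is
    fitted; unset it to scan k_range and select by `criterion` ("cv" for the
    cross-validation criterion, "gev_gain" for the elbow rule with
    `gev_gain_threshold`).
    """

    k_range: tuple[int, int] = (2, 8)
    max_iterations: int = 1000
    final_max_iterations: int = 5000
    restarts: int = 20
    tol: float = 1e-6
    seed: int = 0
    k_fixed: int | None = 4
    criterion: str = "cv"
    gev_gain_threshold: float = 0.02
    centroid: str = "eigen"  # "eigen" or "mean" (sign-aligned mean)

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ConfigError("restarts must be >= 1")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ConfigError("k_range must be an increasing range with lower bound >= 2")
        if self.centroid not in ("eigen", "mean"):
            raise ConfigError("centroid must be 'eigen' or 'mean'")


@dataclass
class MicrostateSet:
    """K template topographies plus provenance of how they were obtained.

    Templates are stored as a (K, N) matrix, each row mean-centered and
    unit-L2-norm. `explained` is the mean R^2 of the candidate maps used to
    fit (their GEV when the maps are unit-GFP). `criterion_value` holds the
    selection-criterion score when K was selected rather than fixed.
    """

    templates: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    criterion_value: float | None = None
    explained: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.templates.shape[1])]

    @property
    def K(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]

    def as_maps(self) -> list[TopographyMap]:
        return [TopographyMap(t, channel_names=list(self.channel_names)) for t in self.templates]


def _prepare_maps(maps: Sequence[TopographyMap] | np.ndarray) -> np.ndarray:
    """Center and unit-L2-normalize maps; drop zero-variance rows."""
    X = stack_maps(maps).astype(float)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    keep = norms > 0
    return X[keep] / norms[keep, None]


def _channel_names(maps: Sequence[TopographyMap] | np.ndarray) -> list[str]:
    if not isinstance(maps, np.ndarray) and len(maps) and isinstance(maps[0], TopographyMap):
        return list(maps[0].channel_names)
    return []


def _dominant_eigvec(X: np.ndarray, ref: np.ndarray | None = None) -> np.ndarray:
    """Unit dominant eigenvector of X^T X, sign-aligned to `ref`.

    Uses the Gram matrix X X^T when it is the smaller of the two.
    """
    n, d = X.shape
    if n == 1:
        v = X[0].copy()
    elif n < d:
        G = X @ X.T
        w, U = np.linalg.eigh(G)
        u = U[:, -1]
        v = X.T @ u
    else:
        S = X.T @ X
        w, U = np.linalg.eigh(S)
        v = U[:, -1]
    v = v / np.linalg.norm(v)
    if ref is not None and float(v @ ref) < 0:
        v = -v
    return v


def _sign_aligned_mean(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    signs = np.sign(X @ ref)
    signs[signs == 0] = 1.0
    v = (signs[:, None] * X).mean(axis=0)
    nrm = np.linalg.norm(v)
    return ref if nrm == 0 else v / nrm


def _objective(X: np.ndarray, T: np.ndarray) -> float:
    """Total R^2 of each map against its best-matching template."""
    return float(((X @ T.T) ** 2).max(axis=1).sum())


def _kmeans_once(
    X: np.ndarray, K: int, rng: np.random.Generator, params: ClusteringParams, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n = X.shape[0]
    T = X[rng.choice(n, size=K, replace=False)].copy()
    history: list[float] = []
    prev = -np.inf
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        C = X @ T.T
        labels = np.argmax(C**2, axis=1)  # ties -> lowest index (argmax rule)
        fit = C[np.arange(n), labels] ** 2
        # re-seed empty clusters from the worst-fit map of a multi-member
        # cluster (so re-seeding never empties another cluster)
        empty = [k for k in range(K) if not np.any(labels == k)]
        while empty:
            k = empty.pop()
            counts = np.bincount(labels, minlength=K)
            movable = counts[labels] > 1
            candidates = np.flatnonzero(movable)
            worst = int(candidates[np.argmin(fit[candidates])])
            labels[worst] = k
            fit[worst] = 1.0
        for k in range(K):
            Xk = X[labels == k]
            if params.centroid == "eigen":
                T[k] = _dominant_eigvec(Xk, ref=T[k])
            else:
                T[k] = _sign_aligned_mean(Xk, ref=T[k])
        obj = _objective(X, T)
        history.append(obj)
        if prev > -np.inf and obj - prev <= params.tol * max(abs(prev), 1.0):
            break
        prev = obj
    C = X @ T.T
    labels = np.argmax(C**2, axis=1)
    return T, labels, _objective(X, T), history


def modified_kmeans(
    maps: Sequence[TopographyMap] | np.ndarray,
    K: int,
    params: ClusteringParams | None = None,
    max_iterations: int | None = None,
    seed: int | None = None,
) -> MicrostateSet:
    """Fit K polarity-invariant microstate templates to candidate maps.

    Runs `params.restarts` random initializations (templates seeded from
    distinct randomly chosen maps) and keeps the run with the highest total
    explained variance. Deterministic given the seed.
    """
    params = params or ClusteringParams()
    names = _channel_names(maps)
    X = _prepare_maps(maps)
    n = X.shape[0]
    if n < K:
        raise InvalidInputError(f"need at least K={K} usable maps, got {n}")
    if K >= 2 and n >= 2 and np.all(np.abs(X @ X[0]) > 1.0 - 1e-12):
        raise DegenerateClusteringError(
            "all candidate maps identical up to sign; cannot fit K >= 2 clusters"
        )
    max_iter = max_iterations if max_iterations is not None else params.max_iterations
    rng = np.random.default_rng(params.seed if seed is None else seed)
    best: tuple[np.ndarray, np.ndarray, float, list[float]] | None = None
    for _ in range(params.restarts):
        result = _kmeans_once(X, K, rng, params, max_iter)
        if best is None or result[2] > best[2]:
            best = result
    T, labels, obj, history = best
    return MicrostateSet(
        templates=T,
        channel_names=names,
        explained=obj / n,
        provenance={
            "method": "modified_kmeans",
            "K": K,
            "n_maps": n,
            "restarts": params.restarts,
            "max_iterations": max_iter,
            "seed": params.seed if seed is None else seed,
            "objective_history": history,
        },
    )


def _cv_criterion(X: np.ndarray, ms: MicrostateSet) -> float:
    """Pascual-Marqui cross-validation criterion (lower is better).

    sigma^2 = sum_i (x_i.x_i - (x_i . t_label)^2) / (n (N-1));
    CV = sigma^2 * ((N-1)/(N-1-K))^2.
    """
    n, N = X.shape
    K = ms.K
    if K >= N - 1:
        return np.inf
    C = X @ ms.templates.T
    resid = float((1.0 - (C**2).max(axis=1)).sum())  # unit-norm maps: x.x = 1
    sigma2 = resid / (n * (N - 1))
    return sigma2 * ((N - 1) / (N - 1 - K)) ** 2


def select_cluster_number(
    maps: Sequence[TopographyMap] | np.ndarray,
    params: ClusteringParams | None = None,
    max_iterations: int | None = None,
    seed: int | None = None,
) -> MicrostateSet:
    """Fit with a fixed K, or scan k_range and select by the criterion.

    With `params.k_fixed` set (the default workflow) exactly one fit is
    performed. Otherwise every K in k_range is fitted and the configured
    criterion selects the winner ("cv": minimize the cross-validation
    criterion; "gev_gain": smallest K whose explained-variance gain over K-1
    falls below the threshold). Per-K diagnostics are attached to provenance.
    """
    params = params or ClusteringParams()
    n = stack_maps(maps).shape[0]
    if params.k_fixed is not None:
        ms = modified_kmeans(maps, params.k_fixed, params, max_iterations, seed)
        ms.criterion_value = _cv_criterion(_prepare_maps(maps), ms)
        return ms
    lo, hi = params.k_range
    if hi > n:
        warnings.warn(f"k_range upper bound {hi} exceeds map count {n}; truncating")
        hi = n
    if lo > hi:
        raise InvalidInputError("no feasible K in k_range for this map count")
    X = _prepare_maps(maps)
    fits: dict[int, MicrostateSet] = {}
    diags: dict[int, dict] = {}
    for K in range(lo, hi + 1):
        ms = modified_kmeans(maps, K, params, max_iterations, seed)
        ms.criterion_value = _cv_criterion(X, ms)
        fits[K] = ms
        diags[K] = {"cv": ms.criterion_value, "explained": ms.explained}
    if params.criterion == "cv":
        # smallest K within numerical tolerance of the minimum CV (ties at
        # ~0 arise on noiseless data, where any K >= K_true fits exactly)
        cv_min = min(ms.criterion_value for ms in fits.values())
        tol = 1e-9 * max(cv_min, 1e-12) + 1e-15
        chosen = min(K for K, ms in fits.items() if ms.criterion_value <= cv_min + tol)
    elif params.criterion == "gev_gain":
        chosen = hi
        for K in range(lo + 1, hi + 1):
            if fits[K].explained - fits[K - 1].explained < params.gev_gain_threshold:
                chosen = K - 1
                break
    else:
        raise ConfigError(f"unknown selection criterion {params.criterion!r}")
    ms = fits[chosen]
    ms.provenance["k_selection"] = {"criterion": params.criterion, "diagnostics": diags}
    return ms


@dataclass
class TemplateMatch:
    """Optimal one-to-one matching of two equally sized template sets.

    `permutation[j]` is the index in set `a` matched to reference template j.
    `aligned` is `a` re-ordered and sign-flipped so its row j matches
    reference row j with non-negative R.
    """

    permutation: tuple[int, ...]
    pair_r: np.ndarray  # |R| per matched pair, in reference order
    mean_r: float
    aligned: MicrostateSet


def match_templates(a: MicrostateSet, b: MicrostateSet) -> TemplateMatch:
    """Match templates of `a` to reference `b`, maximizing total |R|.

    Exhaustive over permutations (K <= 8 in practice). Sign of each matched
    template of `a` is chosen so the matched R is >= 0.
    """
    if a.K != b.K:
        raise InvalidInputError(f"template counts differ: {a.K} vs {b.K}")
    if a.n_channels != b.n_channels:
        raise InvalidInputError("template sets are on different montages")
    A = _prepare_maps(a.templates)
    B = _prepare_maps(b.templates)
    R = A @ B.T  # Pearson correlations (rows centered, unit norm)
    K = a.K
    best_perm: tuple[int, ...] | None = None
    best_total = -np.inf
    for perm in itertools.permutations(range(K)):
        total = sum(abs(R[perm[j], j]) for j in range(K))
        if total > best_total:
            best_total = total
            best_perm = perm
    pair_r = np.array([abs(R[best_perm[j], j]) for j in range(K)])
    signs = np.array([1.0 if R[best_perm[j], j] >= 0 else -1.0 for j in range(K)])
    aligned = MicrostateSet(
        templates=signs[:, None] * A[list(best_perm)],
        channel_names=list(a.channel_names),
        explained=a.explained,
        provenance={**a.provenance, "aligned_to": b.provenance.get("method", "reference")},
    )
    return TemplateMatch(
        permutation=best_perm, pair_r=pair_r, mean_r=float(pair_r.mean()), aligned=aligned
    )
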