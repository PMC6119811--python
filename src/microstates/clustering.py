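"""Microstate map extraction and competitive back-fitting.

Five interchangeable algorithms reduce the set of EEG topographies at GFP
maxima to ``M`` representative maps: atomize-and-agglomerate hierarchical
clustering (AAHC), a modified K-means whose cluster update is the principal
eigenvector of the member outer-product sum (hence polarity-blind),
K-medoids under the same squared-correlation dissimilarity, PCA
(eigenvectors of the data covariance), and FastICA (rows of the unmixing
matrix).  All expose the identical contract ``(X_peaks, M, options) ->
MicrostateMaps`` so downstream analysis is algorithm-agnostic.

Back-fitting assigns every time sample the map with maximal squared spatial
correlation ("winner takes all"); squaring makes the assignment — and
everything downstream — blind to map polarity.  Fit quality is scored by
global explained variance (GEV) and the cross-validation criterion (CV)
used to select the best of several stochastic restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA

from .preprocess import EEGRecording, GFPSeries

__all__ = [
    "MicrostateMaps",
    "BackfitResult",
    "backfit",
    "gev",
    "cv_criterion",
    "sigma_sq_residual",
    "cluster_kmeans",
    "cluster_aahc",
    "cluster_kmedoids",
    "cluster_pca",
    "cluster_ica",
    "cluster",
    "ALGORITHMS",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MicrostateMaps:
    """A set of ``M`` unit-norm, zero-mean microstate topographies."""

    maps: np.ndarray           # (M, n_ch)
    algorithm: str

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 2:
            raise ValueError("maps must be a (M >= 2, n_ch) matrix")
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("map rows must have unit Euclidean norm")
        if np.any(np.abs(self.maps.mean(axis=1)) > 1e-9):
            raise ValueError("map rows must be zero-mean (average-reference space)")

    @property
    def M(self) -> int:
        return self.maps.shape[0]

    @property
    def n_ch(self) -> int:
        return self.maps.shape[1]


@dataclass
class BackfitResult:
    """Labels and fit diagnostics from competitive back-fitting."""

    labels: np.ndarray            # (n_t,) ints in 0..M-1
    c_squared: np.ndarray         # (n_t, M) squared covariance with each map
    n_ch: int = 0
    gev_per_map: np.ndarray | None = None
    gev_total: float | None = None
    cv: float | None = None
    sigma_sq: float | None = None


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Project map rows onto the zero-mean subspace and unit-normalize."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate all-zero map")
    return maps / norms


# ---------------------------------------------------------------------------
# back-fitting and fit scores
# ---------------------------------------------------------------------------

def backfit(maps: MicrostateMaps | np.ndarray, rec: EEGRecording | np.ndarray) -> BackfitResult:
    """Assign each topography the map of maximal squared correlation.

    ``C_il^2 = (sum_j X_ij A_lj)^2`` and ``L_i = argmax_l C_il^2``; ties are
    broken toward the lowest map index (argmax convention), and the squared
    form ignores polarity.
    """
    A = maps.maps if isinstance(maps, MicrostateMaps) else np.asarray(maps, float)
    X = rec.data if isinstance(rec, EEGRecording) else np.asarray(rec, float)
    if X.shape[1] != A.shape[1]:
        raise ValueError(
            f"channel mismatch: data has {X.shape[1]} channels, maps {A.shape[1]}"
        )
    c2 = (X @ A.T) ** 2
    labels = np.argmax(c2, axis=1)
    return BackfitResult(labels=labels, c_squared=c2, n_ch=X.shape[1])


def gev(
    result: BackfitResult, gfp: GFPSeries | np.ndarray
) -> tuple[np.ndarray, float]:
    """Global explained variance, per map and total.

    ``GEV_l = sum_{i: L_i = l} sigma_i^2 Corr_il^2 / sum_i sigma_i^2`` where
    ``Corr_il^2`` is the squared covariance normalized by the data vector's
    own power, ``C_il^2 / (sigma_i^2 (n_ch - 1))`` for unit-norm maps — the
    squared spatial correlation — so the total GEV is a bona fide fraction
    in [0, 1].
    """
    sigma = gfp.sigma if isinstance(gfp, GFPSeries) else np.asarray(gfp, float)
    if len(sigma) != len(result.labels):
        raise ValueError("GFP length does not match label length")
    s2 = sigma**2
    denom_total = s2.sum()
    if denom_total <= 0:
        raise ValueError("all-zero GFP: explained variance undefined")
    M = result.c_squared.shape[1]
    idx = np.arange(len(result.labels))
    c2_win = result.c_squared[idx, result.labels]
    # squared correlation = C^2 / (sigma^2 * (n_ch - 1)); infer n_ch-1 scale
    # from the data power: sum_j X_ij^2 = sigma_i^2 * (n_ch - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr2_win = np.where(s2 > 0, c2_win / (s2 * (result.n_ch - 1)), 0.0)
    gev_l = np.zeros(M)
    np.add.at(gev_l, result.labels, s2 * corr2_win)
    gev_l /= denom_total
    total = float(gev_l.sum())
    result.gev_per_map = gev_l
    result.gev_total = total
    return gev_l, total


def sigma_sq_residual(X: np.ndarray, maps: np.ndarray, labels: np.ndarray) -> float:
    """Residual variance of the winner-takes-all representation.

    ``sigma_L^2 = sum_i [ sum_j X_ij^2 - (sum_j X_ij A_{L_i j})^2 ]``
    normalized by ``n_t (n_ch - 1)`` (the constant does not affect the
    optimization but makes values comparable across data sizes).
    """
    n_t, n_ch = X.shape
    proj = np.einsum("ij,ij->i", X, maps[labels])
    resid = np.sum(X**2) - np.sum(proj**2)
    return float(resid / (n_t * (n_ch - 1)))


def cv_criterion(sigma_sq_hat: float, n_ch: int, M: int) -> float:
    """Cross-validation criterion ``CV = sigma_hat^2 ((n_ch-1)/(n_ch-1-M))^2``.

    Penalizes residual variance by the effective degrees of freedom consumed
    by ``M`` maps; used to pick the best stochastic restart.
    """
    if n_ch - 1 <= M:
        raise ValueError("CV requires n_ch - 1 > M")
    return float(sigma_sq_hat * ((n_ch - 1) / (n_ch - 1 - M)) ** 2)


# ---------------------------------------------------------------------------
# clustering algorithms
# ---------------------------------------------------------------------------

def _principal_map(members: np.ndarray) -> np.ndarray:
    """Principal eigenvector of ``sum_i x_i' x_i`` — the polarity-blind mean."""
    # eigh on the small (n_ch x n_ch) scatter matrix; leading eigenvector
    S = members.T @ members
    w, v = np.linalg.eigh(S)
    return v[:, -1]


def _score_cv(X_peaks: np.ndarray, maps: np.ndarray, X_full: np.ndarray | None) -> float:
    """CV of a candidate map set, on the full recording when available."""
    X = X_full if X_full is not None else X_peaks
    labels = np.argmax((X @ maps.T) ** 2, axis=1)
    s2 = sigma_sq_residual(X, maps, labels)
    return cv_criterion(s2, X.shape[1], maps.shape[0])


def cluster_kmeans(
    X_peaks: np.ndarray,
    M: int = 4,
    n_runs: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | np.random.Generator = 0,
    X_full: np.ndarray | None = None,
    trace: list | None = None,
) -> MicrostateMaps:
    """Modified (polarity-blind) K-means.

    Each run starts from ``M`` distinct random GFP-peak topographies and
    alternates competitive back-fitting with the eigenvector map update
    ``A_l <- principal eigenvector of S_l = sum_{i: L_i = l} x_i' x_i``
    until the relative change of the residual variance falls below ``tol``
    or ``max_iter`` is reached.  The run with minimum CV (evaluated on the
    full recording when ``X_full`` is given) wins.  When a list is passed
    as ``trace``, the per-iteration residual variances of each run are
    appended to it (one sub-list per run).
    """
    X = np.asarray(X_peaks, float)
    n_max, n_ch = X.shape
    if n_max < M:
        raise ValueError("fewer GFP peaks than requested clusters")
    rng = np.random.default_rng(seed)
    best_maps, best_cv = None, np.inf
    for _ in range(n_runs):
        init = rng.choice(n_max, size=M, replace=False)
        maps = _normalize_maps(X[init].copy())
        s2_prev = np.inf
        run_trace: list[float] = []
        for _ in range(max_iter):
            labels = np.argmax((X @ maps.T) ** 2, axis=1)
            for l in range(M):
                members = X[labels == l]
                if len(members) == 0:  # re-seed empty cluster from a random peak
                    members = X[rng.integers(n_max)][None, :]
                maps[l] = _principal_map(members)
            maps = _normalize_maps(maps)
            s2 = sigma_sq_residual(X, maps, np.argmax((X @ maps.T) ** 2, axis=1))
            run_trace.append(s2)
            if s2_prev < np.inf and abs(s2_prev - s2) <= tol * max(s2, 1e-30):
                break
            s2_prev = s2
        if trace is not None:
            trace.append(run_trace)
        cv = _score_cv(X, maps, X_full)
        if cv < best_cv:
            best_cv, best_maps = cv, maps.copy()
    return MicrostateMaps(best_maps, "kmeans")


def cluster_aahc(
    X_peaks: np.ndarray, M: int = 4, X_full: np.ndarray | None = None
) -> MicrostateMaps:
    """Atomize-and-agglomerate hierarchical clustering (deterministic).

    Starts with one cluster per peak topography.  Each iteration back-fits
    all peaks to the current cluster maps, computes per-cluster GEV (with
    the peak-set GFP), atomizes the lowest-GEV cluster, re-assigns each of
    its members to the remaining cluster of maximal squared correlation,
    and updates the receiving clusters' maps as the principal eigenvector
    of their member scatter (the polarity-blind mean), until ``M`` clusters
    remain.
    """
    X = np.asarray(X_peaks, float)
    n_max, n_ch = X.shape
    if M > n_max:
        raise ValueError("M exceeds the number of initial clusters (peaks)")
    s2 = np.sum(X**2, axis=1)           # peak-set GFP^2 * (n_ch - 1)
    members: list[list[int]] = [[i] for i in range(n_max)]
    maps = _normalize_maps(X.copy())
    while len(members) > M:
        # per-cluster GEV under the current assignment (members lists)
        gev_l = np.zeros(len(members))
        for l, mem in enumerate(members):
            Xm = X[mem]
            corr2 = (Xm @ maps[l]) ** 2 / s2[mem]
            gev_l[l] = np.sum(s2[mem] * corr2)
        l_min = int(np.argmin(gev_l))
        orphans = members.pop(l_min)
        maps = np.delete(maps, l_min, axis=0)
        # re-assign each orphan to the remaining cluster of max squared corr
        c2 = (X[orphans] @ maps.T) ** 2
        target = np.argmax(c2, axis=1)
        touched = set()
        for o, tgt in zip(orphans, target):
            members[tgt].append(o)
            touched.add(int(tgt))
        for l in touched:
            maps[l] = _principal_map(X[members[l]])
        maps = _normalize_maps(maps)
    return MicrostateMaps(maps, "aahc")


def cluster_kmedoids(
    X_peaks: np.ndarray,
    M: int = 4,
    n_runs: int = 10,
    max_iter: int = 500,
    seed: int | np.random.Generator = 0,
    X_full: np.ndarray | None = None,
) -> MicrostateMaps:
    """K-medoids under the polarity-invariant dissimilarity ``1 - corr^2``.

    Every output map is (a normalized copy of) an actual input topography:
    the member minimizing the total dissimilarity to its co-members.
    """
    X = np.asarray(X_peaks, float)
    n_max, n_ch = X.shape
    if n_max < M:
        raise ValueError("fewer GFP peaks than requested clusters")
    rng = np.random.default_rng(seed)
    Xn = _normalize_maps(X.copy())      # normalized rows for corr^2 distance
    best_idx, best_cv = None, np.inf
    for _ in range(n_runs):
        medoids = rng.choice(n_max, size=M, replace=False)
        for _ in range(max_iter):
            c2 = (Xn @ Xn[medoids].T) ** 2
            labels = np.argmax(c2, axis=1)
            new_medoids = medoids.copy()
            for l in range(M):
                mem = np.where(labels == l)[0]
                if len(mem) == 0:       # re-seed empty cluster
                    new_medoids[l] = rng.integers(n_max)
                    continue
                d = 1.0 - (Xn[mem] @ Xn[mem].T) ** 2
                new_medoids[l] = mem[int(np.argmin(d.sum(axis=1)))]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                medoids = new_medoids
                break
            medoids = new_medoids
        cv = _score_cv(X, Xn[medoids], X_full)
        if cv < best_cv:
            best_cv, best_idx = cv, medoids.copy()
    return MicrostateMaps(Xn[best_idx], "kmedoids")


def cluster_pca(X_peaks: np.ndarray, M: int = 4) -> MicrostateMaps:
    """Top-``M`` eigenvectors of the data covariance ``Q = X'X/(n_max-1)``.

    Deterministic up to row sign, which is irrelevant downstream.  The
    average-referenced data confine the signal to the zero-mean subspace,
    so the leading eigenvectors are themselves zero-mean and mutually
    orthogonal — whence the exactly-zero intra-set correlation this
    algorithm is known for.
    """
    X = np.asarray(X_peaks, float)
    n_max, n_ch = X.shape
    Q = X.T @ X / (n_max - 1)
    w, v = np.linalg.eigh(Q)
    order = np.argsort(w)[::-1]
    if w[order[M - 1]] <= 1e-12 * max(w[order[0]], 1e-30):
        raise ValueError(f"data covariance has rank < {M}")
    maps = v[:, order[:M]].T
    # deterministic sign convention: largest-|.| entry positive
    for row in maps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return MicrostateMaps(_normalize_maps(maps), "pca")


def cluster_ica(
    X_peaks: np.ndarray,
    M: int = 4,
    seed: int | np.random.Generator = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> MicrostateMaps:
    """FastICA unmixing rows as microstate maps.

    Parallel (symmetric) FastICA with whitening to ``M`` components and the
    exponential contrast ``g(u) = u exp(-u^2/2)``; the rows of the unmixing
    matrix are taken as maps.  Row polarity is non-informative downstream.
    """
    X = np.asarray(X_peaks, float)
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many peaks as channels for ICA")
    rs = np.random.RandomState(
        seed if isinstance(seed, int) else int(np.random.default_rng(seed).integers(2**31))
    )
    ica = FastICA(
        n_components=M,
        algorithm="parallel",
        fun="exp",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=rs,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        ica.fit(X)
    W = ica.components_            # (M, n_ch) unmixing matrix
    return MicrostateMaps(_normalize_maps(W), "ica")


ALGORITHMS = {
    "aahc": cluster_aahc,
    "kmeans": cluster_kmeans,
    "kmedoids": cluster_kmedoids,
    "pca": cluster_pca,
    "ica": cluster_ica,
}


def cluster(
    algorithm: str,
    X_peaks: np.ndarray,
    M: int = 4,
    seed: int | np.random.Generator = 0,
    X_full: np.ndarray | None = None,
    **kwargs,
) -> MicrostateMaps:
    """Uniform entry point: dispatch to one of the five algorithms."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    fn = ALGORITHMS[algorithm]
    if algorithm in ("kmeans", "kmedoids"):
        return fn(X_peaks, M=M, seed=seed, X_full=X_full, **kwargs)
    if algorithm == "ica":
        return fn(X_peaks, M=M, seed=seed, **kwargs)
    if algorithm == "aahc":
        return fn(X_peaks, M=M, X_full=X_full, **kwargs)
    return fn(X_peaks, M=M, **kwargs)
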