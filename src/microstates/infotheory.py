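"""Information-theoretic analysis of microstate label sequences.

A back-fitted microstate sequence is a symbolic time series; ordinary
metric tools (autocorrelation, spectra) do not apply directly.  This
module implements the symbolic battery: Shannon and joint entropies
(plug-in estimates), the entropy rate as the least-squares slope of the
joint entropy versus history length (with the usable history length
calibrated against first-order Markov surrogates), the empirical
transition matrix with its spectral summary and mixing time, the
autoinformation function (lagged mutual information, the symbolic analog
of the autocorrelation function) and its first peak, and likelihood-ratio
(G) tests of the Markov property of orders 0-2 and of transition-matrix
stationarity.

Every quantity here is invariant under relabeling permutations of the
symbols.  All entropies are in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import synthetic as _syn

__all__ = [
    "LabelSequence",
    "TransitionMatrix",
    "EntropyRateEstimate",
    "AIFCurve",
    "shannon_entropy",
    "joint_entropy",
    "entropy_rate",
    "mc_entropy_rate",
    "markov_surrogate",
    "calibrate_history",
    "transition_matrix",
    "mixing_time",
    "aif",
    "first_aif_peak",
    "markov_test",
    "stationarity_test",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LabelSequence:
    """An integer symbol sequence with alphabet size and sampling rate."""

    labels: np.ndarray
    M: int
    fs: float = 250.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) < 1:
            raise ValueError("labels must be a non-empty 1-D integer array")
        if self.labels.min() < 0 or self.labels.max() >= self.M:
            raise ValueError(f"labels must lie in 0..{self.M - 1}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TransitionMatrix:
    """Empirical one-step transition matrix with eigen-summary."""

    T: np.ndarray                  # (M, M) row-stochastic
    counts: np.ndarray             # (M, M) integer transition counts
    pi: np.ndarray                 # empirical symbol distribution
    eigenvalues: np.ndarray        # sorted by modulus, descending
    spectral_gap: float            # lambda_0 - |lambda_1|
    mixing_time: float             # 1 / (1 - |lambda_1|); inf if |lambda_1| = 1
    zero_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class EntropyRateEstimate:
    """Joint entropies h_1..h_{n_max} and the fitted entropy rate."""

    h_n: np.ndarray                # joint entropies, index n-1
    slope: float                   # OLS slope of h_n vs n (nats / step)
    n_max: int
    n_hat: int | None = None       # calibrated history length, if known
    epsilon: float | None = None   # relative error vs surrogate theory


@dataclass
class AIFCurve:
    """Autoinformation function I(k) over integer lags."""

    lags: np.ndarray               # sample lags 0..max_lag
    values: np.ndarray             # I(k) in nats
    fs: float

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs


def _labels_of(seq: LabelSequence | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(seq, LabelSequence):
        return seq.labels, seq.M
    x = np.asarray(seq, dtype=int)
    return x, int(x.max()) + 1


def _plugin_entropy(counts: np.ndarray) -> float:
    """Entropy of a count vector; 0 log 0 := 0, natural log."""
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# entropies and entropy rate
# ---------------------------------------------------------------------------

def shannon_entropy(seq: LabelSequence | np.ndarray) -> float:
    """Shannon entropy h = -sum_i p_i log p_i of the symbol distribution."""
    x, M = _labels_of(seq)
    return _plugin_entropy(np.bincount(x, minlength=M))


def _ngram_codes(x: np.ndarray, M: int, n: int) -> np.ndarray:
    """Encode all overlapping n-grams as base-M integers."""
    n_win = len(x) - n + 1
    codes = np.zeros(n_win, dtype=np.int64)
    for i in range(n):
        codes = codes * M + x[i : i + n_win]
    return codes


def joint_entropy(seq: LabelSequence | np.ndarray, n: int) -> float:
    """Plug-in joint entropy h_n over all overlapping n-grams."""
    x, M = _labels_of(seq)
    if n < 1:
        raise ValueError("history length n must be >= 1")
    if len(x) < n + 1:
        raise ValueError(f"sequence of length {len(x)} too short for n = {n}")
    _, counts = np.unique(_ngram_codes(x, M, n), return_counts=True)
    return _plugin_entropy(counts)


def entropy_rate(
    seq: LabelSequence | np.ndarray, n_max: int = 8
) -> EntropyRateEstimate:
    """Entropy rate as the OLS slope of (n, h_n) for n = 1..n_max.

    The plug-in joint entropies saturate once M^n outgrows the sample size;
    ``n_max`` should be chosen by :func:`calibrate_history` (8 for typical
    4-symbol microstate sequences of ~30,000 samples).
    """
    x, M = _labels_of(seq)
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    if len(x) < 10 * M**n_max:
        warnings.warn(
            f"sequence length {len(x)} < 10 * M^n_max = {10 * M**n_max}: "
            "joint entropies at large n may be undersampled",
            stacklevel=2,
        )
    ns = np.arange(1, n_max + 1)
    h_n = np.array([joint_entropy(seq, int(n)) for n in ns])
    slope = float(np.polyfit(ns, h_n, 1)[0])
    return EntropyRateEstimate(h_n=h_n, slope=slope, n_max=n_max)


def mc_entropy_rate(pi: np.ndarray, T: np.ndarray) -> float:
    """Closed-form Markov-chain entropy rate -sum_i pi_i sum_j T_ij log T_ij."""
    pi = np.asarray(pi, float)
    T = np.asarray(T, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logT = np.where(T > 0, np.log(np.where(T > 0, T, 1.0)), 0.0)
    return float(-np.sum(pi[:, None] * T * logT))


# ---------------------------------------------------------------------------
# surrogates and history-length calibration
# ---------------------------------------------------------------------------

def markov_surrogate(
    seq: LabelSequence | np.ndarray, seed: int | np.random.Generator = 0
) -> LabelSequence:
    """First-order Markov surrogate with the sequence's empirical pi and T.

    Symbols never observed in the input are excluded from the surrogate
    alphabet (their transition rows are undefined), with a warning.
    """
    x, M = _labels_of(seq)
    fs = seq.fs if isinstance(seq, LabelSequence) else 250.0
    observed = np.unique(x)
    if len(observed) < M:
        warnings.warn(
            f"{M - len(observed)} symbol(s) never observed; surrogate uses the "
            f"{len(observed)}-symbol sub-alphabet",
            stacklevel=2,
        )
        remap = -np.ones(M, dtype=int)
        remap[observed] = np.arange(len(observed))
        x = remap[x]
        M_eff = len(observed)
    else:
        M_eff = M
    if M_eff == 1:
        return LabelSequence(np.zeros(len(x), dtype=int) + observed[0], M, fs)
    tm = transition_matrix(LabelSequence(x, M_eff, fs))
    sur = _syn.generate_markov_labels(tm.pi, tm.T, len(x), seed)
    if M_eff < M:
        sur = observed[sur]
    return LabelSequence(sur, M, fs)


def calibrate_history(
    seqs: list[LabelSequence],
    n_range: range = range(4, 11),
    eps_max: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[int, dict[int, float]]:
    """Largest history length whose entropy-rate estimate is trustworthy.

    For each sequence a same-length first-order Markov surrogate is built;
    ``eps(n)`` is the mean over sequences of the relative error between the
    slope estimate at history ``n`` and the surrogate's closed-form rate.
    Returns the largest ``n`` in ``n_range`` with ``eps(n) < eps_max`` and
    the full ``eps`` profile.  If no ``n`` qualifies, the smallest ``n`` is
    returned with a warning.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    rng = np.random.default_rng(seed)
    n_list = sorted(n_range)
    rel_err = np.zeros((len(seqs), len(n_list)))
    for s_i, seq in enumerate(seqs):
        sur = markov_surrogate(seq, rng)
        tm = transition_matrix(sur)
        h_mc = mc_entropy_rate(tm.pi, tm.T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = entropy_rate(sur, n_max=max(n_list))
        ns = np.arange(1, max(n_list) + 1)
        for n_j, n in enumerate(n_list):
            slope = float(np.polyfit(ns[:n], est.h_n[:n], 1)[0])
            rel_err[s_i, n_j] = abs(slope - h_mc) / h_mc
    eps = {n: float(rel_err[:, j].mean()) for j, n in enumerate(n_list)}
    good = [n for n in n_list if eps[n] < eps_max]
    if good:
        return max(good), eps
    warnings.warn(
        f"no history length in {n_list} meets eps < {eps_max}; "
        f"returning the smallest ({n_list[0]})",
        stacklevel=2,
    )
    return n_list[0], eps


# ---------------------------------------------------------------------------
# transition matrix, spectrum, mixing time
# ---------------------------------------------------------------------------

def transition_matrix(seq: LabelSequence | np.ndarray) -> TransitionMatrix:
    """Empirical one-step transition matrix with eigen-summary.

    Rows without outgoing transitions are replaced by the empirical symbol
    distribution (flagged in ``zero_rows``) so that T stays row-stochastic.
    The eigenvalues are sorted by modulus; the Perron eigenvalue is 1, the
    spectral gap is ``1 - |lambda_1|`` and the mixing time its reciprocal.
    """
    x, M = _labels_of(seq)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to estimate transitions")
    counts = np.zeros((M, M), dtype=np.int64)
    np.add.at(counts, (x[:-1], x[1:]), 1)
    pi = np.bincount(x, minlength=M) / len(x)
    rowsums = counts.sum(axis=1)
    zero_rows = np.where(rowsums == 0)[0]
    T = np.empty((M, M))
    for i in range(M):
        T[i] = pi if rowsums[i] == 0 else counts[i] / rowsums[i]
    eig = np.linalg.eigvals(T)
    order = np.argsort(-np.abs(eig))
    eig = eig[order]
    lam1 = float(np.abs(eig[1])) if M > 1 else 0.0
    gap = 1.0 - lam1
    tau = np.inf if gap <= 0 else 1.0 / gap
    return TransitionMatrix(
        T=T,
        counts=counts,
        pi=pi,
        eigenvalues=eig,
        spectral_gap=gap,
        mixing_time=float(tau),
        zero_rows=zero_rows,
    )


def mixing_time(tm: TransitionMatrix) -> float:
    """Relaxation time tau = 1 / (1 - |lambda_1|) of the label chain."""
    return tm.mixing_time


# ---------------------------------------------------------------------------
# autoinformation function
# ---------------------------------------------------------------------------

def aif(seq: LabelSequence | np.ndarray, max_lag: int) -> AIFCurve:
    """Time-lagged mutual information I(k) = H(X_{t+k}) - H(X_{t+k} | X_t).

    Plug-in estimate from the empirical joint distribution of
    ``(X_t, X_{t+k})`` over all valid ``t``; marginals are taken from the
    same joint, so ``I(k) >= 0`` and ``I(0)`` equals the Shannon entropy
    exactly.
    """
    x, M = _labels_of(seq)
    fs = seq.fs if isinstance(seq, LabelSequence) else 250.0
    if max_lag >= len(x):
        raise ValueError("max_lag must be smaller than the sequence length")
    values = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        a = x[: len(x) - k]
        b = x[k:]
        joint = np.zeros((M, M))
        np.add.at(joint, (a, b), 1)
        h_a = _plugin_entropy(joint.sum(axis=1))
        h_b = _plugin_entropy(joint.sum(axis=0))
        h_ab = _plugin_entropy(joint.ravel())
        values[k] = h_a + h_b - h_ab
    return AIFCurve(lags=np.arange(max_lag + 1), values=values, fs=fs)


def first_aif_peak(
    curve: AIFCurve, min_lag: int = 8, smooth_window: int = 3
) -> float | None:
    """First local AIF maximum at lags strictly greater than ``min_lag``.

    The curve is smoothed with a centered moving average of ``smooth_window``
    samples, then scanned with the same discrete sign-change rule used for
    GFP peaks.  Returns the location in milliseconds, or ``None`` when no
    local maximum exists beyond ``min_lag``.
    """
    v = curve.values
    if len(v) <= min_lag + 2:
        raise ValueError("AIF curve does not extend beyond min_lag")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.convolve(v, kernel, mode="same")
        # restore unsmoothed edges (partial windows)
        h = smooth_window // 2
        sm[:h] = v[:h]
        sm[len(v) - h :] = v[len(v) - h :]
    else:
        sm = v
    delta = np.diff(sm)
    sgn = np.sign(delta)
    peaks = np.where(sgn[1:] - sgn[:-1] == -2)[0] + 1
    peaks = peaks[peaks > min_lag]
    if len(peaks) == 0:
        return None
    return float(peaks[0] * 1000.0 / curve.fs)


# ---------------------------------------------------------------------------
# Markov-order and stationarity tests
# ---------------------------------------------------------------------------

def _g_statistic(obs: np.ndarray, expected: np.ndarray) -> float:
    """Likelihood-ratio statistic 2 sum obs * log(obs / expected)."""
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))


def markov_test(seq: LabelSequence | np.ndarray, order: int) -> tuple[float, int, float]:
    """Likelihood-ratio (G) test of the Markov property of order 0, 1 or 2.

    order 0 tests independence of consecutive symbols
    (``G = 2 sum n_ij log(n_ij n / (n_i. n_.j))``, df ``(M-1)^2``); order 1
    tests first- against second-order dependence on trigram counts
    (df ``M (M-1)^2``); order 2 the analogous tetragram form
    (df ``M^2 (M-1)^2``).  Zero-count cells contribute zero.  Returns
    ``(G, df, p)`` with the asymptotic chi-square null.
    """
    x, M = _labels_of(seq)
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate single-symbol sequence: test undefined")
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    k = order + 2  # k-gram counts needed
    if len(x) < k:
        raise ValueError("sequence too short for the requested order")
    n_win = len(x) - k + 1
    grams = np.stack([x[i : i + n_win] for i in range(k)], axis=1)

    if order == 0:
        counts = np.zeros((M, M))
        np.add.at(counts, (grams[:, 0], grams[:, 1]), 1)
        n = counts.sum()
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
        df = (M - 1) ** 2
    elif order == 1:
        counts = np.zeros((M, M, M))
        np.add.at(counts, (grams[:, 0], grams[:, 1], grams[:, 2]), 1)
        n_ij = counts.sum(axis=2)          # (i, j)
        n_jk = counts.sum(axis=0)          # (j, k)
        n_j = counts.sum(axis=(0, 2))      # (j,)
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = (
                n_ij[:, :, None] * n_jk[None, :, :] / n_j[None, :, None]
            )
        expected = np.nan_to_num(expected)
        df = M * (M - 1) ** 2
    else:
        counts = np.zeros((M, M, M, M))
        np.add.at(counts, (grams[:, 0], grams[:, 1], grams[:, 2], grams[:, 3]), 1)
        n_ijk = counts.sum(axis=3)         # (i, j, k)
        n_jkl = counts.sum(axis=0)         # (j, k, l)
        n_jk = counts.sum(axis=(0, 3))     # (j, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = (
                n_ijk[:, :, :, None] * n_jkl[None, :, :, :] / n_jk[None, :, :, None]
            )
        expected = np.nan_to_num(expected)
        df = M**2 * (M - 1) ** 2

    min_expected = expected[counts > 0].min() if np.any(counts > 0) else 0.0
    if min_expected < 1.0:
        warnings.warn(
            "expected counts below 1: the chi-square approximation may be poor",
            stacklevel=2,
        )
    G = _g_statistic(counts, expected)
    p = float(stats.chi2.sf(G, df))
    return G, df, p


def stationarity_test(
    seq: LabelSequence | np.ndarray, L: int
) -> tuple[float, int, float]:
    """G-test of transition-matrix homogeneity across blocks of length ``L``.

    The sequence is partitioned into ``r = floor(n / L)`` non-overlapping
    blocks; block transition counts are tested against the pooled transition
    matrix, ``df = (r - 1) M (M - 1)``.  Small p-values indicate the one-step
    dynamics drift over time (non-stationarity).
    """
    x, M = _labels_of(seq)
    r = len(x) // L
    if r < 2:
        raise ValueError(f"need at least 2 blocks of length {L}; have {len(x)} samples")
    block_counts = np.zeros((r, M, M))
    for b in range(r):
        blk = x[b * L : (b + 1) * L]
        np.add.at(block_counts[b], (blk[:-1], blk[1:]), 1)
    pooled = block_counts.sum(axis=0)
    pooled_rows = pooled.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        T_pooled = np.where(pooled_rows > 0, pooled / pooled_rows, 0.0)
    block_rows = block_counts.sum(axis=2, keepdims=True)
    expected = block_rows * T_pooled[None, :, :]
    G = _g_statistic(block_counts, expected)
    df = (r - 1) * M * (M - 1)
    p = float(stats.chi2.sf(G, df))
    return G, df, p
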