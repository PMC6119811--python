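"""Hurst-exponent estimation for symbolic microstate sequences.

A symbolic sequence carries no metric scale, so long-range dependence is
probed through a random-walk embedding: each balanced bipartition of the
label alphabet maps the sequence to a +/-1 increment series whose
cumulative sum is a random walk.  Three standard estimators of the Hurst
exponent H are applied to the increments and averaged over the
embeddings: aggregated variance (AV), detrended fluctuation analysis
(DFA, order 1), and the wavelet log-scale diagram (Veitch-Abry style,
Daubechies-2).  For a short-range-correlated stationary process H = 0.5;
H > 0.5 indicates persistent long-range correlations (subject to the
usual caveat that non-stationarity mimics them).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .infotheory import LabelSequence

__all__ = [
    "WalkEmbedding",
    "HurstEstimate",
    "embed_walks",
    "hurst_av",
    "hurst_dfa",
    "hurst_dwt",
    "hurst_all",
]


@dataclass
class WalkEmbedding:
    """+/-1 increment series (one per balanced label bipartition) and walks."""

    increments: np.ndarray         # (n_parts, n_t) of +/-1
    walks: np.ndarray              # cumulative sums, same shape
    partitions: list[tuple[int, ...]]


@dataclass
class HurstEstimate:
    """Hurst exponents from the three estimators, with per-scale diagnostics."""

    H_av: float
    H_dfa: float
    H_dwt: float
    diagnostics: dict


def _balanced_bipartitions(M: int) -> list[tuple[int, ...]]:
    """Subsets defining the +1 side of each balanced bipartition.

    For even M each unordered bipartition is listed once (the subset
    containing symbol 0); for odd M the near-balanced subsets of size
    M // 2 are used.
    """
    half = M // 2
    if M % 2 == 0:
        return [s for s in combinations(range(M), half) if 0 in s]
    return list(combinations(range(M), half))


def embed_walks(seq: LabelSequence | np.ndarray) -> WalkEmbedding:
    """Map a label sequence to +/-1 increments, one per balanced bipartition.

    For the canonical M = 4 alphabet this yields the 3 bipartitions
    {01|23}, {02|13}, {03|12}.
    """
    if isinstance(seq, LabelSequence):
        x, M = seq.labels, seq.M
    else:
        x = np.asarray(seq, dtype=int)
        M = int(x.max()) + 1
    parts = _balanced_bipartitions(M)
    inc = np.empty((len(parts), len(x)))
    for p_i, subset in enumerate(parts):
        member = np.isin(x, subset)
        inc[p_i] = np.where(member, 1.0, -1.0)
    return WalkEmbedding(increments=inc, walks=np.cumsum(inc, axis=1), partitions=parts)


def _log_scales(n: int, smallest: int, largest: int, per_decade: int = 10) -> np.ndarray:
    """Distinct integer scales, log-spaced ``per_decade`` per decade."""
    n_pts = max(4, int(np.log10(largest / smallest) * per_decade) + 1)
    scales = np.unique(np.round(np.geomspace(smallest, largest, n_pts)).astype(int))
    return scales[scales >= smallest]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def hurst_av(x: np.ndarray) -> tuple[float, dict]:
    """Aggregated-variance estimate.

    Block-average the increments at log-spaced block sizes m; the variance
    of the block means scales as m^(2H-2), so the log-log slope beta gives
    H = 1 + beta / 2.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2**9:
        raise ValueError("aggregated variance needs at least 512 samples")
    scales = _log_scales(n, smallest=2, largest=n // 16)
    if len(scales) < 4:
        raise ValueError("too few block sizes for the log-log regression")
    variances = np.empty(len(scales))
    for s_i, m in enumerate(scales):
        k = n // m
        means = x[: k * m].reshape(k, m).mean(axis=1)
        variances[s_i] = means.var(ddof=1)
    if np.any(variances <= 0):
        raise ValueError("degenerate (constant) increments: variance collapses to 0")
    beta = float(np.polyfit(np.log(scales), np.log(variances), 1)[0])
    return 1.0 + beta / 2.0, {"scales": scales, "variances": variances}


def hurst_dfa(x: np.ndarray) -> tuple[float, dict]:
    """Detrended fluctuation analysis, order 1.

    Integrate the (mean-removed) increments, split into windows of size s,
    remove a linear trend per window, and regress log RMS fluctuation F(s)
    on log s; the slope is H.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2**9:
        raise ValueError("DFA needs at least 512 samples")
    y = np.cumsum(x - x.mean())
    scales = _log_scales(n, smallest=8, largest=n // 8)
    if len(scales) < 4:
        raise ValueError("too few window sizes for the log-log regression")
    fluct = np.empty(len(scales))
    for s_i, s in enumerate(scales):
        k = n // s
        seg = y[: k * s].reshape(k, s)
        t = np.arange(s)
        # per-window linear detrend via least squares on a shared design
        A = np.vstack([t, np.ones(s)]).T
        coef, *_ = np.linalg.lstsq(A, seg.T, rcond=None)
        resid = seg.T - A @ coef
        fluct[s_i] = np.sqrt(np.mean(resid**2))
    if np.any(fluct <= 0):
        raise ValueError("degenerate increments: zero fluctuation")
    H = float(np.polyfit(np.log(scales), np.log(fluct), 1)[0])
    return H, {"scales": scales, "fluctuations": fluct}


# Daubechies-2 (4-tap) analysis filters
_SQ3 = np.sqrt(3.0)
_DB2_LO = np.array([1 + _SQ3, 3 + _SQ3, 3 - _SQ3, 1 - _SQ3]) / (4 * np.sqrt(2.0))
_DB2_HI = np.array([_DB2_LO[3], -_DB2_LO[2], _DB2_LO[1], -_DB2_LO[0]])


def _dwt_details(x: np.ndarray, max_level: int) -> list[np.ndarray]:
    """Mallat pyramid: detail coefficients per octave (periodic extension)."""
    details = []
    approx = x
    for _ in range(max_level):
        if len(approx) < 4:
            break
        ext = np.concatenate([approx, approx[:3]])  # periodic boundary
        lo = np.convolve(ext, _DB2_LO[::-1], mode="valid")[: len(approx)][::2]
        hi = np.convolve(ext, _DB2_HI[::-1], mode="valid")[: len(approx)][::2]
        details.append(hi)
        approx = lo
    return details


def hurst_dwt(x: np.ndarray) -> tuple[float, dict]:
    """Wavelet log-scale-diagram estimate (Veitch-Abry style).

    Per octave j the log2 of the mean squared Daubechies-2 detail
    coefficients is regressed on j with weights proportional to the number
    of coefficients per octave; for a stationary increment process the
    slope gamma relates to the Hurst exponent as H = (gamma + 1) / 2.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2**10:
        raise ValueError("wavelet estimate needs at least 1024 samples")
    j_max = int(np.floor(np.log2(n))) - 3
    details = _dwt_details(x, j_max)
    j_lo = 3
    if len(details) < j_lo + 1:
        raise ValueError("insufficient octaves for the log-scale regression")
    js, mus, njs = [], [], []
    for j, d in enumerate(details, start=1):
        if j < j_lo or len(d) < 4:
            continue
        js.append(j)
        mus.append(np.mean(d**2))
        njs.append(len(d))
    if len(js) < 3:
        raise ValueError("insufficient octaves for the log-scale regression")
    js = np.array(js, float)
    logmu = np.log2(np.array(mus))
    w = np.array(njs, float)       # more coefficients -> smaller variance
    # weighted least squares slope
    W = w / w.sum()
    jbar = np.sum(W * js)
    ybar = np.sum(W * logmu)
    gamma = float(np.sum(W * (js - jbar) * (logmu - ybar)) / np.sum(W * (js - jbar) ** 2))
    return (gamma + 1.0) / 2.0, {"octaves": js, "log2_energy": logmu, "n_coeffs": njs}


def hurst_all(seq: LabelSequence | np.ndarray) -> HurstEstimate:
    """All three estimators, averaged over the balanced-bipartition walks."""
    emb = embed_walks(seq)
    per_method: dict[str, list[float]] = {"av": [], "dfa": [], "dwt": []}
    diags = []
    for inc in emb.increments:
        h_av, d_av = hurst_av(inc)
        h_dfa, d_dfa = hurst_dfa(inc)
        h_dwt, d_dwt = hurst_dwt(inc)
        per_method["av"].append(h_av)
        per_method["dfa"].append(h_dfa)
        per_method["dwt"].append(h_dwt)
        diags.append({"av": d_av, "dfa": d_dfa, "dwt": d_dwt})
    return HurstEstimate(
        H_av=float(np.mean(per_method["av"])),
        H_dfa=float(np.mean(per_method["dfa"])),
        H_dwt=float(np.mean(per_method["dwt"])),
        diagnostics={"per_partition": diags, "partitions": emb.partitions},
    )
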