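"""Map-similarity measures and group-level statistics.

Similarity between microstate topographies is the absolute Pearson
correlation (polarity is not physiological, so the sign is discarded).
Within one algorithm's map set the summary is the maximum off-diagonal
|rho| over all unordered pairs (rho_max); between two algorithms it is
the maximum |rho| over all cross pairs (c_max), assembled into the
across-algorithm C^max table.  Group-level comparisons across algorithms
use a classical one-way ANOVA, pairwise Welch (unequal-variance) t-tests
and Bonferroni correction; cohort-level relations between the summary
quantities are plain Pearson cross-correlations across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import MicrostateMaps

__all__ = [
    "map_correlation",
    "similarity_matrix",
    "intragroup_rho_max",
    "intergroup_cmax",
    "cmax_table",
    "GroupStats",
    "group_stats",
    "property_correlations",
]


def _rows_of(maps: MicrostateMaps | np.ndarray) -> np.ndarray:
    return maps.maps if isinstance(maps, MicrostateMaps) else np.asarray(maps, float)


def map_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute Pearson correlation |rho(u, v)| between two topographies.

    Map means are subtracted even though average-reference maps are already
    (near) zero-mean; a zero-variance map makes the correlation undefined.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("maps must have equal channel counts")
    du = u - u.mean()
    dv = v - v.mean()
    su = np.linalg.norm(du)
    sv = np.linalg.norm(dv)
    if su == 0 or sv == 0:
        raise ValueError("zero-variance map: correlation undefined")
    return float(abs(du @ dv) / (su * sv))


def similarity_matrix(
    mapsA: MicrostateMaps | np.ndarray, mapsB: MicrostateMaps | np.ndarray
) -> np.ndarray:
    """|rho| between every map of A and every map of B (M_A x M_B)."""
    A = _rows_of(mapsA)
    B = _rows_of(mapsB)
    dA = A - A.mean(axis=1, keepdims=True)
    dB = B - B.mean(axis=1, keepdims=True)
    nA = np.linalg.norm(dA, axis=1)
    nB = np.linalg.norm(dB, axis=1)
    if np.any(nA == 0) or np.any(nB == 0):
        raise ValueError("zero-variance map: correlation undefined")
    return np.abs(dA @ dB.T) / np.outer(nA, nB)


def intragroup_rho_max(maps: MicrostateMaps | np.ndarray) -> float:
    """Maximum |rho| over the M(M-1)/2 unordered map pairs of one set."""
    A = _rows_of(maps)
    if A.shape[0] < 2:
        raise ValueError("need at least two maps")
    C = similarity_matrix(A, A)
    iu = np.triu_indices(A.shape[0], k=1)
    return float(C[iu].max())


def intergroup_cmax(
    mapsA: MicrostateMaps | np.ndarray, mapsB: MicrostateMaps | np.ndarray
) -> float:
    """Maximum |rho| over all cross pairs between two map sets."""
    return float(similarity_matrix(mapsA, mapsB).max())


def cmax_table(map_sets: dict[str, MicrostateMaps | np.ndarray]) -> pd.DataFrame:
    """Across-algorithm C^max table (symmetric, unit diagonal)."""
    names = list(map_sets)
    out = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in combinations(names, 2):
        c = intergroup_cmax(map_sets[a], map_sets[b])
        out.loc[a, b] = out.loc[b, a] = c
    return out


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupStats:
    """Across-subject summary of one quantity, compared across algorithms."""

    mean: pd.Series                 # per algorithm
    sd: pd.Series                   # per algorithm (ddof=1)
    sem: pd.Series                  # standard error of the mean
    anova_F: float
    anova_p: float
    pairwise_p: pd.DataFrame        # Welch t-test p-values (raw)
    pairwise_p_bonf: pd.DataFrame   # Bonferroni-adjusted (x n_pairs, capped at 1)
    degenerate: bool = False        # constant columns make the ANOVA undefined


def group_stats(values: pd.DataFrame) -> GroupStats:
    """One-way ANOVA + pairwise Welch t-tests across algorithm columns.

    ``values`` is a subjects x algorithms table of one summary quantity.
    The ANOVA is the classical equal-variance one-way test; the post-hoc
    pairwise tests are two-sided Welch t-tests with Bonferroni correction
    over the number of pairs.
    """
    if values.shape[1] < 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 algorithms and 2 subjects")
    cols = list(values.columns)
    arrays = [values[c].to_numpy(float) for c in cols]
    degenerate = all(np.allclose(a, a[0]) for a in arrays)
    if degenerate:
        F, p_anova = 0.0, 1.0
    else:
        F, p_anova = stats.f_oneway(*arrays)
    n_pairs = len(cols) * (len(cols) - 1) // 2
    praw = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        _, p = stats.ttest_ind(values[a], values[b], equal_var=False)
        if np.isnan(p):            # identical constant columns
            p = 1.0
        praw.loc[a, b] = praw.loc[b, a] = p
    pbonf = (praw * n_pairs).clip(upper=1.0)
    np.fill_diagonal(pbonf.values, 1.0)
    return GroupStats(
        mean=values.mean(),
        sd=values.std(ddof=1),
        sem=values.sem(ddof=1),
        anova_F=float(F),
        anova_p=float(p_anova),
        pairwise_p=praw,
        pairwise_p_bonf=pbonf,
        degenerate=degenerate,
    )


def property_correlations(
    report: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson cross-correlations between summary quantities across subjects.

    ``report`` is a subjects x quantities table (one algorithm).  Returns
    the correlation matrix and a boolean significance mask at level
    ``alpha`` (two-sided, uncorrected).
    """
    if report.shape[0] < 3:
        raise ValueError("need at least 3 subjects for correlations")
    cols = list(report.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    sig = pd.DataFrame(
        np.eye(len(cols), dtype=bool), index=cols, columns=cols
    )
    for a, b in combinations(cols, 2):
        rho, p = stats.pearsonr(report[a], report[b])
        r.loc[a, b] = r.loc[b, a] = rho
        sig.loc[a, b] = sig.loc[b, a] = p < alpha
    return r, sig
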