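"""End-to-end orchestration: simulate/load -> cluster -> back-fit -> analyze.

One *cell* of the analysis is (subject, algorithm): microstate maps are
computed from the subject's GFP-peak topographies with one clustering
algorithm, labels are back-fitted over the whole recording, and the
static (rho_max, GEV, entropy) and dynamic (mixing time, entropy rate,
first AIF peak) summaries plus the Markov-order, stationarity and Hurst
batteries are evaluated on the label sequence.  Cells are independent;
a failure in one is recorded and the run continues.  Per-cell seeds are
derived from the master seed, so reruns with the same config are
bit-identical.
"""

from __future__ import annotations

import json
import logging
import traceback
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as cl
from . import compare as cmp
from . import infotheory as it
from . import hurst as hu
from .preprocess import EEGRecording, average_reference, gfp_peak_maps, compute_gfp
from .synthetic import SyntheticSpec, generate_alpha_eeg

logger = logging.getLogger("microstates")

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "write_report"]

ALGORITHM_ORDER = ["aahc", "kmeans", "kmedoids", "pca", "ica"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults follow the standard resting-state protocol: M = 4 maps, best
    of 10 stochastic restarts (500 iterations, tol 1e-6), entropy-rate
    history n = 8, AIF first peak searched at lags > 8 samples after
    size-3 smoothing, stationarity blocks L in {500, 1000, 2500, 5000,
    10000}, Bonferroni over the number of subjects.
    """

    n_subjects: int = 20
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHM_ORDER))
    M: int = 4
    seed: int = 0
    synthetic: SyntheticSpec | None = None
    recordings: list[EEGRecording] | None = None
    n_runs: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    entropy_history: int = 8
    aif_max_lag: int = 100
    aif_min_lag: int = 8
    aif_smooth: int = 3
    stationarity_blocks: list[int] = field(
        default_factory=lambda: [500, 1000, 2500, 5000, 10000]
    )
    bonferroni: int | None = None      # defaults to n_subjects
    hurst: bool = True
    aahc_max_peaks: int | None = 2000  # subsample AAHC input beyond this

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHM_ORDER)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")


@dataclass
class AnalysisReport:
    """Per-cell summaries plus raw artifacts of a pipeline run."""

    cells: pd.DataFrame                       # one row per (subject, algorithm)
    maps: dict[tuple[int, str], cl.MicrostateMaps]
    labels: dict[tuple[int, str], it.LabelSequence]
    cmax: pd.DataFrame | None = None          # across-algorithm C^max (mean)
    errors: list[dict] = field(default_factory=list)
    config: RunConfig | None = None

    def table(self, quantity: str) -> pd.DataFrame:
        """Subjects x algorithms table of one summary quantity."""
        return self.cells.pivot(index="subject", columns="algorithm", values=quantity)


def _cell_seed(master: int, subject: int, algo: str) -> int:
    """Stable per-cell seed below 2**31."""
    h = (master * 1_000_003 + subject * 1009 + ALGORITHM_ORDER.index(algo)) % (2**31 - 1)
    return int(h)


def _analyze_cell(
    rec: EEGRecording,
    X_peaks: np.ndarray,
    algo: str,
    cfg: RunConfig,
    seed: int,
    rng: np.random.Generator,
) -> tuple[dict, cl.MicrostateMaps, it.LabelSequence]:
    X_full = rec.data
    if algo == "aahc" and cfg.aahc_max_peaks and len(X_peaks) > cfg.aahc_max_peaks:
        # AAHC cost grows ~quadratically with the initial cluster count;
        # subsample the peak set deterministically to keep it tractable
        idx = np.sort(rng.choice(len(X_peaks), cfg.aahc_max_peaks, replace=False))
        X_in = X_peaks[idx]
    else:
        X_in = X_peaks
    maps = cl.cluster(
        algo, X_in, M=cfg.M, seed=seed, X_full=X_full,
        **(
            {"n_runs": cfg.n_runs, "max_iter": cfg.max_iter, "tol": cfg.tol}
            if algo == "kmeans"
            else {"n_runs": cfg.n_runs, "max_iter": cfg.max_iter}
            if algo == "kmedoids"
            else {}
        ),
    )
    fit = cl.backfit(maps, rec)
    _, gev_total = cl.gev(fit, compute_gfp(rec))
    seq = it.LabelSequence(fit.labels, cfg.M, rec.fs)

    row: dict = {
        "algorithm": algo,
        "rho_max": cmp.intragroup_rho_max(maps),
        "gev": gev_total,
        "entropy": it.shannon_entropy(seq),
    }
    tm = it.transition_matrix(seq)
    row["mixing_time"] = tm.mixing_time
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        row["entropy_rate"] = it.entropy_rate(seq, n_max=cfg.entropy_history).slope
    curve = it.aif(seq, cfg.aif_max_lag)
    row["aif_first_peak_ms"] = it.first_aif_peak(
        curve, min_lag=cfg.aif_min_lag, smooth_window=cfg.aif_smooth
    )
    for order in (0, 1, 2):
        try:
            _, _, p = it.markov_test(seq, order)
        except ValueError:
            p = np.nan
        row[f"markov_p{order}"] = p
    for L in cfg.stationarity_blocks:
        try:
            _, _, p = it.stationarity_test(seq, L)
        except ValueError:
            p = np.nan
        row[f"stationarity_p_L{L}"] = p
    if cfg.hurst:
        hest = hu.hurst_all(seq)
        row["H_av"], row["H_dfa"], row["H_dwt"] = hest.H_av, hest.H_dfa, hest.H_dwt
    return row, maps, seq


def run_pipeline(cfg: RunConfig) -> AnalysisReport:
    """Run every (subject, algorithm) cell and assemble the report.

    Subjects come either from ``cfg.recordings`` (already preprocessed,
    average-referenced) or from the synthetic generator (each subject gets
    a distinct seed derived from the master seed).  Failures are isolated
    per cell and collected in ``report.errors``.
    """
    rows, maps_store, labels_store, errors = [], {}, {}, []
    cmax_sum: np.ndarray | None = None
    cmax_n = 0

    if cfg.recordings is not None:
        subjects = list(enumerate(cfg.recordings))
    else:
        base = cfg.synthetic or SyntheticSpec()
        subjects = []
        for s in range(cfg.n_subjects):
            spec = SyntheticSpec(
                duration=base.duration, fs=base.fs, n_ch=base.n_ch,
                M_true=base.M_true, alpha_freq=base.alpha_freq,
                alpha_band=base.alpha_band, dwell_mean=base.dwell_mean,
                snr=base.snr, seed=_cell_seed(cfg.seed, s, "aahc") + 7,
            )
            rec, _ = generate_alpha_eeg(spec)
            subjects.append((s, rec))

    for s, rec in subjects:
        rec = average_reference(rec)
        X_peaks, gfp = gfp_peak_maps(rec)
        subject_maps: dict[str, cl.MicrostateMaps] = {}
        for algo in cfg.algorithms:
            seed = _cell_seed(cfg.seed, s, algo)
            rng = np.random.default_rng(seed)
            try:
                row, maps, seq = _analyze_cell(rec, X_peaks, algo, cfg, seed, rng)
            except Exception as exc:  # isolate the cell, keep going
                logger.warning("cell (subject=%d, algo=%s) failed: %s", s, algo, exc)
                errors.append(
                    {"subject": s, "algorithm": algo, "error": str(exc),
                     "traceback": traceback.format_exc()}
                )
                continue
            row["subject"] = s
            row["seed"] = seed
            rows.append(row)
            maps_store[(s, algo)] = maps
            labels_store[(s, algo)] = seq
            subject_maps[algo] = maps
        if len(subject_maps) == len(cfg.algorithms) and len(cfg.algorithms) > 1:
            table = cmp.cmax_table(subject_maps)
            cmax_sum = table.to_numpy() if cmax_sum is None else cmax_sum + table.to_numpy()
            cmax_n += 1

    cells = pd.DataFrame(rows)
    cmax = None
    if cmax_n:
        cmax = pd.DataFrame(
            cmax_sum / cmax_n, index=cfg.algorithms, columns=cfg.algorithms
        )
    return AnalysisReport(
        cells=cells, maps=maps_store, labels=labels_store,
        cmax=cmax, errors=errors, config=cfg,
    )


def write_report(report: AnalysisReport, outdir: str | Path) -> list[Path]:
    """Write TSV summary tables and JSON artifacts; returns written paths.

    Emits the across-algorithm similarity table, the static and dynamic
    summary tables (mean +/- SD and SEM per algorithm), the per-block
    stationarity rejection proportions (Bonferroni over subjects), Hurst
    estimates, the full per-cell table, and a JSON run log with seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    cells = report.cells
    cfg = report.config

    def _save(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", float_format="%.6g")
        written.append(p)

    _save(cells.set_index(["subject", "algorithm"]) if len(cells) else cells,
          "cells.tsv")
    if report.cmax is not None:
        _save(report.cmax, "table1_cmax.tsv")

    if len(cells):
        static = ["rho_max", "gev", "entropy"]
        dynamic = ["mixing_time", "entropy_rate", "aif_first_peak_ms"]
        for name, quants in (("table2_static.tsv", static), ("table3_dynamic.tsv", dynamic)):
            agg = cells.groupby("algorithm")[quants].agg(["mean", "std", "sem"])
            _save(agg, name)
        n_subj = cells["subject"].nunique()
        bonf = (cfg.bonferroni if cfg and cfg.bonferroni else n_subj) or 1
        blocks = [c for c in cells.columns if c.startswith("stationarity_p_L")]
        if blocks:
            rej = cells.groupby("algorithm")[blocks].agg(
                lambda p: float(np.mean(np.minimum(p * bonf, 1.0) < 0.05))
            )
            rej.columns = [c.replace("stationarity_p_", "") for c in rej.columns]
            _save(rej, "table4_stationarity.tsv")
        hcols = [c for c in ("H_av", "H_dfa", "H_dwt") if c in cells.columns]
        if hcols:
            _save(cells.groupby("algorithm")[hcols].mean(), "table5_hurst.tsv")

    log = {
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in (asdict(cfg) if cfg else {}).items()
            if k != "recordings"
        },
        "errors": report.errors,
        "numpy_version": np.__version__,
    }
    p = outdir / "run_log.json"
    p.write_text(json.dumps(log, indent=2, default=str))
    written.append(p)
    return written
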