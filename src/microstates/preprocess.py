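"""EEG loading and preprocessing.

The analysis chain expects multichannel scalp EEG as a time-major voltage
matrix.  Preprocessing follows the standard resting-state microstate recipe:
band-pass filter (zero-phase Butterworth), decimate to the analysis rate,
re-reference to the common average, then compute the global field power
(GFP) and extract its local maxima.  Only the topographies at GFP maxima —
moments of maximal topographic signal-to-noise — are handed to the
clustering algorithms.

Conventions
-----------
Data are stored as ``(n_t, n_ch)`` float arrays (rows = time samples,
columns = channels), 0-based indices throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "GFPSeries",
    "bandpass_filter",
    "resample",
    "average_reference",
    "compute_gfp",
    "find_gfp_peaks",
    "gfp_peak_maps",
    "read_edf",
    "write_edf",
    "read_matrix",
    "write_matrix",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """A multichannel EEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_t, n_ch)
        Voltage samples in microvolts, time-major.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        One label per channel; generated as ``ch00, ch01, ...`` if omitted.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be a 2-D (time x channel) array")
        n_t, n_ch = self.data.shape
        if n_t < 2 or n_ch < 2:
            raise ValueError(
                f"need at least 2 samples and 2 channels, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{j:02d}" for j in range(n_ch)]
        elif len(self.channel_names) != n_ch:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_t(self) -> int:
        return self.data.shape[0]

    @property
    def n_ch(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n_t / self.fs

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.fs, list(self.channel_names))


@dataclass
class GFPSeries:
    """Global field power trace with (optionally) its local maxima.

    ``sigma`` is the spatial standard deviation of the topography at each
    sample; ``peak_indices`` are the interior local maxima found by the
    sign-change rule, and ``n_max`` their count.
    """

    sigma: np.ndarray
    fs: float
    peak_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 1:
            raise ValueError("GFP must be a 1-D series")
        if np.any(self.sigma < 0):
            raise ValueError("GFP is non-negative by construction")

    @property
    def n_max(self) -> int:
        if self.peak_indices is None:
            raise ValueError("peaks not computed yet; call find_gfp_peaks")
        return len(self.peak_indices)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def bandpass_filter(
    rec: EEGRecording, low: float = 1.0, high: float = 30.0, order: int = 6
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    The filter is applied forward and backward (``filtfilt``), so the phase
    response is exactly zero and the effective magnitude response is the
    square of the order-``order`` design.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < {low} < {high} < Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=0)
    return EEGRecording(out, rec.fs, list(rec.channel_names))


def resample(rec: EEGRecording, target_fs: float = 250.0) -> EEGRecording:
    """Decimate to ``target_fs`` by keeping every k-th sample.

    The ratio ``fs / target_fs`` must be a (near-)exact integer; rational
    resampling is out of contract.  The caller is responsible for having
    low-passed the signal below ``target_fs / 2`` beforehand.
    """
    ratio = rec.fs / target_fs
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError(
            f"fs ({rec.fs} Hz) must be an integer multiple of target_fs "
            f"({target_fs} Hz); got ratio {ratio}"
        )
    if k == 1:
        return rec.copy()
    return EEGRecording(rec.data[::k].copy(), target_fs, list(rec.channel_names))


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous channel mean from every time sample.

    After this step every row of the data matrix sums to zero, which is the
    reference frame in which spatial correlations and GFP are defined.
    """
    out = rec.data - rec.data.mean(axis=1, keepdims=True)
    return EEGRecording(out, rec.fs, list(rec.channel_names))


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """Global field power: sigma_i = sqrt( sum_j X_ij^2 / (n_ch - 1) ).

    Assumes average-referenced input (the formula is the spatial standard
    deviation only when the channel mean is zero).
    """
    sigma = np.sqrt(np.sum(rec.data**2, axis=1) / (rec.n_ch - 1))
    return GFPSeries(sigma, rec.fs)


def find_gfp_peaks(gfp: GFPSeries) -> GFPSeries:
    """Locate local GFP maxima with the discrete sign-change rule.

    With the forward difference ``delta_i = sigma_{i+1} - sigma_i``, sample
    ``i`` is a peak when ``sgn(delta_i) - sgn(delta_{i-1}) == -2``.  Peaks
    can therefore only occur at interior samples, and an exactly flat
    plateau is never detected (the sign sequence +1, 0, ..., 0, -1 contains
    no -2 jump) — irrelevant in practice for continuous-valued GFP.
    """
    sigma = gfp.sigma
    if len(sigma) < 3:
        raise ValueError("need at least 3 samples to detect peaks")
    delta = np.diff(sigma)  # delta[i] = sigma[i+1] - sigma[i]
    sgn = np.sign(delta)
    # peak at i (1..n-2) when sgn(delta_i) - sgn(delta_{i-1}) == -2
    peaks = np.where(sgn[1:] - sgn[:-1] == -2)[0] + 1
    return GFPSeries(sigma, gfp.fs, peak_indices=peaks.astype(int))


def gfp_peak_maps(rec: EEGRecording) -> tuple[np.ndarray, GFPSeries]:
    """Convenience: GFP + peak detection, returning the peak topographies.

    Returns the ``(n_max, n_ch)`` matrix of EEG topographies at local GFP
    maxima (the clustering input) together with the peak-filled GFP series.
    """
    gfp = find_gfp_peaks(compute_gfp(rec))
    return rec.data[gfp.peak_indices], gfp


def preprocess(
    rec: EEGRecording,
    low: float = 1.0,
    high: float = 30.0,
    order: int = 6,
    target_fs: float = 250.0,
) -> EEGRecording:
    """Full chain: band-pass -> decimate -> average reference."""
    out = bandpass_filter(rec, low=low, high=high, order=order)
    out = resample(out, target_fs=target_fs)
    return average_reference(out)


# ---------------------------------------------------------------------------
# I/O: delimited text matrix with JSON sidecar, and 16-bit EDF
# ---------------------------------------------------------------------------

def write_matrix(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as TSV (time-major) plus a ``.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t")
    meta = {"fs": rec.fs, "channel_names": rec.channel_names}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_matrix(path: str | Path) -> EEGRecording:
    """Read a TSV matrix written by :func:`write_matrix`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EEGRecording(data, float(meta["fs"]), list(meta["channel_names"]))


# EDF: fixed-layout ASCII header (256 bytes + 256 per signal) followed by
# data records of int16 little-endian samples.  Only the continuous,
# equal-rate standard dialect is supported.

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path, record_duration: float = 1.0) -> None:
    """Write a recording as standard 16-bit EDF (one data record per second).

    Physical scaling maps the observed amplitude range onto the full int16
    range; samples are quantized accordingly (EDF is a 16-bit format).
    """
    path = Path(path)
    ns = rec.n_ch
    spr = int(round(rec.fs * record_duration))  # samples per record per signal
    if abs(spr - rec.fs * record_duration) > 1e-9 or spr < 1:
        raise ValueError("fs * record_duration must be a positive integer")
    n_rec = rec.n_t // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one data record")
    data = rec.data[: n_rec * spr]

    pmin = float(np.min(data))
    pmax = float(np.max(data))
    if pmax <= pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin) * scale + dmin).astype("<i2")

    hdr = b""
    hdr += _edf_field("0", 8)                      # version
    hdr += _edf_field("X X X X", 80)               # patient id
    hdr += _edf_field("Startdate X", 80)           # recording id
    hdr += _edf_field("01.01.00", 8)               # start date
    hdr += _edf_field("00.00.00", 8)               # start time
    hdr += _edf_field(str(256 * (ns + 1)), 8)      # header bytes
    hdr += _edf_field("", 44)                      # reserved
    hdr += _edf_field(str(n_rec), 8)               # number of records
    hdr += _edf_field(f"{record_duration:g}", 8)   # record duration (s)
    hdr += _edf_field(str(ns), 4)                  # number of signals

    def sig(field_val: str, width: int) -> bytes:
        return b"".join(_edf_field(field_val, width) for _ in range(ns))

    hdr += b"".join(_edf_field(nm, 16) for nm in rec.channel_names)  # labels
    hdr += sig("", 80)                              # transducer
    hdr += sig("uV", 8)                             # physical dimension
    hdr += b"".join(_edf_field(f"{pmin:.6g}"[:8], 8) for _ in range(ns))
    hdr += b"".join(_edf_field(f"{pmax:.6g}"[:8], 8) for _ in range(ns))
    hdr += sig(str(dmin), 8)
    hdr += sig(str(dmax), 8)
    hdr += sig("", 80)                              # prefiltering
    hdr += sig(str(spr), 8)                         # samples per record
    hdr += sig("", 32)                              # reserved

    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            block = digital[r * spr : (r + 1) * spr]  # (spr, ns)
            f.write(block.T.tobytes())                # signal-major per record


def read_edf(path: str | Path) -> EEGRecording:
    """Read a continuous 16-bit EDF file (standard dialect, equal rates)."""
    with open(Path(path), "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF header")
        n_rec = int(head[236:244].decode("ascii").strip())
        rec_dur = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        sig_hdr = f.read(256 * ns)

        def col(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_hdr[base + k * width : base + (k + 1) * width].decode("ascii").strip()
                for k in range(ns)
            ]

        labels = col(0, 16)
        pmin = np.array([float(v) for v in col(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in col(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in col(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in col(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in col(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("mixed sampling rates are not supported")
        spr0 = spr[0]
        raw = np.frombuffer(f.read(n_rec * ns * spr0 * 2), dtype="<i2")

    raw = raw.reshape(n_rec, ns, spr0)                # record, signal, sample
    digital = raw.transpose(0, 2, 1).reshape(n_rec * spr0, ns).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin) * gain + pmin
    return EEGRecording(data, spr0 / rec_dur, labels)
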