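"""Shared fixtures: small synthetic recordings and canonical toy inputs."""

import numpy as np
import pytest

import microstates as ms


@pytest.fixture(scope="session")
def default_recording():
    """One default-spec synthetic subject (120 s, 250 Hz, 30 ch, 4 states)."""
    spec = ms.SyntheticSpec(seed=7)
    rec, truth = ms.generate_alpha_eeg(spec)
    return rec, truth


@pytest.fixture(scope="session")
def default_peaks(default_recording):
    rec, _ = default_recording
    X_peaks, gfp = ms.gfp_peak_maps(rec)
    return X_peaks, gfp


@pytest.fixture(scope="session")
def orthogonal_family_data():
    """Noise-free topographies drawn from 4 orthogonal maps, heavy-tailed
    amplitudes (so ICA is identifiable), average-referenced."""
    rng = np.random.default_rng(42)
    maps = ms.make_topographies(4, 12, rng)
    n = 600
    labels = rng.integers(0, 4, n)
    amp = rng.laplace(0, 1.0, n) + np.sign(rng.standard_normal(n)) * 0.5
    X = amp[:, None] * maps[labels]
    return X, maps, labels


@pytest.fixture(scope="session")
def backfit_sequence(default_recording):
    """K-means microstate label sequence of the default synthetic subject."""
    rec, _ = default_recording
    X_peaks, _ = ms.gfp_peak_maps(rec)
    maps = ms.cluster_kmeans(X_peaks, M=4, n_runs=5, seed=3, X_full=rec.data)
    fit = ms.backfit(maps, rec)
    return ms.LabelSequence(fit.labels, 4, rec.fs)
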