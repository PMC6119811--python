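# microstates

Resting-state EEG alternates among a handful of quasi-stable scalp potential
topographies — *microstates*.  Segmenting a recording into a microstate
sequence turns multichannel voltage data into a symbolic time series whose
statistics (entropy, entropy rate, transition-matrix spectra, lagged mutual
information, Hurst exponents) characterize the temporal organization of
large-scale brain activity.  A long-standing practical question is whether
those statistics depend on which clustering algorithm produced the maps.
This package implements the full comparison pipeline so the question can be
studied quantitatively — and, because real recordings of this kind are
rarely shareable, ships a synthetic-EEG generator with known ground truth
so every stage is verifiable.

It is intended for computational neuroscientists and methods developers who
work with EEG microstate analysis or, more generally, with symbolic
dynamics of neural time series.

## What it computes

**Maps.**  EEG topographies at local maxima of the global field power
(GFP), `σ_i = sqrt(Σ_j X_ij² / (n_ch − 1))`, are clustered into `M` maps
`A_l` (unit-norm, zero-mean rows) by any of five interchangeable
algorithms: AAHC (atomize-and-agglomerate hierarchical clustering),
modified K-means (cluster update = principal eigenvector of the member
scatter `S_l = Σ_{i:L_i=l} x_iᵀx_i`, hence polarity-blind), K-medoids under
the dissimilarity `1 − corr²`, PCA (eigenvectors of the data covariance),
and FastICA (rows of the unmixing matrix).

**Sequences.**  Competitive back-fitting assigns every sample the map of
maximal squared spatial correlation, `L_i = argmax_l (Σ_j X_ij A_lj)²`
("winner takes all"; squaring discards polarity).  Fit quality is the
global explained variance `GEV = Σ_i σ_i² C²_{i,L_i} / Σ_i σ_i²` and the
cross-validation criterion `CV = σ̂_L² ((n_ch−1)/(n_ch−1−M))²` used to pick
the best of several stochastic restarts.

**Statistics.**  *Static:* max intra-set map correlation ρ_max, GEV,
Shannon entropy `h = −Σ p_i log p_i`.  *Dynamic:* mixing time
`τ = 1/(1 − |λ₁|)` of the transition matrix, entropy rate as the OLS slope
of joint entropy `h_n` vs history length `n` (history calibrated against
first-order Markov surrogates), and the first peak of the autoinformation
function `I(k) = H(X_{t+k}) − H(X_{t+k}|X_t)`.  Plus likelihood-ratio (G)
tests of the Markov property (orders 0–2) and of transition-matrix
stationarity, and Hurst exponents (aggregated variance, DFA, wavelet
log-scale diagram) of ±1 random-walk embeddings of the label sequence.

## Worked example

```python
import microstates as ms

spec = ms.SyntheticSpec(seed=42)           # 120 s, 250 Hz, 30 ch, 4 states
rec, truth = ms.generate_alpha_eeg(spec)
X_peaks, gfp = ms.gfp_peak_maps(rec)
maps = ms.cluster_kmeans(X_peaks, M=4, n_runs=10, seed=0, X_full=rec.data)
fit = ms.backfit(maps, rec)
_, gev = ms.gev(fit, ms.compute_gfp(rec))
seq = ms.LabelSequence(fit.labels, 4, rec.fs)
tm = ms.transition_matrix(seq)
```

prints, with the quantities filled in:

```
GFP peaks: 8973
map recovery |rho|: [1. 1. 1. 1.]
GEV = 0.372
entropy = 1.385 nats (max 1.386)
mixing time = 2.58 samples
entropy rate = 0.799 nats/step
first AIF peak = 44.0 ms
```

Reading: the four planted topographies are recovered essentially exactly
(|ρ| = 1 per true map); the maps explain 37% of GFP-weighted variance at
this noise level; the label distribution is near-uniform (entropy ≈ log 4);
the sequence decorrelates in ~2.6 samples; and the autoinformation function
peaks near half the ~10 Hz alpha period — the *frequency doubling*
signature, since polarity-blind maps recur twice per oscillation cycle.

The same analysis for a whole cohort and all five algorithms:

```bash
microstates all --subjects 20 --seed 1 --out report/
```

writes per-cell results (`cells.tsv`), the across-algorithm map-similarity
table, static/dynamic summary tables, stationarity rejection proportions,
and Hurst estimates.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the GFP-maximum count of a noise-free 200 s
recording with an exactly 10 Hz topography (two maxima per cycle); the
maximum pairwise correlation among PCA maps of a synthetic recording; the
20-subject mean location of the first autoinformation peak under modified
K-means; and the mean relative error of the entropy-rate estimate at
history length 8 against the closed-form Markov-chain rate on length-30,000
surrogates.

See `docs/methods.md` for the model, estimator and test details.
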