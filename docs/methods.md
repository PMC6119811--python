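# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic generator does and does not emulate, and the
known limitations.  Conventions: data are time-major `(n_t, n_ch)` arrays,
average-referenced (each row sums to zero); maps are unit-norm, zero-mean
row vectors; entropies are in nats; indices are 0-based.

## 1. Preprocessing

Band-pass: order-6 Butterworth applied forward–backward (`sosfiltfilt`),
so the phase response is exactly zero and the effective magnitude response
is the *square* of the order-6 design.  The design choice follows the
common "zero-phase sixth order" recipe, which leaves this squaring
ambiguity open; we accept the squared response.  (A 6th-order Butterworth
has a 36 dB/octave asymptote; descriptions quoting 24 dB/octave for such a
filter are internally inconsistent — we implement order 6.)

Resampling is plain decimation (every k-th sample) and requires an integer
rate ratio; the caller must have low-passed below the target Nyquist
(the default 1–30 Hz band at a 250 Hz target satisfies this).  Rational
resampling is deliberately out of contract.

GFP is `σ_i = sqrt(Σ_j X_ij²/(n_ch−1))`; local maxima are found by the
discrete sign-change rule on `δ_i = σ_{i+1} − σ_i`: sample *i* is a peak
iff `sgn(δ_i) − sgn(δ_{i−1}) = −2`.  Consequences we keep deliberately:
peaks cannot occur at the first or last sample, and an exactly flat
plateau is never detected (the sign sequence `+1, 0, …, 0, −1` contains no
−2 jump).  Both are measure-zero events for continuous-valued GFP.

I/O: TSV matrices with a JSON sidecar (`fs`, channel names), and a minimal
reader/writer for continuous 16-bit EDF (standard dialect, equal sampling
rates).  EDF quantizes to 16 bits over the observed amplitude range;
round-trips are exact to one quantization step.

## 2. Clustering

All five algorithms consume the `(n_max, n_ch)` matrix of GFP-peak
topographies and return `M` unit-norm zero-mean maps.  Shared numerical
conventions: argmax ties break toward the lowest map index; map polarity
is meaningless downstream (assignment uses squared correlation), and each
algorithm's output rows are projected onto the zero-mean subspace and
renormalized.

* **Modified K-means** — stochastic; per run, alternate winner-takes-all
  assignment with the polarity-blind map update (principal eigenvector of
  the member outer-product sum); converged when the relative change of the
  residual variance `σ_L²` drops below `tol` (default 1e-6, cap 500
  iterations).  Empty clusters are re-seeded from a random peak, keeping
  `M` fixed.  Best of `n_runs = 10` restarts by the CV criterion,
  evaluated on the *entire* recording (all time samples), not just peaks.
* **AAHC** — deterministic bottom-up: one cluster per peak initially; each
  iteration removes the cluster with the lowest GEV (computed with the
  peak-set GFP), re-assigns its members by maximal squared correlation,
  and updates receiving clusters' maps as the principal eigenvector of
  their member scatter (the polarity-invariant mean — the update is not
  specified by the classical description; we use the same operator as the
  K-means step for consistency).  Membership is tracked incrementally
  rather than re-derived by global back-fitting each iteration; this is
  what keeps the cost ~quadratic in the initial cluster count.  The
  pipeline subsamples peak sets above 2,000 for AAHC to stay desk-scale.
* **K-medoids** — as K-means but each representative is an actual input
  topography: the member minimizing total dissimilarity `1 − corr²` to its
  co-members.  Best of 10 restarts by CV (the CV selection rule is stated
  for K-means in the classical literature; we apply it to K-medoids too so
  restart selection is uniform).
* **PCA** — top-`M` eigenvectors of `Q = X̃ᵀX̃/(n_max−1)` via `eigh`
  (uncentered, as defined; average-referenced data have ~zero column means
  anyway).  Deterministic up to sign; we fix signs by making the
  largest-magnitude entry positive.  Because average-referenced data are
  confined to the zero-mean subspace, the leading eigenvectors are
  themselves zero-mean and mutually orthogonal — so the intra-set ρ_max of
  PCA maps is *exactly* zero, a structural property, not an empirical one.
* **FastICA** — scikit-learn's parallel (symmetric) FastICA with
  pre-whitening to `M` components and the exponential contrast
  `g(u) = u·exp(−u²/2)`; maps are the rows of the unmixing matrix.
  Component count equals `M` via whitening-dimension reduction.

Back-fitting uses the squared covariance `C_il² = (Σ_j X_ij A_lj)²` for
assignment.  For GEV we normalize the winner's `C²` by the data vector's
own power (`σ_i²(n_ch−1)` for unit-norm maps), i.e. use the squared
spatial *correlation*; this makes GEV a true explained-variance fraction
bounded by 1 while leaving the argmax labeling untouched.

## 3. Sequence statistics

Joint entropies `h_n` are plug-in (maximum-likelihood) estimates over all
*overlapping* n-grams.  The entropy rate is the OLS slope of `(n, h_n)`
for `n = 1…n̂`; the fit includes `n = 1` (the lower end is a free choice;
including it makes the deterministic-cycle rate exactly zero).  The usable
history length `n̂` is calibrated per cohort: for each sequence a
same-length first-order Markov surrogate (empirical π and T) is
synthesized, the slope estimate is compared with the closed-form rate
`h′_MC = −Σ_i π_i Σ_j T_ij log T_ij`, and `n̂` is the largest `n` with
mean relative error < 0.05.  For 4-symbol sequences of ~30,000 samples in
the realistic entropy-rate regime (~1 nat/step) this lands at `n̂ = 8`,
which is the package default.  Plug-in estimates are biased low when
`M^n` approaches the sample count; an undersampling warning fires below
`10·M^n_max` samples.  No Miller–Madow/NSB-style corrections are applied
(out of scope).

The transition matrix is the row-normalized bigram count; rows of
never-visited symbols are replaced by the empirical symbol distribution
and flagged.  The eigenvalues are sorted by modulus; λ₁ is the
second-largest *modulus* (T need not be reversible, so complex pairs
occur; the modulus is the standard convergence-rate choice), the spectral
gap is `1 − |λ₁|` and the mixing time its reciprocal, flagged infinite for
periodic/reducible chains (|λ₁| = 1).

The autoinformation function is the plug-in lagged mutual information with
marginals taken from the empirical joint of `(X_t, X_{t+k})`, so
`I(k) ≥ 0` and `I(0)` equals the Shannon entropy identically.  The first
AIF peak is searched at lags strictly greater than 8 samples (32 ms at
250 Hz) after a centered size-3 moving average, with the same sign-change
rule as for GFP peaks; absence of a local maximum returns an explicit
missing value, never an error.  Note a structural bias of this detector:
when the periodic bump rides on a decaying baseline, smoothing plus the
sign rule shift the detection ~1 sample toward zero.  On the synthetic
cohort this places the mean first peak at ≈45–47 ms for a ~10 Hz carrier
(ideal: half-period ≈ 50 ms).

Markov-order and stationarity tests are likelihood-ratio G statistics with
asymptotic χ² nulls.  Order 0: `G = 2Σ_ij n_ij log(n_ij n/(n_i· n_·j))`,
df `(M−1)²`; order 1 on trigram counts with expected
`n_ij· n_·jk / n_·j·`, df `M(M−1)²`; order 2 the analogous tetragram form,
df `M²(M−1)²`.  Stationarity: the sequence is cut into `r = ⌊n/L⌋` blocks
and block transition counts are tested against the pooled matrix, df
`(r−1)M(M−1)`.  Zero-count cells contribute zero; df are not reduced for
structurally empty cells; a warning fires when expected counts drop below
1 (the order-2 test is anticonservative in that regime).  Simulated
type-I rates at α = 0.01 (500 replicates, n = 5000): order 0 ≈ 0.012,
order 1 ≈ 0.010, stationarity ≈ 0.002 (conservative).  Bonferroni
correction multiplies p by the number of subjects (default: cohort size).

All sequence statistics are invariant under relabeling permutations of
the symbols (checked by property tests).

## 4. Hurst exponents

Symbolic sequences are embedded as random walks: each *balanced
bipartition* of the alphabet maps labels to ±1 and the increments are
cumulatively summed; for `M = 4` there are three bipartitions
({01|23}, {02|13}, {03|12}) and the reported `H` is the mean over them.
The embedding construction is our interpretation of the symbolic-walk
approach used in the microstate literature, which is inherited from prior
work without a canonical restatement; the balanced choice avoids
degenerate (nearly constant) increments for near-uniform label
distributions.

* **Aggregated variance** — variance of block means (ddof = 1; the naive
  estimator's `1 − 1/k` bias tilts the log-log slope) at log-spaced block
  sizes from 2 to n/16; `H = 1 + β/2`.
* **DFA, order 1** — integrate, linearly detrend windows of log-spaced
  sizes 8 … n/8 (10 scales per decade), RMS fluctuation; `H` = log-log
  slope.
* **Wavelet (log-scale diagram)** — Daubechies-2 pyramid DWT with
  periodic extension (implemented in-package; no wavelet library is
  assumed); per octave `j ≥ 3` up to `⌊log₂ n⌋ − 3`, regress
  `log₂ mean(d_j²)` on `j` with weights proportional to the coefficient
  count; `H = (γ + 1)/2`.

On exact fractional Gaussian noise of length 2¹⁴ all three agree with the
nominal `H ∈ {0.5, 0.6, 0.7}` within ±0.05–0.1 and with each other within
0.1.  Sign-clipping a Gaussian series (as the ±1 embedding does) is a
Hermite-rank-1 transform: it preserves `H` asymptotically but weakens
short-lag correlations, biasing finite-sample estimates down by ~0.03–0.05
at this length.  All estimates are invariant to a global sign flip of the
increments.  Constant increments (a frozen sequence) are rejected as
degenerate rather than returning a spurious exponent.  As usual,
non-stationarity can masquerade as long-range dependence; the estimators
make no attempt to be robust to it.

## 5. Synthetic data

The generator emulates the features of wakeful-rest EEG that the analysis
chain relies on:

```
X(t) = a(t) · sin(2π f t + φ) · m_{ℓ(t)} + ε(t),   then average-referenced
```

* `m_0 … m_{M−1}`: random Gaussian channel vectors, mean-removed,
  Gram-Schmidt-orthogonalized, unit-normalized — maximally distinct,
  recoverable topographies.
* `ℓ(t)`: first-order Markov chain with uniform stationary distribution
  and geometric dwell; default mean dwell 100 ms (diagonal 0.96 at
  250 Hz).
* `f`: per-subject dominant frequency, uniform in `alpha_freq ± 1 Hz`
  clipped to `alpha_band` (defaults: 10 Hz, 8–12 Hz).  The carrier phase
  is continuous across label switches — switching the phase per dwell
  segment would create artificial GFP discontinuities.
* `a(t)`: rectified ~1 Hz sinusoid plus an offset of 0.5 (alpha
  "spindling"); a constant-envelope, fixed-phase variant exists for
  analytic edge cases (e.g. the exact two-peaks-per-cycle count).
* `ε(t)`: white Gaussian sensor noise, scaled so the source-to-noise power
  ratio is `snr` (default 0.5 — the oscillatory source carries about a
  third of the broadband power, a realistic figure for eyes-closed rest).

Defaults (120 s, 250 Hz, 30 channels, M = 4, seeded) are chosen once so
the stated phenomenology emerges and are not tuned per experiment: the
GFP attains two maxima per alpha cycle; back-fitted sequences inherit the
~50 ms (half-period) autoinformation periodicity, because labels are
reliable near GFP maxima and scatter near the oscillation's zero
crossings — polarity-blind maps recur twice per cycle (*frequency
doubling*).  At `snr ≥ 1` the scattering is too weak for the AIF bump to
form a detectable local maximum; 0.5 expresses it robustly.

What the generator does **not** emulate: volume-conduction lead fields or
cortical source geometry, 1/f background spectra, non-alpha rhythms,
artifacts (blinks, movement), inter-channel noise correlations, or
non-stationary dwell statistics.  A green test on synthetic data therefore
establishes the correctness of the estimators and the pipeline plumbing —
not neurobiological claims about real EEG.  Two quantitative consequences
to keep in mind: GEV on default synthetic data (~0.37 at snr 0.5) is lower
than typical resting-state reports (~0.6), and the mean first AIF peak
sits ~3–5 ms left of the ideal 50 ms (detector bias, §3).

Fractional Gaussian noise uses exact circulant-embedding synthesis
(Davies–Harte): the embedding eigenvalues are computed by FFT, the
embedding is enlarged until they are non-negative, and the output's
autocovariance matches `γ(k) = (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})/2`
to numerical precision.

## 6. Pipeline

One analysis *cell* is (subject, algorithm).  Cells are independent; a
failure is logged and recorded in the report without aborting the run.
Per-cell seeds are derived deterministically from the master seed, so
reruns are bit-identical and subject-level parallelism would preserve
determinism.  Report tables: across-algorithm map-similarity (C^max),
static and dynamic summaries (mean, SD, SEM per algorithm), stationarity
rejection proportions per block length (Bonferroni over subjects at
α = 0.05), and Hurst means.  Group comparisons use a classical one-way
ANOVA across algorithms with pairwise Welch (unequal-variance) t-tests;
both the SD and the SEM are emitted, explicitly labeled, since summary
tables in the literature mix the two conventions.

## 7. Known limitations

* Plug-in entropy estimators are biased low near undersampling; the
  surrogate calibration bounds, but does not remove, this bias.
* The AIF first-peak detector inherits the smoothing/sign-rule left bias
  described above (~1 sample on decaying baselines).
* The order-2 Markov test's χ² null is anticonservative for short
  sequences (expected counts < 1).
* AAHC is O(n²) in the initial peak count; the pipeline's 2,000-peak
  subsampling cap trades a little stability for tractability.
* EDF support covers the continuous 16-bit standard dialect only (no
  EDF+ annotations, no per-signal rates).
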