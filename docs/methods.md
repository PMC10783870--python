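# Methods

## The convolution model

All estimation assumes the measured response is a linear, additive,
time-invariant function of stimulus-derived predictor time series:

    y_t = Σ_i Σ_{τ ∈ [τmin, τmax)} h_{i,τ} x_{i,t−τ} + ε_t

on a shared uniform time axis (default analysis rate 100 Hz). The lag
window is half-open and sampled on the response grid, so a window of
(0, 0.5) s at 100 Hz contains exactly 50 lags (0 … 0.49 s). Samples
where `t − τ` precedes the recording are treated as zero (the
simulator uses the identical convention, so estimators can recover
generating kernels exactly in the noiseless case). Forward (encoding)
models predict each response channel from the predictors
independently — a mass-univariate contract; backward (decoding) models
swap the roles, reconstructing a single stimulus feature from all
response channels jointly with a negative lag window.

## Boosting

Per channel and per data partition ("run"):

1. All inputs are centered per component and scaled by the standard
   deviation (ℓ2 error) or the mean absolute deviation (ℓ1). Centering
   removes the intercept, which matters because the estimator prefers
   exact-zero coefficients. Kernels are reported in original units via
   `h_orig = h_norm · scale_y / scale_x`.
2. The kernel starts at zero. Each iteration evaluates, over every
   (predictor, lag) coordinate and both signs, the training error of a
   `±δ` step and takes the best strictly-improving one. Ties resolve
   deterministically: lowest predictor index, then earliest lag, then
   positive sign.
3. If no step improves the training error, δ is halved; when δ would
   fall below `mindelta` the run stops.
4. After each accepted step the validation-segment error is checked:
   two consecutive increases stop the run (early stopping). The kernel
   returned for the run is the one with the lowest validation error
   seen, including the initial zero kernel.
5. With `selective_stopping = s`, a validation increase is charged to
   the predictor that was stepped; a predictor charged `s` consecutive
   times is frozen (its coordinates leave the candidate set) and
   training continues until all predictors are frozen.

Defaults: δ = 0.005 in normalized units, `mindelta = δ/8`, ℓ2 error,
k = 10 partitions without a test set, k = 5 with one. These are
exposed in `BoostConfig` and recorded in every `FitResult`.

For the ℓ2 norm the candidate search is incremental: with residual `r`
and (basis-smeared) design rows `B_j`, the step errors follow in
closed form from `c_j = B_j·r`, and accepting a step updates `c`
through one column of the Gram matrix `B Bᵀ` — per-candidate cost is
O(1) after setup, with a periodic exact recomputation (every 256
steps) to cap floating-point drift. The ℓ1 norm has no such closed
form; candidate errors are evaluated directly (vectorized) on the
training samples, which is why the ℓ1 studies in the test suite use
single-predictor designs.

### Basis windows

With `basis > 0`, each step adds `±δ` times a unit-sum window (default
Hamming; any scipy window family) of the given width centered at the
chosen lag and truncated at the kernel edges, both during candidate
evaluation and in the returned kernel. Unit-sum normalization keeps
the meaning of δ (mass added per step) constant across widths. The
window length is `round(basis / tstep)` samples — 5 samples for 50 ms
at 100 Hz.

### Partitions, cross-validation, metrics

The time axis is split into k contiguous equal-length segments. With a
test set, run j uses segment j as test and segment j+1 (mod k) as
validation; every segment is the test set exactly once, so the
concatenated test predictions cover the entire series and yield
unbiased predictive power. Without a test set, runs rotate only the
validation segment. The reported kernel is the average of the k runs'
kernels (per-run kernels are retained for diagnostics). Predictive
power is `1 − E(y − ŷ)/E(y − mean(y))` with E the sum of squares (ℓ2)
or of absolute values (ℓ1); it can be negative. The denominator
convention (residual about the mean) is a package decision; the
quantity is evaluated on normalized-scale data, where it is invariant
to the normalization. Model comparisons re-estimate kernels for each
predictor set on identical partitions and report the per-channel
difference in held-out power.

### Ridge reference

`ridge_mtrf` solves `(X Xᵀ + λI) h = X y` on the same lagged,
zero-padded design. λ = 0 is solved as plain least squares via QR/SVD
(conditioning guard at 1e10) so the noiseless oracle recovers
generating kernels to machine precision; a λ grid is resolved by
k-fold cross-validated predictive power and refit on all data. Ridge
is deliberately left un-normalized by default (the closed form needs
no scaling and raw units keep the noiseless recovery exact);
`scale_data=True` reproduces the boosting preprocessing.

## Predictors

- **Gammatone spectrogram**: 4th-order gammatone IIR filters
  (`scipy.signal.gammatone`) on ERB-rate-spaced centers, default 256
  filters in 20–5000 Hz; per-band envelope = analytic (Hilbert)
  magnitude averaged in non-overlapping 1 ms frames, then typically
  binned to 8 bands (near-equal contiguous groups, geometric-mean
  centers; per-sample total power is conserved exactly) and resampled
  to the analysis rate.
- **Scales**: linear, power-law (default exponent 1/3) and log
  (20·log10 relative to the spectrogram maximum, floored at −50 dB and
  shifted so the floor maps to 0). The conventional auditory defaults
  are package choices; both parameters are exposed. When an envelope
  is requested together with a scale, the scale is applied after
  summation (configurable).
- **Onsets**: per-band, non-negative edge signals.
  `rectified_difference` (default, 30 ms span) is
  `max(0, x_t − min of the preceding span)` — the standard half-wave
  rectified-derivative-style approximation. `delayed_inhibition`
  subtracts an exponentially decaying maximum of the recent past
  (weight 1 at the nearest past sample so constant input stays
  silent); it is an approximation inspired by neural edge-detection
  models, not a reimplementation of any published one.
- **Events**: impulses at the nearest sample to each event (ties
  toward the earlier sample; coincident events sum), with magnitude 1
  or the event's value (e.g. surprisal); boxcar steps from paired
  onset/offset rows. Linguistic quantities are consumed from event
  tables, never computed here.

## Preprocessing

`bandpass_filter` uses a linear-phase windowed-sinc FIR applied with
centered alignment, i.e. exactly zero phase — latencies in TRFs are
interpretable. The filter order adapts to give ≥ 40 dB attenuation one
octave outside the band edges (capped by signal length). The filter
family/order is a package decision. `resample` applies an FFT low-pass
at 0.4× the target rate (a 2.5× guard band) followed by plain
decimation for integer ratios (polyphase otherwise). Resampling and
convolution do not commute in general (aliasing); this property is
deliberately not claimed or tested.

## The simulator

`simulate_dataset` mirrors the structure the estimator assumes:

- **Correlated bands**: `band_i = √ρ·z + √(1−ρ)·ε_i` with a shared
  latent AR(1) series z (coefficient 0.95) and band-specific pink
  noise ε, giving pairwise correlation ρ (default 0.8 — the
  "structured, highly correlated predictors" regime of adjacent
  spectrogram bands).
- **Ground truth**: `alternating_bands` puts smooth biphasic kernels
  of opposite sign on two adjacent middle bands, signs alternating
  across channels, all other bands exactly zero; `biphasic` and
  `damped_oscillation` cover single-predictor and oscillatory cases.
- **Noise**: pink (1/f power; white-noise spectrum shaped by 1/√f, DC
  zeroed, unit variance per channel) or white, scaled per channel so
  that `10·log10(var_signal/var_noise) = snr_db`. Default 0 dB.
- **Events design**: Poisson onsets (2/s) with log-normal magnitudes.
- `simulate_group` perturbs a shared kernel per subject with Gaussian
  noise of stated SD; all randomness derives deterministically from
  the master seed via `SeedSequence`.

What the simulator does **not** emulate: real EEG topographies and
volume conduction, artifacts (blinks, muscle), non-stationarity, and
nonlinear responses. Passing tests therefore demonstrate estimator
correctness and calibration under the model's own assumptions, not
performance on any particular real dataset.

### Study conditions used in the test suite

- Recovery/sparsity: 8 bands (2 active), ρ = 0.8, 2 channels, 0 dB
  pink noise, 60 s at 100 Hz, 20 seeds.
- Basis-window study: single predictor with a biphasic kernel at
  −10 dB — the weak-SNR envelope-TRF regime in which the smoothing
  benefit of a 50 ms Hamming basis is expressed; at 0 dB fits accept
  hundreds of steps and even impulse-basis kernels come out dense.
- ℓ1 robustness: same single-predictor design at 0 dB with 1% of
  response samples contaminated by 20-SD outliers.
- Null calibration: 100 independent white-noise response/predictor
  pairs, 30 s; and 200 null group datasets (12 subjects, 32 sensors on
  a 4×8 grid) for the cluster test.

These sizes keep the full suite within a few minutes while leaving
every comparison well-powered.

## Statistics

Paired (related-measures) t-tests with df = n−1 and two-tailed p.
Mass-univariate maps use an element-wise paired t, thresholded at the
two-tailed t critical value for α = 0.05 by default (the
cluster-forming threshold is a field-conventional package choice, not
part of the test's validity); suprathreshold elements are clustered by
sensor adjacency × temporal contiguity, separately per sign. The null
distribution of the maximum |cluster mass| is built from sign flips of
the subject difference maps: full enumeration when `2^n ≤
n_permutations` (default 10 000), otherwise Monte Carlo with
`p = (b+1)/(m+1)`. Sensor adjacency comes from an explicit neighbor
list or a coordinate/distance helper — no dependence on any montage
library. Degenerate elements (zero variance across subjects) get t = 0
rather than ±∞, so they can never seed clusters.

## Numerical notes and limitations

- Exact ties in the candidate search are resolved by index order, so
  results are platform-stable; all stochastic paths are pure functions
  of their seeds.
- The run-averaged kernel unions the supports of the k per-run
  kernels: on pure-noise data each run's kernel is almost entirely
  exact zeros (median per-run zero fraction ≈ 1), while the average
  retains the rare spurious coordinates of any run (zero fraction
  ≈ 0.8 at 50 lags, k = 10).
- Candidate steps are scored against the training segments only,
  matching the estimation procedure's own contract.
- The boosting amplitude is biased toward zero (early stopping shrinks
  peaks); ridge preserves amplitude better but produces dense
  estimates. Choose by the question: feature selection and
  interpretability favor boosting, amplitude fidelity favors ridge.
- No GPU path, no time-varying kernels, no source-space estimation,
  no artifact rejection; EEG vendor formats are out of scope (arrays,
  HDF5 containers, WAV and CSV/TSV only).
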