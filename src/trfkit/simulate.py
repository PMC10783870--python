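"""Synthetic data with the statistical structure the estimator assumes.

The generator mirrors the collinearity simulation design: a known
multivariate kernel drives two adjacent spectrogram-like bands (out of
several, the rest silent) with a spatiotemporally alternating pattern;
band envelopes are mutually correlated through a shared latent AR(1)
series; the convolved response is corrupted with additive pink noise at
a configurable SNR. Event-stream designs (Poisson onsets, log-normal
magnitudes) support discrete-predictor tests, and a group generator
supports statistics-module calibration. All outputs are pure functions
of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boosting import Kernel
from .timecore import TimeAxis, TimeSeries, convolve_mtrf

__all__ = [
    "SimSpec",
    "ground_truth_kernel",
    "pink_noise",
    "simulate_dataset",
    "simulate_group",
]


@dataclass
class SimSpec:
    """Conditions for one simulated recording.

    Defaults follow the collinearity-simulation regime: 60 s at 100 Hz,
    8 correlated bands (adjacent-band correlation 0.8, as produced by a
    shared latent AR(1) envelope), 2 response channels, additive pink
    noise at 0 dB SNR (signal and noise variance equal per channel).
    """

    duration: float = 60.0
    rate: float = 100.0
    n_channels: int = 2
    design: str = "bands"  # bands | events
    n_bands: int = 8
    band_correlation: float = 0.8
    event_rate: float = 2.0  # events/s (events design)
    event_magnitude_sigma: float = 0.5  # log-normal sigma
    kernel: Kernel | None = None  # ground truth; default alternating_bands
    snr_db: float = 0.0  # inf for noiseless
    noise_kind: str = "pink"
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))

    @property
    def axis(self) -> TimeAxis:
        return TimeAxis(0.0, 1.0 / self.rate, self.n_samples)


def _biphasic(lags: np.ndarray, t_peak: float, t_trough: float, width: float):
    """Smooth biphasic response shape (positive peak then negative trough)."""
    g = lambda mu: np.exp(-0.5 * ((lags - mu) / width) ** 2)
    return g(t_peak) - 0.8 * g(t_trough)


def ground_truth_kernel(
    style: str = "alternating_bands",
    tmin: float = 0.0,
    tmax: float = 0.5,
    rate: float = 100.0,
    n_bands: int = 8,
    n_channels: int = 2,
    amplitude: float = 1.0,
    custom: np.ndarray | None = None,
) -> Kernel:
    """Known mTRF used to generate simulated responses.

    alternating_bands
        two adjacent middle bands carry smooth biphasic kernels of
        opposite sign, with signs alternating across channels; all
        other bands are exactly zero.
    biphasic
        every band carries the smooth biphasic kernel (sign alternating
        across channels); the single-predictor envelope-TRF analogue.
    damped_oscillation
        a Gabor-like (damped oscillatory) kernel on every band, scaled
        down with band index.
    custom
        a user-supplied ``(n_bands, n_lags, n_channels)`` array.
    """
    tstep = 1.0 / rate
    n_lags = int(round((tmax - tmin) / tstep))
    lag_axis = TimeAxis(tmin, tstep, n_lags)
    lags = lag_axis.times
    h = np.zeros((n_bands, n_lags, n_channels))
    if style == "alternating_bands":
        shape = _biphasic(lags, 0.08, 0.18, 0.03)
        b0 = n_bands // 2 - 1
        for c in range(n_channels):
            s = 1.0 if c % 2 == 0 else -1.0
            h[b0, :, c] = s * amplitude * shape
            h[b0 + 1, :, c] = -s * amplitude * shape
    elif style == "biphasic":
        shape = _biphasic(lags, 0.08, 0.18, 0.03)
        for c in range(n_channels):
            s = 1.0 if c % 2 == 0 else -1.0
            for b in range(n_bands):
                h[b, :, c] = s * amplitude * shape
    elif style == "damped_oscillation":
        env = np.exp(-((lags - lags[0]) / max(tmax - tmin, 1e-9)) * 4)
        gabor = amplitude * env * np.sin(2 * np.pi * 8 * (lags - lags[0]))
        for b in range(n_bands):
            for c in range(n_channels):
                h[b, :, c] = gabor / (1 + b)
    elif style == "custom":
        if custom is None or custom.shape != h.shape:
            raise ValueError(f"custom kernel must have shape {h.shape}")
        h = np.asarray(custom, dtype=float)
    else:
        raise ValueError(f"unknown kernel style {style!r}")
    return Kernel(h, lag_axis, [f"band{b}" for b in range(n_bands)],
                  [f"ch{c}" for c in range(n_channels)])


def pink_noise(n_samples: int, n_channels: int, seed) -> TimeSeries:
    """1/f noise: white Gaussian noise spectrally shaped so power ~ 1/f.

    The amplitude spectrum is scaled by 1/sqrt(f), the DC bin is zeroed
    (exact zero mean), and each channel is standardized to unit
    variance. Deterministic given the seed.
    """
    if n_samples < 16:
        raise ValueError("pink_noise requires n_samples >= 16")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    out = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True)
    axis = TimeAxis(0.0, 1.0, n_samples)
    return TimeSeries(out, axis, [f"ch{c}" for c in range(n_channels)], "channel")


def _ar1(n: int, rho: float, rng) -> np.ndarray:
    """Unit-variance AR(1) series."""
    e = rng.standard_normal(n) * np.sqrt(1 - rho**2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for t in range(1, n):
        x[t] = rho * x[t - 1] + e[t]
    return x


def _band_predictors(spec: SimSpec, rng) -> TimeSeries:
    """Correlated band envelopes: shared latent AR(1) + band-specific pink noise.

    band_i = sqrt(rho) * z + sqrt(1 - rho) * eps_i gives pairwise
    correlation rho between any two bands.
    """
    n = spec.n_samples
    rho = spec.band_correlation
    if not 0 <= rho < 1:
        raise ValueError("band_correlation must be in [0, 1)")
    z = _ar1(n, 0.95, rng)
    eps = pink_noise(n, spec.n_bands, rng.integers(2**31)).values
    vals = np.sqrt(rho) * z[None, :] + np.sqrt(1 - rho) * eps
    return TimeSeries(vals, spec.axis, [f"band{b}" for b in range(spec.n_bands)],
                      "band")


def _event_predictor(spec: SimSpec, rng) -> TimeSeries:
    """Impulse stream: Poisson event times, log-normal magnitudes."""
    n = spec.n_samples
    gaps = rng.exponential(1.0 / spec.event_rate, size=int(spec.duration *
                                                           spec.event_rate * 3) + 10)
    times = np.cumsum(gaps)
    times = times[times < spec.duration]
    vals = np.zeros(n)
    mags = rng.lognormal(0.0, spec.event_magnitude_sigma, size=times.size)
    idx = np.clip(np.round(times * spec.rate).astype(int), 0, n - 1)
    np.add.at(vals, idx, mags)
    return TimeSeries(vals, spec.axis, ["events"], "scalar")


def simulate_dataset(spec: SimSpec):
    """Generate ``(response, predictors, truth)`` for one recording.

    response = truth (*) predictors + noise, with the noise scaled per
    channel so that 10 log10(var_signal / var_noise) equals ``snr_db``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.design == "bands":
        predictors = _band_predictors(spec, rng)
        n_comp = spec.n_bands
    elif spec.design == "events":
        predictors = _event_predictor(spec, rng)
        n_comp = 1
    else:
        raise ValueError(f"unknown design {spec.design!r}")

    truth = spec.kernel
    if truth is None:
        truth = ground_truth_kernel(
            "alternating_bands" if spec.design == "bands" else "damped_oscillation",
            rate=spec.rate, n_bands=n_comp, n_channels=spec.n_channels,
        )
    if truth.values.shape[0] != n_comp:
        raise ValueError("ground-truth kernel does not match the predictor design")

    signal = convolve_mtrf(predictors, truth)
    sig_var = signal.values.var(axis=1)
    if np.isfinite(spec.snr_db):
        if np.any(sig_var == 0):
            raise ValueError(
                "all-zero signal with finite SNR requested; "
                "supply a non-zero ground-truth kernel"
            )
        if spec.noise_kind == "pink":
            noise = pink_noise(spec.n_samples, spec.n_channels,
                               rng.integers(2**31)).values
        elif spec.noise_kind == "white":
            noise = rng.standard_normal((spec.n_channels, spec.n_samples))
            noise /= noise.std(axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown noise_kind {spec.noise_kind!r}")
        noise_sd = np.sqrt(sig_var * 10 ** (-spec.snr_db / 10))
        values = signal.values + noise * noise_sd[:, None]
    else:
        values = signal.values
    response = TimeSeries(values, spec.axis,
                          [f"ch{c}" for c in range(spec.n_channels)], "channel")
    return response, predictors, truth


def simulate_group(n_subjects: int, spec: SimSpec, between_subject_sd: float = 0.0):
    """Per-subject datasets sharing a group-level ground-truth kernel.

    Each subject's kernel is the shared kernel plus Gaussian
    perturbation of the stated SD (in kernel units); subject seeds are
    spawned deterministically from the master seed.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be >= 0")
    base = spec.kernel
    if base is None:
        n_comp = spec.n_bands if spec.design == "bands" else 1
        base = ground_truth_kernel(
            "alternating_bands" if spec.design == "bands" else "damped_oscillation",
            rate=spec.rate, n_bands=n_comp, n_channels=spec.n_channels,
        )
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(n_subjects)
    out = []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        perturbed = base.values + between_subject_sd * rng.standard_normal(
            base.values.shape
        )
        k_s = Kernel(perturbed, base.lag_axis, list(base.predictor_labels),
                     list(base.channel_labels))
        sub_seed = int(rng.integers(2**31))
        sub_spec = SimSpec(**{**spec.__dict__, "kernel": k_s, "seed": sub_seed})
        out.append(simulate_dataset(sub_spec))
    return out
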