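"""Uniform time-series data model and the convolution engine.

The data model mirrors the needs of continuous-recording regression
analyses: every signal (EEG channels, spectrogram bands, scalar
predictors) lives on a uniform time axis, and the forward model is a
discrete convolution of predictor components with a multivariate kernel

    y_hat[c, t] = sum_i sum_l h[i, l, c] * x[i, t - (lag0 + l)]

with zero-padding before the start of the predictors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeAxis",
    "TimeSeries",
    "EventTable",
    "resample",
    "bandpass_filter",
    "convolve_mtrf",
    "epoch_average",
    "subtract_reference",
]

#: tolerance (s) for considering two time axes aligned
ALIGN_TOL = 1e-9


@dataclass(frozen=True)
class TimeAxis:
    """Uniformly sampled time axis: sample ``i`` lives at ``tstart + i * tstep``."""

    tstart: float
    tstep: float
    n_samples: int

    def __post_init__(self):
        if self.tstep <= 0:
            raise ValueError(f"tstep must be > 0, got {self.tstep}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.tstep

    @property
    def times(self) -> np.ndarray:
        return self.tstart + np.arange(self.n_samples) * self.tstep

    @property
    def tstop(self) -> float:
        """Time just past the last sample (half-open interval end)."""
        return self.tstart + self.n_samples * self.tstep

    def index_of(self, t: float) -> int:
        """Nearest-sample index for time ``t``; ties resolve toward the earlier sample."""
        x = (t - self.tstart) / self.tstep
        i = int(np.floor(x + 0.5))
        if i - x == 0.5:  # exact midpoint: prefer earlier sample
            i -= 1
        return i

    def aligned(self, other: "TimeAxis") -> bool:
        return (
            abs(self.tstart - other.tstart) < ALIGN_TOL
            and abs(self.tstep - other.tstep) < ALIGN_TOL
            and self.n_samples == other.n_samples
        )


@dataclass
class TimeSeries:
    """Multi-component signal on a uniform time axis.

    ``values`` is indexed ``(component, time)``. Components are EEG
    channels for responses, frequency bands or scalar features for
    predictors.
    """

    values: np.ndarray
    axis: TimeAxis
    component_labels: list[str] = field(default_factory=list)
    component_kind: str = "channel"  # channel | band | scalar

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[None, :]
        if v.ndim != 2:
            raise ValueError("values must be 1-D or 2-D (component, time)")
        if v.shape[1] != self.axis.n_samples:
            raise ValueError(
                f"values have {v.shape[1]} time samples, axis has {self.axis.n_samples}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("TimeSeries values must be finite (no NaN/Inf)")
        self.values = v
        if not self.component_labels:
            self.component_labels = [str(i) for i in range(v.shape[0])]
        if len(self.component_labels) != v.shape[0]:
            raise ValueError("component_labels length does not match component count")
        if len(set(self.component_labels)) != len(self.component_labels):
            raise ValueError("component_labels must be unique")
        if self.component_kind not in ("channel", "band", "scalar"):
            raise ValueError(f"unknown component_kind {self.component_kind!r}")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, **kw) -> "TimeSeries":
        d = dict(
            values=self.values,
            axis=self.axis,
            component_labels=list(self.component_labels),
            component_kind=self.component_kind,
        )
        d.update(kw)
        return TimeSeries(**d)


@dataclass
class EventTable:
    """Discrete stimulus events: onset time (s), magnitude and label per event."""

    times: np.ndarray
    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape or len(self.labels) != t.size:
            raise ValueError("times, values and labels must have matching 1-D shapes")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("event times must be non-decreasing")
        if t.size and t[0] < 0:
            raise ValueError("event times must be >= 0")
        self.times = t
        self.values = v

    @classmethod
    def from_rows(cls, rows) -> "EventTable":
        """Build from an iterable of ``(time, value, label)`` rows."""
        rows = list(rows)
        if not rows:
            return cls(np.empty(0), np.empty(0), [])
        t, v, lab = zip(*rows)
        order = np.argsort(np.asarray(t), kind="stable")
        return cls(
            np.asarray(t, float)[order],
            np.asarray(v, float)[order],
            [lab[i] for i in order],
        )

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# preprocessing


def resample(ts: TimeSeries, target_rate: float) -> TimeSeries:
    """Anti-aliased downsampling to ``target_rate`` Hz.

    An FFT low-pass with cutoff 0.4 * target_rate (2.5x guard band)
    precedes polyphase rate conversion, so content above the guard band
    cannot alias into the analysis band.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be > 0, got {target_rate}")
    rate = ts.axis.rate
    if target_rate > rate * (1 + 1e-9):
        raise ValueError(
            f"upsampling not supported: target {target_rate} Hz > source {rate:g} Hz"
        )
    if abs(target_rate - rate) < 1e-9 * rate:
        return ts.copy_with()
    n = ts.n_samples
    # FFT low-pass at 0.4 * target_rate with a short cosine taper
    spec = np.fft.rfft(ts.values, axis=1)
    freqs = np.fft.rfftfreq(n, ts.axis.tstep)
    cutoff = 0.4 * target_rate
    width = max(0.1 * cutoff, freqs[1] if len(freqs) > 1 else cutoff)
    gain = np.clip((cutoff + width - freqs) / width, 0.0, 1.0)
    gain = 0.5 - 0.5 * np.cos(np.pi * gain)  # raised-cosine edge
    filtered = np.fft.irfft(spec * gain, n=n, axis=1)
    # rate conversion: plain decimation for integer ratios (the FFT
    # low-pass already removed content above the guard band), polyphase
    # otherwise
    from fractions import Fraction

    frac = Fraction(target_rate / rate).limit_denominator(10**6)
    if frac.numerator == 1:
        out = filtered[:, :: frac.denominator]
    else:
        out = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    axis = TimeAxis(ts.axis.tstart, 1.0 / target_rate, out.shape[1])
    return ts.copy_with(values=out, axis=axis)


def _firwin_taps(low: float, high: float, rate: float, n_samples: int) -> np.ndarray:
    nyq = rate / 2
    # transition widths one octave outside the edges
    width = min(low / 2 if low > 0 else high, nyq - high, high)
    numtaps = int(np.ceil(3.3 * rate / width))  # Hamming: >= ~53 dB stopband
    numtaps = min(numtaps, max(3, (n_samples // 3) * 2 - 1))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, [low, high], pass_zero=False, fs=rate)


def bandpass_filter(ts: TimeSeries, low: float, high: float) -> TimeSeries:
    """Zero-phase FIR band-pass (windowed-sinc, linear phase, delay-compensated)."""
    nyq = ts.axis.rate / 2
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq:g} Hz); "
            f"got low={low}, high={high}"
        )
    taps = _firwin_taps(low, high, ts.axis.rate, ts.n_samples)
    # linear-phase FIR applied with 'same' alignment => exactly zero phase
    out = np.stack(
        [sps.fftconvolve(row, taps, mode="same") for row in ts.values]
    )
    return ts.copy_with(values=out)


def subtract_reference(ts: TimeSeries, reference_labels: list[str]) -> TimeSeries:
    """Re-reference by subtracting the mean of a designated channel set."""
    idx = [ts.component_labels.index(l) for l in reference_labels]
    ref = ts.values[idx].mean(axis=0)
    return ts.copy_with(values=ts.values - ref)


# ---------------------------------------------------------------------------
# convolution engine


def convolve_mtrf(predictors: TimeSeries, kernel) -> TimeSeries:
    """Predicted response ``y_hat[c, t] = sum_i sum_l h[i, l, c] x[i, t - tau_l]``.

    Samples where ``t - tau`` falls before the predictor start are
    zero-padded. The output axis is identical to the predictor axis.
    """
    h = kernel.values
    n_pred, n_lags, n_ch = h.shape
    if predictors.n_components != n_pred:
        raise ValueError(
            f"kernel expects {n_pred} predictor components, got {predictors.n_components}"
        )
    if abs(kernel.lag_axis.tstep - predictors.axis.tstep) > ALIGN_TOL:
        raise ValueError("kernel lag step does not match predictor sampling step")
    n = predictors.n_samples
    lag0 = int(round(kernel.lag_axis.tstart / kernel.lag_axis.tstep))
    out = np.zeros((n_ch, n))
    for i in range(n_pred):
        x = predictors.values[i]
        for c in range(n_ch):
            hic = h[i, :, c]
            if not np.any(hic):
                continue
            full = sps.fftconvolve(x, hic)  # full[m] = sum_l h_l x_{m-l}
            # y[t] = full[t - lag0]
            src_lo = max(0, lag0)
            src_hi = min(n, full.size + lag0)
            if src_lo < src_hi:
                out[c, src_lo:src_hi] += full[src_lo - lag0 : src_hi - lag0]
    labels = [f"ch{c}" for c in range(n_ch)]
    if kernel.channel_labels:
        labels = list(kernel.channel_labels)
    return TimeSeries(out, predictors.axis, labels, "channel")


def epoch_average(
    response: TimeSeries, events: EventTable, window: tuple[float, float]
) -> tuple[np.ndarray, int]:
    """ERP-style average of response segments around events.

    Segments span ``[event_time + tmin, event_time + tmax)`` on the
    response sampling grid. Events whose window is not fully inside the
    recording are dropped.

    Returns ``(mean_segments, n_dropped)`` where ``mean_segments`` has
    shape (channels, window samples).
    """
    tmin, tmax = window
    if tmax <= tmin:
        raise ValueError("window tmax must exceed tmin")
    axis = response.axis
    n_win = int(round((tmax - tmin) / axis.tstep))
    segs = []
    dropped = 0
    for t in events.times:
        i0 = axis.index_of(t + tmin)
        if i0 < 0 or i0 + n_win > axis.n_samples:
            dropped += 1
            continue
        segs.append(response.values[:, i0 : i0 + n_win])
    if not segs:
        raise ValueError("no event has its full window inside the recording")
    return np.mean(segs, axis=0), dropped
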