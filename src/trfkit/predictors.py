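"""Stimulus representations for encoding models.

Continuous predictors derive from the audio waveform: a gammatone
spectrogram models the cochlear decomposition, contiguous bands can be
binned for efficiency, summing all bands yields the broadband acoustic
envelope, and an auditory edge-detection transform marks acoustic
onsets per band. Discrete predictors are impulse (or step) trains built
from event tables, with constant magnitude or per-event values such as
word surprisal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .timecore import EventTable, TimeAxis, TimeSeries

__all__ = [
    "Spectrogram",
    "ScaleTransform",
    "erb_space",
    "gammatone_spectrogram",
    "bin_bands",
    "envelope",
    "apply_scale",
    "onset_spectrogram",
    "impulse_predictor",
    "step_predictor",
]


@dataclass
class Spectrogram(TimeSeries):
    """Band-decomposed TimeSeries with strictly increasing center frequencies."""

    band_centers: np.ndarray = None

    def __post_init__(self):
        if self.band_centers is None:
            raise ValueError("Spectrogram requires band_centers")
        super().__post_init__()
        bc = np.asarray(self.band_centers, dtype=float)
        if bc.shape != (self.n_components,):
            raise ValueError("band_centers must have one entry per band")
        if bc.size > 1 and np.any(np.diff(bc) <= 0):
            raise ValueError("band_centers must be strictly increasing")
        self.band_centers = bc
        self.component_kind = "band"


@dataclass(frozen=True)
class ScaleTransform:
    """Nonlinear response scale: linear, power-law, or log (dB re max, floored)."""

    mode: str = "log"
    exponent: float = 1.0 / 3.0  # power mode
    floor_db: float = -50.0  # log mode

    def __post_init__(self):
        if self.mode not in ("linear", "power", "log"):
            raise ValueError(f"unknown scale mode {self.mode!r}")
        if not 0 < self.exponent <= 1:
            raise ValueError("power exponent must be in (0, 1]")
        if self.floor_db >= 0:
            raise ValueError("floor_db must be negative")


def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """``n`` center frequencies uniformly spaced on the ERB-rate scale."""
    # Glasberg & Moore ERB-rate: E(f) = 21.4 log10(1 + 0.00437 f)
    e = lambda f: 21.4 * np.log10(1 + 0.00437 * f)
    einv = lambda x: (10 ** (x / 21.4) - 1) / 0.00437
    return einv(np.linspace(e(fmin), e(fmax), n))


def gammatone_spectrogram(
    wave: TimeSeries,
    n_filters: int = 256,
    fmin: float = 20.0,
    fmax: float = 5000.0,
    frame_rate: float = 1000.0,
) -> Spectrogram:
    """Cochlea-inspired spectrogram from a 4th-order gammatone filterbank.

    Filters are spaced uniformly on the ERB-rate scale in [fmin, fmax].
    The per-band envelope is the magnitude (analytic amplitude) of the
    filter output, averaged in non-overlapping frames of ``1/frame_rate``.
    """
    if wave.n_components != 1:
        raise ValueError("audio must be single-component (mono)")
    fs = wave.axis.rate
    if not (0 < fmin < fmax < fs / 2):
        raise ValueError(
            f"need 0 < fmin < fmax < Nyquist ({fs / 2:g} Hz); got {fmin}, {fmax}"
        )
    x = wave.values[0]
    centers = erb_space(fmin, fmax, n_filters)
    frame_len = max(1, int(round(fs / frame_rate)))
    n_frames = x.size // frame_len
    if n_frames < 1:
        raise ValueError("audio shorter than one output frame")
    out = np.empty((n_filters, n_frames))
    analytic_of = None
    for b, fc in enumerate(centers):
        bcoef, acoef = sps.gammatone(fc, "iir", fs=fs)
        y = sps.lfilter(bcoef, acoef, x)
        env = np.abs(sps.hilbert(y))
        out[b] = env[: n_frames * frame_len].reshape(n_frames, frame_len).mean(axis=1)
    axis = TimeAxis(wave.axis.tstart, 1.0 / frame_rate, n_frames)
    labels = [f"{fc:.0f}Hz" for fc in centers]
    return Spectrogram(out, axis, labels, "band", band_centers=centers)


def bin_bands(sgram: Spectrogram, n_bins: int) -> Spectrogram:
    """Sum contiguous near-equal groups of bands; conserves per-sample total power."""
    nb = sgram.n_components
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > nb:
        raise ValueError(f"n_bins ({n_bins}) exceeds band count ({nb})")
    groups = np.array_split(np.arange(nb), n_bins)
    vals = np.stack([sgram.values[g].sum(axis=0) for g in groups])
    centers = np.array(
        [np.exp(np.mean(np.log(sgram.band_centers[g]))) for g in groups]
    )
    labels = [f"{c:.0f}Hz" for c in centers]
    return Spectrogram(vals, sgram.axis, labels, "band", band_centers=centers)


def envelope(sgram: Spectrogram) -> TimeSeries:
    """Broadband acoustic envelope: per-sample sum of energy across all bands."""
    binned = bin_bands(sgram, 1)
    return TimeSeries(binned.values, sgram.axis, ["envelope"], "scalar")


def apply_scale(sgram: Spectrogram, transform: ScaleTransform) -> Spectrogram:
    """Map spectrogram values through the requested response scale.

    log mode computes ``20 log10(v / max)``, clips below at ``floor_db``
    and shifts so that the floor maps to 0 (range ``[0, -floor_db]``);
    exact zeros stay finite at 0.
    """
    v = sgram.values
    if np.any(v < 0):
        raise ValueError("apply_scale requires non-negative spectrogram values")
    if transform.mode == "linear":
        out = v.copy()
    elif transform.mode == "power":
        out = v**transform.exponent
    else:  # log
        ref = v.max()
        if ref == 0:
            out = np.zeros_like(v)
        else:
            with np.errstate(divide="ignore"):
                db = 20.0 * np.log10(v / ref)
            out = np.maximum(db, transform.floor_db) - transform.floor_db
    return dataclasses.replace(sgram, values=out)


def onset_spectrogram(
    sgram: Spectrogram,
    method: str = "rectified_difference",
    delay_span: float = 0.030,
) -> Spectrogram:
    """Acoustic onset (edge-detection) transform, per band, non-negative.

    rectified_difference
        ``max(0, x_t - x_{t-d})`` maximized over delays ``d`` up to
        ``delay_span`` — equivalently ``relu(x_t - min`` of the
        preceding window ``)``. A practical stand-in for neural
        edge-detection models, closely related to the half-wave
        rectified derivative of the envelope.
    delayed_inhibition
        ``max(0, x_t - max_d exp(-(d - 1)/D) x_{t-d})``: the recent past
        inhibits the present with exponentially decaying strength
        (weight 1 at the nearest past sample, so constant input stays
        silent).
    """
    d_max = int(round(delay_span / sgram.axis.tstep))
    if d_max < 1:
        raise ValueError(
            f"delay_span ({delay_span}s) is shorter than one sample "
            f"({sgram.axis.tstep}s)"
        )
    x = sgram.values
    if method == "rectified_difference":
        from scipy.ndimage import minimum_filter1d

        # right-aligned window [t - d_max + 1, t], then shifted one sample back
        origin = d_max // 2 - d_max + 1
        past_min = minimum_filter1d(
            x, size=d_max, axis=1, mode="nearest", origin=origin
        )
        past_min = np.concatenate([x[:, :1], past_min[:, :-1]], axis=1)
        out = np.maximum(0.0, x - past_min)
    elif method == "delayed_inhibition":
        inhib = np.full_like(x, -np.inf)
        for d in range(1, d_max + 1):
            w = np.exp(-(d - 1) * sgram.axis.tstep / delay_span)
            shifted = np.concatenate([np.repeat(x[:, :1], d, axis=1), x[:, :-d]], axis=1)
            inhib = np.maximum(inhib, w * shifted)
        out = np.maximum(0.0, x - inhib)
    else:
        raise ValueError(f"unknown onset method {method!r}")
    return dataclasses.replace(sgram, values=out)


def impulse_predictor(
    events: EventTable, axis: TimeAxis, use_values: bool = False
) -> tuple[TimeSeries, int]:
    """Impulse train: one impulse at the sample nearest each event time.

    Magnitudes are 1 (``use_values=False``) or the event's value.
    Coincident events sum. Events outside the axis are dropped;
    the dropped count is returned alongside the series.
    """
    out = np.zeros(axis.n_samples)
    dropped = 0
    for t, v in zip(events.times, events.values):
        i = axis.index_of(t)
        if 0 <= i < axis.n_samples:
            out[i] += v if use_values else 1.0
        else:
            dropped += 1
    return TimeSeries(out, axis, ["impulse"], "scalar"), dropped


def step_predictor(events: EventTable, axis: TimeAxis) -> TimeSeries:
    """Sustained (boxcar) predictor from paired onset/offset event rows.

    Consecutive row pairs encode ``[onset, offset)`` intervals; the
    value of the onset row is held over the interval.
    """
    if len(events) % 2:
        raise ValueError("step_predictor requires paired onset/offset rows")
    out = np.zeros(axis.n_samples)
    for j in range(0, len(events), 2):
        t_on, t_off = events.times[j], events.times[j + 1]
        if t_off < t_on:
            raise ValueError(f"offset before onset in pair starting at row {j}")
        i0 = max(0, axis.index_of(t_on))
        i1 = min(axis.n_samples, axis.index_of(t_off))
        if i1 > i0:
            out[i0:i1] += events.values[j]
    return TimeSeries(out, axis, ["step"], "scalar")
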