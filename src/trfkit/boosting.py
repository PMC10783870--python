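"""Sparse mTRF estimation by boosting, plus a ridge reference estimator.

The estimator is a coordinate-descent procedure with validation-based
early stopping. Starting from an all-zero kernel, each iteration finds
the single kernel element (predictor component x lag, optionally
expressed through a smooth basis window) whose change by ``+delta`` or
``-delta`` most reduces the training error. When no step reduces the
training error, ``delta`` is halved; when the validation error has
risen on two consecutive accepted steps, training stops and the kernel
with the lowest validation error over the whole history is returned.
Because most elements are never touched, the resulting kernels are
sparse: unimportant coefficients remain exactly zero.

Channels are fitted independently (mass-univariate). With k-fold
partitioning the final kernel is the average over the k runs' kernels,
expressed in the original units of the inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .timecore import TimeAxis, TimeSeries, convolve_mtrf

__all__ = [
    "Kernel",
    "BoostConfig",
    "PartitionSpec",
    "FitResult",
    "normalize_inputs",
    "make_partitions",
    "boost_fit",
    "cross_validate",
    "compare_models",
    "fit_backward",
    "proportion_explained",
    "basis_window_taps",
    "ridge_mtrf",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Kernel:
    """mTRF: filter kernel h over (predictor component, lag, output channel)."""

    values: np.ndarray  # (n_pred, n_lags, n_channels)
    lag_axis: TimeAxis
    predictor_labels: list[str] = field(default_factory=list)
    channel_labels: list[str] = field(default_factory=list)
    scale_info: dict | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("kernel values must be (predictor, lag, channel)")
        if v.shape[1] != self.lag_axis.n_samples:
            raise ValueError("lag count does not match lag_axis")
        if not np.all(np.isfinite(v)):
            raise ValueError("kernel values must be finite")
        self.values = v
        if not self.predictor_labels:
            self.predictor_labels = [f"x{i}" for i in range(v.shape[0])]
        if not self.channel_labels:
            self.channel_labels = [f"ch{c}" for c in range(v.shape[2])]

    @property
    def n_lags(self) -> int:
        return self.values.shape[1]

    @property
    def zero_fraction(self) -> float:
        """Fraction of exactly-zero kernel entries (sparsity of the estimate)."""
        return float(np.mean(self.values == 0.0))


@dataclass(frozen=True)
class BoostConfig:
    """Estimation meta-parameters.

    tmin, tmax
        lag window in seconds, half-open ``[tmin, tmax)`` sampled at the
        response rate (negative lags give decoding models).
    delta, mindelta
        coordinate step size in normalized units; halved when stuck,
        training stops once it would fall below ``mindelta``.
    error_norm
        'l2' (sum of squares) or 'l1' (sum of absolute errors; robust to
        outlier samples such as artifacts).
    basis, basis_window
        width (s) of the smooth basis window composing the TRF; 0 means
        the impulse basis (each element independent).
    selective_stopping
        if > 0, a predictor whose accepted steps raise the validation
        error this many consecutive times is frozen while the others
        continue training.
    """

    tmin: float = 0.0
    tmax: float = 0.5
    delta: float = 0.005
    mindelta: float | None = None  # default delta / 8
    error_norm: str = "l2"
    basis: float = 0.0
    basis_window: str = "hamming"
    selective_stopping: int = 0
    scale_data: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.tmax <= self.tmin:
            raise ValueError("tmax must exceed tmin")
        md = self.mindelta if self.mindelta is not None else self.delta / 8
        if not 0 < md <= self.delta:
            raise ValueError("need 0 < mindelta <= delta")
        if self.error_norm not in ("l1", "l2"):
            raise ValueError("error_norm must be 'l1' or 'l2'")
        if self.basis < 0:
            raise ValueError("basis width must be >= 0")
        if self.selective_stopping < 0:
            raise ValueError("selective_stopping must be >= 0")

    @property
    def mindelta_(self) -> float:
        return self.mindelta if self.mindelta is not None else self.delta / 8


@dataclass
class PartitionSpec:
    """k-fold assignment of contiguous segments to train/validation/test."""

    k: int
    n_samples: int
    segments: list[tuple[int, int]]
    runs: list[dict]  # each: {'test': [seg ids], 'validation': [...], 'train': [...]}
    has_test: bool

    def masks(self, run: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Boolean (train, validation, test) masks over the time axis for one run."""
        out = []
        for role in ("train", "validation", "test"):
            m = np.zeros(self.n_samples, dtype=bool)
            for s in self.runs[run].get(role, []):
                lo, hi = self.segments[s]
                m[lo:hi] = True
            out.append(m)
        return tuple(out)


@dataclass
class FitResult:
    """Kernel plus fit metrics, training history and full configuration."""

    kernel: Kernel
    proportion_explained: np.ndarray  # per channel
    residual_error: np.ndarray  # per channel, under the fit's error norm
    history: list  # per run: list of (step, pred, lag, sign, train_err, val_err)
    config: BoostConfig
    partitions: PartitionSpec
    cross_validated: bool
    run_kernels: list[Kernel] = field(default_factory=list)
    y_pred: np.ndarray | None = None  # normalized-scale prediction used for metrics
    min_validation_error: np.ndarray | None = None  # (runs, channels)
    stop_reasons: list = field(default_factory=list)  # per run, per channel


# ---------------------------------------------------------------------------
# normalization


def _component_rows(xs: list[TimeSeries]) -> tuple[np.ndarray, list[str]]:
    rows, labels = [], []
    for ts in xs:
        for j in range(ts.n_components):
            rows.append(ts.values[j])
            lab = ts.component_labels[j]
            labels.append(lab if lab not in labels else f"{len(labels)}:{lab}")
    return np.asarray(rows), labels


def normalize_inputs(
    y: np.ndarray, xs: np.ndarray, error_norm: str = "l2"
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Center each component and scale by SD (l2) or mean |.| (l1).

    Centering eliminates the intercept, which matters because the
    estimator favors exact-zero coefficients. Returns
    ``(y_scaled, xs_scaled, scale_info)``; kernels in original units are
    ``h_norm * scale_y[channel] / scale_x[component]``.
    """

    def _scale(arr, names):
        mu = arr.mean(axis=1, keepdims=True)
        centered = arr - mu
        if error_norm == "l2":
            s = centered.std(axis=1)
        else:
            s = np.abs(centered).mean(axis=1)
        bad = np.flatnonzero(s == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance component(s): {[names[b] for b in bad]}"
            )
        return centered / s[:, None], mu.ravel(), s

    y_s, y_mu, y_sc = _scale(y, [f"y[{i}]" for i in range(y.shape[0])])
    x_s, x_mu, x_sc = _scale(xs, [f"x[{i}]" for i in range(xs.shape[0])])
    info = {
        "y_mean": y_mu,
        "y_scale": y_sc,
        "x_mean": x_mu,
        "x_scale": x_sc,
        "error_norm": error_norm,
    }
    return y_s, x_s, info


# ---------------------------------------------------------------------------
# partitions


def make_partitions(
    axis: TimeAxis, k: int, test: bool = False, min_segment: float = 0.0
) -> PartitionSpec:
    """Split the time axis into k contiguous equal-length segments.

    With ``test=True`` run j uses segment j as test, segment (j+1) mod k
    as validation, the rest as train — every segment is the test set
    exactly once. Without test, runs rotate only the validation segment.
    """
    if test and k < 3:
        raise ValueError("k >= 3 required when a test segment is reserved")
    if not test and k < 2:
        raise ValueError("k >= 2 required")
    n = axis.n_samples
    bounds = np.linspace(0, n, k + 1).round().astype(int)
    segments = [(int(bounds[i]), int(bounds[i + 1])) for i in range(k)]
    min_len = int(round(min_segment / axis.tstep))
    for lo, hi in segments:
        if hi - lo < max(min_len, 1):
            raise ValueError(
                f"segment of {hi - lo} samples is shorter than the lag window "
                f"({min_len} samples); use fewer partitions or more data"
            )
    runs = []
    for j in range(k):
        if test:
            te, va = [j], [(j + 1) % k]
        else:
            te, va = [], [j]
        tr = [s for s in range(k) if s not in te and s not in va]
        runs.append({"test": te, "validation": va, "train": tr})
    return PartitionSpec(k, n, segments, runs, test)


# ---------------------------------------------------------------------------
# design matrix and basis


def basis_window_taps(basis: float, basis_window: str, tstep: float) -> np.ndarray:
    """Unit-sum taps of the basis window (``[1.0]`` for the impulse basis)."""
    if basis == 0:
        return np.ones(1)
    m = int(round(basis / tstep))
    if m < 1:
        return np.ones(1)
    try:
        w = sps.get_window(basis_window, m, fftbins=False)
    except ValueError as e:
        raise ValueError(f"unknown basis window family {basis_window!r}") from e
    return w / w.sum()


def _smear_lags(arr_lagged: np.ndarray, n_pred: int, n_lags: int, taps: np.ndarray):
    """Combine lag-shifted copies through the basis window, truncated at edges.

    ``arr_lagged`` has rows ordered predictor-major then lag. A
    coefficient at lag l contributes ``taps[k]`` at lag ``l + k - off``
    for lags inside the kernel window.
    """
    if taps.size == 1:
        return arr_lagged
    off = (taps.size - 1) // 2
    out = np.zeros_like(arr_lagged)
    a = arr_lagged.reshape(n_pred, n_lags, -1)
    o = out.reshape(n_pred, n_lags, -1)
    for kk, w in enumerate(taps):
        shift = kk - off
        lo, hi = max(0, shift), min(n_lags, n_lags + shift)
        o[:, lo:hi] += w * a[:, lo - shift : hi - shift]
    return out


def _lagged_design(x: np.ndarray, lag0: int, n_lags: int) -> np.ndarray:
    """Rows ``X[(i, l), t] = x[i, t - (lag0 + l)]`` with zero-padding."""
    n_pred, n = x.shape
    out = np.zeros((n_pred * n_lags, n))
    for i in range(n_pred):
        for l in range(n_lags):
            tau = lag0 + l
            row = out[i * n_lags + l]
            if tau >= 0:
                if tau < n:
                    row[tau:] = x[i, : n - tau]
            else:
                if -tau < n:
                    row[: n + tau] = x[i, -tau:]
    return out


def _smear_beta(beta: np.ndarray, n_pred: int, n_lags: int, taps: np.ndarray):
    """Kernel (n_pred, n_lags) from coefficient vector via the basis window."""
    return _smear_lags(beta[:, None], n_pred, n_lags, taps)[:, 0].reshape(
        n_pred, n_lags
    )


# ---------------------------------------------------------------------------
# the boosting inner loop (one channel, one run)


_RECOMPUTE_EVERY = 256  # refresh incremental quantities to cap float drift


def _boost_run_l2(y, B, Gram, sumsq_tr, train, val, cfg, n_pred, n_lags):
    """l2 boosting with incremental candidate evaluation.

    Maintains ``c[j] = B_j[train] . r[train]``; candidate errors follow
    in closed form, and accepting a step updates ``c`` through one Gram
    column — per-candidate cost is O(1) after setup.
    """
    n_coords = B.shape[0]
    r = y.copy()
    c = B[:, train] @ r[train]
    e_tr = float(r[train] @ r[train])
    e_val = float(r[val] @ r[val])
    beta = np.zeros(n_coords)
    best_val, best_beta = e_val, beta.copy()
    delta = cfg.delta
    mindelta = cfg.mindelta_
    frozen = np.zeros(n_pred, dtype=bool)
    sel_count = np.zeros(n_pred, dtype=int)
    n_val_up = 0
    history = []
    cand = np.empty(2 * n_coords)
    coord_pred = np.repeat(np.arange(n_pred), n_lags)
    step = 0
    while True:
        d2s = delta * delta * sumsq_tr
        two_dc = 2 * delta * c
        cand[0::2] = e_tr - two_dc + d2s
        cand[1::2] = e_tr + two_dc + d2s
        if frozen.any():
            mask = np.repeat(frozen, n_lags)
            cand[0::2][mask] = np.inf
            cand[1::2][mask] = np.inf
        j2 = int(np.argmin(cand))
        best_err = cand[j2]
        if not best_err < e_tr:
            delta *= 0.5
            if delta >= mindelta:
                continue
            reason = "delta_underflow"
            break
        j, sign = j2 >> 1, 1.0 if (j2 & 1) == 0 else -1.0
        beta[j] += sign * delta
        r -= sign * delta * B[j]
        c -= sign * delta * Gram[:, j]
        e_tr = float(best_err)
        new_val = float(r[val] @ r[val])
        step += 1
        history.append((step, coord_pred[j], j % n_lags, sign, e_tr, new_val))
        if step % _RECOMPUTE_EVERY == 0:
            c = B[:, train] @ r[train]
            e_tr = float(r[train] @ r[train])
        if new_val < best_val:
            best_val = new_val
            best_beta = beta.copy()
        if new_val > e_val:
            if cfg.selective_stopping:
                p = coord_pred[j]
                sel_count[p] += 1
                if sel_count[p] >= cfg.selective_stopping:
                    frozen[p] = True
                    if frozen.all():
                        e_val = new_val
                        reason = "all_frozen"
                        break
            else:
                n_val_up += 1
                if n_val_up >= 2:
                    e_val = new_val
                    reason = "validation_increase"
                    break
        else:
            if cfg.selective_stopping:
                sel_count[coord_pred[j]] = 0
            n_val_up = 0
        e_val = new_val
    return best_beta, history, best_val, reason


def _boost_run_l1(y, B, train, val, cfg, n_pred, n_lags):
    """l1 boosting; candidate errors evaluated directly on the training samples."""
    n_coords = B.shape[0]
    Btr = np.ascontiguousarray(B[:, train])
    r = y.copy()
    e_tr = float(np.abs(r[train]).sum())
    e_val = float(np.abs(r[val]).sum())
    beta = np.zeros(n_coords)
    best_val, best_beta = e_val, beta.copy()
    delta = cfg.delta
    mindelta = cfg.mindelta_
    frozen = np.zeros(n_pred, dtype=bool)
    sel_count = np.zeros(n_pred, dtype=int)
    n_val_up = 0
    history = []
    coord_pred = np.repeat(np.arange(n_pred), n_lags)
    cand = np.empty(2 * n_coords)
    step = 0
    while True:
        rtr = r[train]
        cand[0::2] = np.abs(rtr[None, :] - delta * Btr).sum(axis=1)
        cand[1::2] = np.abs(rtr[None, :] + delta * Btr).sum(axis=1)
        if frozen.any():
            mask = np.repeat(frozen, n_lags)
            cand[0::2][mask] = np.inf
            cand[1::2][mask] = np.inf
        j2 = int(np.argmin(cand))
        best_err = cand[j2]
        if not best_err < e_tr:
            delta *= 0.5
            if delta >= mindelta:
                continue
            reason = "delta_underflow"
            break
        j, sign = j2 >> 1, 1.0 if (j2 & 1) == 0 else -1.0
        beta[j] += sign * delta
        r -= sign * delta * B[j]
        e_tr = float(best_err)
        new_val = float(np.abs(r[val]).sum())
        step += 1
        history.append((step, coord_pred[j], j % n_lags, sign, e_tr, new_val))
        if new_val < best_val:
            best_val = new_val
            best_beta = beta.copy()
        if new_val > e_val:
            if cfg.selective_stopping:
                p = coord_pred[j]
                sel_count[p] += 1
                if sel_count[p] >= cfg.selective_stopping:
                    frozen[p] = True
                    if frozen.all():
                        e_val = new_val
                        reason = "all_frozen"
                        break
            else:
                n_val_up += 1
                if n_val_up >= 2:
                    e_val = new_val
                    reason = "validation_increase"
                    break
        else:
            if cfg.selective_stopping:
                sel_count[coord_pred[j]] = 0
            n_val_up = 0
        e_val = new_val
    return best_beta, history, best_val, reason


# ---------------------------------------------------------------------------
# public estimation API


def _prepare(y: TimeSeries, xs, config: BoostConfig):
    if isinstance(xs, TimeSeries):
        xs = [xs]
    for ts in xs:
        if not ts.axis.aligned(y.axis):
            raise ValueError("response and predictors must share an aligned time axis")
    x_rows, x_labels = _component_rows(xs)
    y_rows = y.values
    tstep = y.axis.tstep
    lag0 = int(round(config.tmin / tstep))
    n_lags = int(round((config.tmax - config.tmin) / tstep))
    if n_lags < 1:
        raise ValueError("lag window contains zero lags")
    return x_rows, x_labels, y_rows, lag0, n_lags, tstep


def _fit(y: TimeSeries, xs, config: BoostConfig, partitions: PartitionSpec | None,
         with_test: bool) -> FitResult:
    x_rows, x_labels, y_rows, lag0, n_lags, tstep = _prepare(y, xs, config)
    n_pred, n = x_rows.shape
    n_ch = y_rows.shape[0]

    if config.scale_data:
        y_n, x_n, scale_info = normalize_inputs(y_rows, x_rows, config.error_norm)
    else:
        y_n, x_n = y_rows, x_rows
        scale_info = {
            "y_mean": np.zeros(n_ch), "y_scale": np.ones(n_ch),
            "x_mean": np.zeros(n_pred), "x_scale": np.ones(n_pred),
            "error_norm": config.error_norm,
        }

    if partitions is None:
        k = 5 if with_test else 10
        partitions = make_partitions(
            y.axis, k, test=with_test, min_segment=config.tmax - config.tmin
        )
    elif with_test and not partitions.has_test:
        raise ValueError("cross-validation requires partitions with a test segment")

    taps = basis_window_taps(config.basis, config.basis_window, tstep)
    X = _lagged_design(x_n, lag0, n_lags)
    B = _smear_lags(X, n_pred, n_lags, taps)

    lag_axis = TimeAxis(lag0 * tstep, tstep, n_lags)
    unit = scale_info["y_scale"][None, None, :] / scale_info["x_scale"][:, None, None]

    run_kernels: list[Kernel] = []
    history: list = []
    min_val_err: list = []
    stop_reasons: list = []
    test_pred = np.full((n_ch, n), np.nan) if with_test else None
    l2 = config.error_norm == "l2"
    for run_i in range(partitions.k):
        train, val, test = partitions.masks(run_i)
        if l2:
            Btr = np.ascontiguousarray(B[:, train])
            Gram = Btr @ Btr.T
            sumsq = np.einsum("ij,ij->i", Btr, Btr)
        betas = np.empty((n_pred * n_lags, n_ch))
        run_hist = []
        run_best = []
        run_reasons = []
        for ch in range(n_ch):
            if l2:
                beta, hist, best_val, reason = _boost_run_l2(
                    y_n[ch], B, Gram, sumsq, train, val, config, n_pred, n_lags
                )
            else:
                beta, hist, best_val, reason = _boost_run_l1(
                    y_n[ch], B, train, val, config, n_pred, n_lags
                )
            betas[:, ch] = beta
            run_hist.append(hist)
            run_best.append(best_val)
            run_reasons.append(reason)
        history.append(run_hist)
        min_val_err.append(run_best)
        stop_reasons.append(run_reasons)
        h_norm = np.stack(
            [_smear_beta(betas[:, ch], n_pred, n_lags, taps) for ch in range(n_ch)],
            axis=-1,
        )
        run_kernels.append(
            Kernel(h_norm * unit, lag_axis, list(x_labels),
                   list(y.component_labels), scale_info)
        )
        if with_test:
            pred = (B.T @ betas).T  # (n_ch, n), normalized scale
            test_pred[:, test] = pred[:, test]

    k_mean = np.mean([k.values for k in run_kernels], axis=0)
    kernel = Kernel(
        k_mean, lag_axis, list(x_labels), list(y.component_labels), scale_info,
        info={"config": dataclasses.asdict(config)},
    )

    if with_test:
        if np.isnan(test_pred).any():
            raise AssertionError("test partitions do not cover the series")
        y_pred = test_pred
    else:
        # prediction from the averaged normalized kernel over the full series
        h_norm_avg = kernel.values / unit
        y_pred = np.stack([
            np.einsum("il,ilt->t", h_norm_avg[:, :, ch],
                      X.reshape(n_pred, n_lags, n))
            for ch in range(n_ch)
        ])

    pe = _proportion_explained_arrays(y_n, y_pred, config.error_norm)
    resid = y_n - y_pred
    if l2:
        residual_error = np.sum(resid**2, axis=1)
    else:
        residual_error = np.sum(np.abs(resid), axis=1)

    return FitResult(
        kernel=kernel,
        proportion_explained=pe,
        residual_error=residual_error,
        history=history,
        config=config,
        partitions=partitions,
        cross_validated=with_test,
        run_kernels=run_kernels,
        y_pred=y_pred,
        min_validation_error=np.asarray(min_val_err),
        stop_reasons=stop_reasons,
    )


def boost_fit(
    y: TimeSeries, xs, config: BoostConfig, partitions: PartitionSpec | None = None
) -> FitResult:
    """Fit an mTRF by boosting; metrics are computed on the training data.

    Use :func:`cross_validate` for unbiased predictive-power estimates.
    """
    return _fit(y, xs, config, partitions, with_test=False)


def cross_validate(
    y: TimeSeries, xs, config: BoostConfig, k: int = 5,
    partitions: PartitionSpec | None = None,
) -> FitResult:
    """k-fold cross-validated fit: every sample is predicted from unseen data.

    For each run the kernel is estimated on train+validation segments
    and used to predict the held-out test segment; the concatenated test
    predictions cover the whole series and yield unbiased per-channel
    predictive power.
    """
    if partitions is None:
        partitions = make_partitions(
            y.axis, k, test=True, min_segment=config.tmax - config.tmin
        )
    return _fit(y, xs, config, partitions, with_test=True)


def fit_backward(
    stimulus_feature: TimeSeries, response: TimeSeries, config: BoostConfig,
    partitions: PartitionSpec | None = None, k: int = 5, cross_validated: bool = True,
) -> FitResult:
    """Decoding model: reconstruct a stimulus feature from all response channels.

    Identical algorithm with roles swapped; delays are specified from
    the predictor's point of view, so the lag window is typically
    negative (each response sample reconstructs the stimulus preceding
    it).
    """
    if config.tmin >= 0:
        raise ValueError("backward models require a lag window with tmin < 0")
    if stimulus_feature.n_components != 1:
        raise ValueError("stimulus_feature must be a single component")
    if cross_validated:
        return cross_validate(stimulus_feature, [response], config, k=k,
                              partitions=partitions)
    return boost_fit(stimulus_feature, [response], config, partitions)


# ---------------------------------------------------------------------------
# metrics and model comparison


def _proportion_explained_arrays(y, y_hat, error_norm):
    if error_norm == "l2":
        num = np.sum((y - y_hat) ** 2, axis=1)
        den = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    else:
        num = np.sum(np.abs(y - y_hat), axis=1)
        den = np.sum(np.abs(y - y.mean(axis=1, keepdims=True)), axis=1)
    if np.any(den == 0):
        raise ValueError("response has zero variability; proportion undefined")
    return 1.0 - num / den


def proportion_explained(
    y: TimeSeries, y_hat: TimeSeries, error_norm: str = "l2"
) -> np.ndarray:
    """Per-channel ``1 - E(y - y_hat) / E(y - mean(y))``; may be negative."""
    if not y.axis.aligned(y_hat.axis):
        raise ValueError("series must be aligned")
    return _proportion_explained_arrays(y.values, y_hat.values, error_norm)


def compare_models(
    y: TimeSeries, xs_a, xs_b, config: BoostConfig, k: int = 5,
    partitions: PartitionSpec | None = None,
):
    """Difference in cross-validated predictive power, model B minus model A.

    Kernels are re-estimated for each model on identical partitions, so
    the difference isolates the unique contribution of the predictors
    that differ between the models.
    """
    if partitions is None:
        partitions = make_partitions(
            y.axis, k, test=True, min_segment=config.tmax - config.tmin
        )
    fit_a = cross_validate(y, xs_a, config, partitions=partitions)
    fit_b = cross_validate(y, xs_b, config, partitions=partitions)
    delta = fit_b.proportion_explained - fit_a.proportion_explained
    return delta, fit_a, fit_b


# ---------------------------------------------------------------------------
# ridge reference estimator


def ridge_mtrf(
    y: TimeSeries, xs, tmin: float, tmax: float, lam,
    k: int = 10, scale_data: bool = False,
) -> Kernel:
    """Closed-form Tikhonov-regularized mTRF on the lagged design matrix.

    Solves ``(X Xt + lam I) h = X y`` per channel with the same
    half-open lag convention and zero-padding as the boosting
    estimator. ``lam`` may be a scalar or a grid; with a grid, the value
    maximizing k-fold cross-validated predictive power is selected and
    the kernel refitted on all data. Unlike boosting, ridge shrinks
    coefficients smoothly toward zero but almost never to exactly zero.
    """
    cfg = BoostConfig(tmin=tmin, tmax=tmax, scale_data=scale_data)
    x_rows, x_labels, y_rows, lag0, n_lags, tstep = _prepare(y, xs, cfg)
    n_pred, n = x_rows.shape
    n_ch = y_rows.shape[0]
    if scale_data:
        y_n, x_n, scale_info = normalize_inputs(y_rows, x_rows, "l2")
    else:
        y_n, x_n = y_rows, x_rows
        scale_info = {"y_scale": np.ones(n_ch), "x_scale": np.ones(n_pred)}
    X = _lagged_design(x_n, lag0, n_lags)

    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam_arr < 0):
        raise ValueError("lambda must be >= 0")

    def _solve(Xm, ym, l):
        if l == 0:
            # plain least squares; QR/SVD avoids squaring the condition number
            cond = np.linalg.cond(Xm)
            if not np.isfinite(cond) or cond > 1e10:
                raise np.linalg.LinAlgError(
                    "singular or near-singular lagged design at lambda=0 "
                    "(collinear predictors); use lambda > 0"
                )
            sol, *_ = np.linalg.lstsq(Xm.T, ym.T, rcond=None)
            return sol  # (n_coords, n_ch)
        G = Xm @ Xm.T + l * np.eye(Xm.shape[0])
        return np.linalg.solve(G, Xm @ ym.T)

    if lam_arr.size > 1:
        parts = make_partitions(y.axis, k, test=True, min_segment=tmax - tmin)
        scores = np.zeros(lam_arr.size)
        for run_i in range(parts.k):
            train, val, test = parts.masks(run_i)
            fit_mask = train | val
            Xf, yf = X[:, fit_mask], y_n[:, fit_mask]
            for li, l in enumerate(lam_arr):
                h = _solve(Xf, yf, l)
                pred = (X[:, test].T @ h).T
                resid = y_n[:, test] - pred
                den = np.sum(
                    (y_n[:, test] - y_n[:, test].mean(1, keepdims=True)) ** 2, axis=1
                )
                scores[li] += np.mean(1 - np.sum(resid**2, axis=1) / den)
        best_lam = float(lam_arr[int(np.argmax(scores))])
    else:
        best_lam = float(lam_arr[0])

    h = _solve(X, y_n, best_lam)  # (n_coords, n_ch)
    h3 = h.reshape(n_pred, n_lags, n_ch)
    unit = scale_info["y_scale"][None, None, :] / scale_info["x_scale"][:, None, None]
    lag_axis = TimeAxis(lag0 * tstep, tstep, n_lags)
    return Kernel(
        h3 * unit, lag_axis, list(x_labels), list(y.component_labels),
        scale_info if scale_data else None, info={"lambda": best_lam},
    )
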