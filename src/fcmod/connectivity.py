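"""ROI time series → symmetric Fisher-z connectivity matrices.

Preprocessing mirrors a standard resting-state pipeline operating on already
denoised ROI time series: convert to percent signal change and demean,
band-pass (0.008–0.09 Hz by default, zero-phase Butterworth), then correlate
every ROI pair with a weighted zero-lag Pearson correlation and apply the
Fisher z transform ``atanh(r)``.

The correlation accepts a per-timepoint weight vector because some
connectivity toolboxes weight time points by condition/HRF envelopes; the
default is uniform weights (plain Pearson), which is a declared divergence
from toolbox-specific weighting schemes that are not publicly specified.

Diagonals of connectivity matrices are NaN by construction — the self
correlation is undefined under Fisher z and must never leak into statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ROITimeSeries",
    "FCMatrix",
    "to_percent_signal",
    "bandpass",
    "weighted_pearson",
    "fisher_z",
    "compute_fc_matrix",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "write_fc_tsv",
    "read_fc_tsv",
]

DEFAULT_BAND = (0.008, 0.09)


class DegenerateSignalError(ValueError):
    """An ROI column with (weighted) zero variance or near-zero mean."""


@dataclass
class ROITimeSeries:
    """Time × ROI sample matrix with its sampling interval in seconds."""

    values: np.ndarray
    sampling_interval: float
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("time series must be 2-D with >= 2 time points")
        if self.values.shape[1] != len(self.roi_labels):
            raise ValueError("roi_labels length does not match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite samples")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix for one subject; NaN diagonal."""

    z: np.ndarray
    subject_id: str
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.z[off])):
            raise ValueError("off-diagonal connectivity values must be finite")
        if not np.allclose(self.z[off], self.z.T[off], atol=1e-12, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")


def to_percent_signal(ts: ROITimeSeries, mean_tolerance: float = 1e-8) -> ROITimeSeries:
    """Percent signal change per ROI, then demean.

    Each column x becomes ``100 * (x - mean(x)) / mean(x)``; constant columns
    map to zero.  A column whose temporal mean is within *mean_tolerance* of
    zero (but not constant-zero variance at zero) cannot be expressed as
    percent change and raises :class:`DegenerateSignalError` naming the ROI.
    """
    x = ts.values
    means = x.mean(axis=0)
    out = np.zeros_like(x)
    for k, label in enumerate(ts.roi_labels):
        col, m = x[:, k], means[k]
        if abs(m) <= mean_tolerance:
            if np.allclose(col, 0.0):
                continue  # all-zero column: percent change is identically 0
            raise DegenerateSignalError(
                f"ROI {label!r}: temporal mean {m:.3g} too close to zero for "
                "percent-signal conversion"
            )
        out[:, k] = 100.0 * (col - m) / m
    out -= out.mean(axis=0)
    return ROITimeSeries(out, ts.sampling_interval, list(ts.roi_labels))


def bandpass(
    ts: ROITimeSeries,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> ROITimeSeries:
    """Zero-phase Butterworth band-pass (forward-backward ``filtfilt``).

    Zero-phase filtering preserves the zero-lag correlation structure that the
    connectivity measure depends on.  ``low`` may be 0 for a pure low-pass.
    The output is demeaned (the filter removes DC up to numerical residue).
    """
    nyquist = 0.5 / ts.sampling_interval
    if not 0 <= low < high:
        raise ValueError("require 0 <= low < high")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyquist} Hz")
    if low == 0:
        sos = signal.butter(order, high / nyquist, btype="low", output="sos")
    else:
        sos = signal.butter(
            order, [low / nyquist, high / nyquist], btype="band", output="sos"
        )
    padlen = min(ts.n_timepoints - 2, 3 * 2 * order * 3)
    out = signal.sosfiltfilt(sos, ts.values, axis=0, padlen=padlen)
    out = out - out.mean(axis=0)
    return ROITimeSeries(out, ts.sampling_interval, list(ts.roi_labels))


def _validate_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weight vector length {w.shape} != series length {n}")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    return w


def weighted_pearson(x, y, w=None) -> float:
    """Weighted zero-lag Pearson correlation.

    ``sum w (x - x̄_w)(y - ȳ_w) / sqrt(sum w (x - x̄_w)² · sum w (y - ȳ_w)²)``
    with weighted means; uniform weights give the plain Pearson coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    w = np.ones(n) if w is None else _validate_weights(w, n)
    xm = x - np.average(x, weights=w)
    ym = y - np.average(y, weights=w)
    vx = np.sum(w * xm * xm)
    vy = np.sum(w * ym * ym)
    if vx <= 0 or vy <= 0:
        raise DegenerateSignalError("zero weighted variance in correlation input")
    return float(np.sum(w * xm * ym) / np.sqrt(vx * vy))


def fisher_z(r) -> np.ndarray | float:
    """Fisher z transform ``atanh(r) = 0.5 ln((1+r)/(1-r))``; requires |r| < 1."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r_arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def compute_fc_matrix(
    ts: ROITimeSeries, w=None, subject_id: str = "subject"
) -> FCMatrix:
    """Fisher-z connectivity matrix from a (preprocessed) ROI time series.

    ``z[i, j] = atanh(weighted_pearson(col_i, col_j, w))`` for all i < j;
    the diagonal is NaN.  With uniform weights this is a weighted rephrasing
    of ``atanh(corrcoef)`` and is computed by fast matrix algebra.
    """
    x = ts.values
    n_t, n_r = x.shape
    w_arr = np.ones(n_t) if w is None else _validate_weights(w, n_t)
    wm = w_arr / w_arr.sum()
    xc = x - wm @ x
    cov = (xc * w_arr[:, None]).T @ xc
    var = np.diag(cov).copy()
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise DegenerateSignalError(
            f"zero-variance ROI column(s): {[ts.roi_labels[k] for k in bad]}"
        )
    r = cov / np.sqrt(np.outer(var, var))
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, np.nan)
    return FCMatrix(z=z, subject_id=subject_id, roi_labels=list(ts.roi_labels))


# ---------------------------------------------------------------------------
# TSV I/O


def read_timeseries_tsv(path: str | Path, sampling_interval: float | None = None) -> ROITimeSeries:
    """Read a time × ROI TSV whose first column is the time index in seconds."""
    df = pd.read_csv(path, sep="\t")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if sampling_interval is None:
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0]):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        sampling_interval = float(dt[0])
    return ROITimeSeries(
        df.iloc[:, 1:].to_numpy(dtype=float),
        sampling_interval,
        list(df.columns[1:]),
    )


def write_timeseries_tsv(ts: ROITimeSeries, path: str | Path) -> None:
    t = np.arange(ts.n_timepoints) * ts.sampling_interval
    df = pd.DataFrame(ts.values, columns=ts.roi_labels)
    df.insert(0, "time_s", t)
    df.to_csv(path, sep="\t", index=False)


def write_fc_tsv(fc: FCMatrix, path: str | Path) -> None:
    labels = fc.roi_labels or [f"roi{k}" for k in range(fc.z.shape[0])]
    pd.DataFrame(fc.z, index=labels, columns=labels).to_csv(path, sep="\t")


def read_fc_tsv(path: str | Path, subject_id: str = "subject") -> FCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FCMatrix(df.to_numpy(dtype=float), subject_id, list(df.columns))
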