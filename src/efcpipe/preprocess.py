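"""Time-series conditioning: volume discard, detrend/demean, PCA nuisance
selection, confound regression and zero-phase low-pass filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as spsignal

from ._validation import ValidationError, require

log = logging.getLogger(__name__)

__all__ = [
    "ROITimeSeries",
    "discard_initial",
    "detrend_demean",
    "select_nuisance_components",
    "regress_out",
    "lowpass_filter",
]


@dataclass(frozen=True)
class ROITimeSeries:
    """ROI-level signal matrix with a uniform time grid and provenance trail."""

    times: np.ndarray  # seconds, strictly increasing, constant step = tr
    values: np.ndarray  # time x ROI
    roi_names: tuple[str, ...]
    tr: float
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.times, float)
        values = np.asarray(self.values, float)
        if values.ndim == 1:
            values = values[:, None]
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        require(values.shape[0] == len(times), "ROITimeSeries rows must match times")
        require(values.shape[1] == len(self.roi_names), "ROITimeSeries columns must match roi_names")
        if len(times) > 1:
            steps = np.diff(times)
            require(np.all(steps > 0), "times must be strictly increasing")
            require(np.allclose(steps, self.tr, atol=1e-6), "time step must equal tr")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, step: str) -> "ROITimeSeries":
        return replace(self, values=values, provenance=self.provenance + (step,))

    def column(self, roi: str) -> np.ndarray:
        return self.values[:, self.roi_names.index(roi)]


def discard_initial(ts: ROITimeSeries, n_discard: int = 5) -> ROITimeSeries:
    """Drop the first ``n_discard`` volumes and re-anchor time at zero.

    The time shift (``n_discard * tr`` seconds) is recorded in provenance so
    event onsets can be shifted consistently by the pipeline.
    """
    require(n_discard >= 0, "n_discard must be >= 0")
    if n_discard == 0:
        return ts
    if n_discard >= ts.n_volumes:
        raise ValidationError(f"n_discard={n_discard} >= number of volumes {ts.n_volumes}")
    shift = ts.times[n_discard] - ts.times[0]
    return replace(
        ts,
        times=ts.times[n_discard:] - ts.times[n_discard],
        values=ts.values[n_discard:],
        provenance=ts.provenance + (f"discard_initial(n={n_discard}, shift_s={shift:g})",),
    )


def detrend_demean(ts: ROITimeSeries) -> ROITimeSeries:
    """Remove each column's best straight-line fit, then its mean."""
    if ts.n_volumes < 3:
        raise ValidationError("detrend_demean needs at least 3 time points")
    out = spsignal.detrend(ts.values, axis=0, type="linear")
    out = out - out.mean(axis=0)
    return ts.with_values(out, "detrend_demean")


def select_nuisance_components(signals: np.ndarray, cum_var: float = 0.70) -> np.ndarray:
    """Leading principal-component time courses reaching ``cum_var`` variance.

    Components are computed on the column-demeaned matrix; the returned array
    is time x component (PC scores).
    """
    signals = np.asarray(signals, float)
    if signals.ndim == 1:
        signals = signals[:, None]
    require(signals.shape[0] >= 2, "need at least 2 time points")
    require(signals.shape[1] >= 1, "need at least 1 column")
    require(0 < cum_var <= 1, "cum_var must be in (0, 1]")
    X = signals - signals.mean(axis=0)
    if not np.any(X):
        raise ValidationError("all-zero (constant) input; no variance to decompose")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, cum_var - 1e-12) + 1)
    k = min(k, np.sum(var > var.sum() * 1e-15))
    return U[:, :k] * s[:k]


def regress_out(ts: ROITimeSeries, confounds: np.ndarray) -> ROITimeSeries:
    """Residualize every ROI column against [intercept | confounds] by OLS."""
    confounds = np.asarray(confounds, float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    require(confounds.shape[0] == ts.n_volumes, "confound rows must match the series")
    X = np.column_stack([np.ones(ts.n_volumes), confounds])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which confound columns are linearly dependent
        bad = []
        for j in range(confounds.shape[1]):
            sub = np.column_stack([np.ones(ts.n_volumes), confounds[:, : j + 1]])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(j)
        raise ValidationError(f"confound matrix rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, ts.values, rcond=None)
    resid = ts.values - X @ beta
    return ts.with_values(resid, f"regress_out(k={confounds.shape[1]})")


def lowpass_filter(
    ts: ROITimeSeries,
    cutoff: float = 0.25,
    order: int = 5,
    stop_atten: float = 40.0,
) -> ROITimeSeries:
    """Zero-phase Chebyshev type-II low-pass filter.

    The stopband edge is ``cutoff`` Hz, clamped to 0.995 x Nyquist when the
    requested cut-off is degenerate at the sampling rate (a warning is
    logged).  Applied forward-backward (``filtfilt``) for zero phase.
    """
    nyq = 1.0 / (2.0 * ts.tr)
    if cutoff > nyq + 1e-12:
        raise ValidationError(f"cutoff {cutoff} Hz exceeds Nyquist {nyq} Hz")
    require(order >= 1, "filter order must be >= 1")
    require(stop_atten > 0, "stopband attenuation must be > 0")
    edge = min(cutoff, 0.995 * nyq)
    if edge < cutoff:
        log.warning("low-pass cutoff %.3f Hz clamped to %.4f Hz (0.995 x Nyquist)", cutoff, edge)
    sos = spsignal.cheby2(order, stop_atten, edge / nyq, btype="low", output="sos")
    padlen = min(3 * (2 * order + 1), ts.n_volumes - 1)
    out = spsignal.sosfiltfilt(sos, ts.values, axis=0, padlen=padlen)
    return ts.with_values(out, f"lowpass_filter(cutoff={cutoff}, order={order}, atten={stop_atten})")
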