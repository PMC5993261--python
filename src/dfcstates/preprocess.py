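"""Node time-course preparation and component quality control.

The canonical order is: discard the first volumes of a run (scanner
signal stabilization), remove each node's linear trend, then low-pass
filter below the hemodynamic band of interest (default cutoff 0.15 Hz
at TR = 2 s). Filtering is zero-phase (forward-backward Butterworth,
order 5) so that state boundaries are not shifted in time.

Component QC summarizes each node's Welch power spectrum by its dynamic
range (peak minus minimum spectral density) and the ratio of integrated
power below vs. above a split frequency; ICA components of neural
origin concentrate power at low frequencies, so a high low/high ratio
supports inclusion.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ComponentTimeSeries

__all__ = [
    "discard_initial_volumes", "detrend", "lowpass", "component_qc",
    "prepare", "TimeCoursePreprocessor",
]


def discard_initial_volumes(ts: ComponentTimeSeries, n_discard: int
                            ) -> ComponentTimeSeries:
    """Drop the first ``n_discard`` volumes (signal-stabilization cut)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_volumes} volumes")
    return ts.with_data(ts.data[n_discard:], extra_flag="discarded")


def detrend(ts: ComponentTimeSeries) -> ComponentTimeSeries:
    """Remove each node's least-squares linear trend (and mean)."""
    if ts.n_volumes < 3:
        raise ValueError("detrend needs at least 3 volumes")
    out = signal.detrend(ts.data, axis=0, type="linear")
    return ts.with_data(out, extra_flag="detrended")


def lowpass(ts: ComponentTimeSeries, cutoff_hz: float = 0.15,
            order: int = 5) -> ComponentTimeSeries:
    """Zero-phase Butterworth low-pass below ``cutoff_hz``.

    Applied forward and backward (``filtfilt``), so the effective
    attenuation is twice the one-pass filter order and no phase shift is
    introduced. Refuses to run twice on the same series.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    if "filtered" in ts.prep_flags:
        raise ValueError("time series is already low-pass filtered")
    b, a = signal.butter(order, cutoff_hz / nyquist, btype="low")
    out = signal.filtfilt(b, a, ts.data, axis=0)
    return ts.with_data(out, extra_flag="filtered")


def prepare(ts: ComponentTimeSeries, n_discard: int = 4,
            cutoff_hz: float = 0.15) -> ComponentTimeSeries:
    """Full prep in canonical order: discard -> detrend -> lowpass."""
    return lowpass(detrend(discard_initial_volumes(ts, n_discard)),
                   cutoff_hz=cutoff_hz)


def component_qc(ts: ComponentTimeSeries, split_hz: float = 0.10,
                 nperseg: int = 64) -> pd.DataFrame:
    """Per-node spectral QC metrics.

    Returns a DataFrame (node_id, dynamic_range, low_high_ratio).
    ``dynamic_range`` is the peak-minus-minimum of the Welch power
    spectral density; ``low_high_ratio`` integrates PSD below vs. above
    ``split_hz`` (trapezoid rule). Constant nodes yield NaN with a
    warning.
    """
    if ts.n_volumes < 32:
        raise ValueError("spectral QC needs at least 32 volumes")
    fs = 1.0 / ts.tr_seconds
    nperseg = min(nperseg, ts.n_volumes)
    freqs, psd = signal.welch(ts.data, fs=fs, axis=0, nperseg=nperseg,
                              noverlap=nperseg // 2)
    dyn = psd.max(axis=0) - psd.min(axis=0)
    low = freqs <= split_hz
    ratio = np.full(ts.n_nodes, np.nan)
    for j in range(ts.n_nodes):
        if np.ptp(ts.data[:, j]) == 0:
            warnings.warn(
                f"node {ts.node_meta['node_id'].iloc[j]} is constant; "
                "QC ratio undefined", RuntimeWarning, stacklevel=2)
            dyn[j] = 0.0
            continue
        num = np.trapezoid(psd[low, j], freqs[low])
        den = np.trapezoid(psd[~low, j], freqs[~low])
        ratio[j] = num / den if den > 0 else np.inf
    return pd.DataFrame({
        "node_id": ts.node_meta["node_id"].to_numpy(),
        "dynamic_range": dyn,
        "low_high_ratio": ratio,
    })


class TimeCoursePreprocessor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer applying the canonical prep chain.

    Operates on plain ``(n_volumes, n_nodes)`` arrays; the
    module-level functions provide the same operations on
    :class:`~dfcstates.containers.ComponentTimeSeries` objects.

    Parameters
    ----------
    n_discard : int, default 4
        Initial volumes removed.
    cutoff_hz : float, default 0.15
        Low-pass cutoff; must be below Nyquist for ``tr_seconds``.
    tr_seconds : float, default 2.0
    apply_detrend, apply_lowpass : bool
        Stage switches (both on by default).
    """

    def __init__(self, n_discard: int = 4, cutoff_hz: float = 0.15,
                 tr_seconds: float = 2.0, apply_detrend: bool = True,
                 apply_lowpass: bool = True, filter_order: int = 5):
        self.n_discard = n_discard
        self.cutoff_hz = cutoff_hz
        self.tr_seconds = tr_seconds
        self.apply_detrend = apply_detrend
        self.apply_lowpass = apply_lowpass
        self.filter_order = filter_order

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (volumes x nodes)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        ts = ComponentTimeSeries(data=X, tr_seconds=self.tr_seconds)
        ts = discard_initial_volumes(ts, self.n_discard)
        if self.apply_detrend:
            ts = detrend(ts)
        if self.apply_lowpass:
            ts = lowpass(ts, cutoff_hz=self.cutoff_hz,
                         order=self.filter_order)
        return ts.data

    def prepare_timeseries(self, ts: ComponentTimeSeries
                           ) -> ComponentTimeSeries:
        """Same chain, preserving metadata and provenance flags."""
        ts = discard_initial_volumes(ts, self.n_discard)
        if self.apply_detrend:
            ts = detrend(ts)
        if self.apply_lowpass:
            ts = lowpass(ts, cutoff_hz=self.cutoff_hz,
                         order=self.filter_order)
        return ts
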