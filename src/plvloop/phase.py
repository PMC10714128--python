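"""Instantaneous μ-phase estimation at the edge of a data window.

Estimating phase at the *end* of a window (rather than its middle) is the
hard part of any real-time phase-locked stimulation system: zero-phase
filtering corrupts the window edges, so the estimator filters, discards the
edges, fits an autoregressive (AR) model to what remains, forecasts the
oscillation past the timepoint of interest, and reads the phase off the
Hilbert analytic signal at that timepoint.  This is the "phastimate"
family of algorithms.

Phase convention: 0 rad at the positive peak of the oscillation, +/-pi at
the trough (the angle of the analytic signal of a cosine).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert, resample_poly
from statsmodels.regression.linear_model import yule_walker

from .recording import MultichannelRecording
from .spatial import Montage, apply_montage


class PhaseUndefinedError(ValueError):
    """The window carries no oscillation whose phase could be defined."""


@dataclass(frozen=True)
class PhaseEstimatorConfig:
    """Parameters of the edge-of-window phase estimator.

    ``band`` defaults to the real-time setting (8-15 Hz); the post-hoc
    re-analysis narrows it to 8-13.5 Hz (see :mod:`plvloop.analysis`).
    All lengths are in samples at ``working_rate``.
    """

    band: tuple[float, float] = (8.0, 15.0)
    bandpass_order: int = 128
    edge_trim: int = 64
    ar_order: int = 30
    forecast_len: int = 128
    working_rate: float = 500.0
    window_len: int = 500  # samples fed to estimate_phase by stream_phases

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0.0 < lo < hi < self.working_rate / 2):
            raise ValueError(
                f"band {self.band} must lie inside (0, {self.working_rate/2})"
            )
        if self.forecast_len <= self.edge_trim:
            raise ValueError("forecast_len must exceed edge_trim")
        if self.window_len <= 2 * self.edge_trim + self.ar_order + 1:
            raise ValueError("window_len too short for edge_trim + ar_order")

    @property
    def min_window(self) -> int:
        return 2 * self.edge_trim + self.ar_order + 2


#: Post-hoc variant: narrower band, as used on logged data after a session.
POSTHOC_BAND = (8.0, 13.5)


@lru_cache(maxsize=16)
def _bandpass_taps(order: int, lo: float, hi: float, fs: float) -> np.ndarray:
    # odd tap count keeps the linear-phase FIR type-I
    return firwin(order + 1, [lo, hi], pass_zero=False, fs=fs)


def _ar_forecast(x: np.ndarray, order: int, steps: int) -> np.ndarray:
    """Forecast ``steps`` samples past the end of ``x`` with a Yule-Walker AR fit."""
    rho, _ = yule_walker(x, order=order, method="mle", demean=True)
    mean = x.mean()
    buf = np.concatenate([x[-order:] - mean, np.zeros(steps)])
    for i in range(steps):
        buf[order + i] = rho @ buf[order + i - 1::-1][:order]
    return buf[order:] + mean


def estimate_phase(window: np.ndarray,
                   config: PhaseEstimatorConfig | None = None) -> float:
    """Instantaneous phase (radians in [-pi, pi)) at the last sample of ``window``.

    Pipeline: zero-phase FIR bandpass -> trim ``edge_trim`` samples per side
    -> AR(``ar_order``) fit -> forecast ``forecast_len`` samples -> Hilbert
    analytic signal -> angle at the original window end.

    Raises
    ------
    PhaseUndefinedError
        For all-zero / constant windows (no oscillation to phase-lock to).
    ValueError
        For non-finite samples or windows shorter than the estimator needs.
    """
    cfg = config or PhaseEstimatorConfig()
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValueError("window must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    if x.size < cfg.min_window:
        raise ValueError(
            f"window of {x.size} samples is too short; need >= {cfg.min_window}"
        )
    if np.ptp(x) == 0.0:
        raise PhaseUndefinedError("constant window has no defined phase")

    taps = _bandpass_taps(cfg.bandpass_order, *cfg.band, cfg.working_rate)
    filt = filtfilt(taps, 1.0, x, padlen=min(3 * taps.size, x.size - 1))
    trimmed = filt[cfg.edge_trim:-cfg.edge_trim]
    if np.ptp(trimmed) == 0.0 or trimmed.std() == 0.0:
        raise PhaseUndefinedError("window is constant after bandpass filtering")

    fc = _ar_forecast(trimmed, cfg.ar_order, cfg.forecast_len)
    analytic = hilbert(np.concatenate([trimmed, fc]))
    # timepoint of interest = end of the *original* window, which sits
    # edge_trim samples into the forecast
    idx = trimmed.size - 1 + cfg.edge_trim
    phi = float(np.angle(analytic[idx]))
    if phi == np.pi:
        phi = -np.pi
    return phi


def resample_to_working_rate(signal: np.ndarray, fs: float,
                             working_rate: float = 500.0) -> np.ndarray:
    """Anti-alias and decimate a signal to the estimator's working rate."""
    if fs == working_rate:
        return np.asarray(signal, dtype=float)
    ratio = fs / working_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(
            f"sample rate {fs} is not an integer multiple of {working_rate}"
        )
    return resample_poly(np.asarray(signal, dtype=float), up=1, down=q)


def stream_phases(recording: MultichannelRecording, montage: Montage,
                  config: PhaseEstimatorConfig | None = None,
                  stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window phase stream of a montaged recording at the working rate.

    Returns ``(times, phases)`` aligned to the recording clock, one estimate
    per working-rate sample (or every ``stride``-th sample).  Samples before
    the first full window, skipped strides, and windows where the estimate is
    undefined are NaN -- never a fabricated phase.
    """
    cfg = config or PhaseEstimatorConfig()
    if recording.duration < cfg.window_len / cfg.working_rate:
        raise ValueError(
            f"recording of {recording.duration:.3f} s is shorter than the "
            f"{cfg.window_len / cfg.working_rate:.3f} s estimation window"
        )
    sig = apply_montage(recording, montage)
    x = resample_to_working_rate(sig, recording.sample_rate, cfg.working_rate)
    n = x.size
    phases = np.full(n, np.nan)
    for k in range(cfg.window_len - 1, n, stride):
        try:
            phases[k] = estimate_phase(x[k - cfg.window_len + 1:k + 1], cfg)
        except PhaseUndefinedError:
            pass  # leave NaN
    times = np.arange(n) / cfg.working_rate
    return times, phases
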