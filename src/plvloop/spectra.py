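"""Welch spectra and 1/f-background fitting shared by synthesis and screening."""

from __future__ import annotations

import numpy as np
from scipy.signal import welch

#: Welch segment length in seconds; fixes the spectral resolution (0.5 Hz)
#: that both the SNR screening and the synthetic-SNR calibration use.
WELCH_SEG_S = 2.0


def welch_psd(signal: np.ndarray, fs: float,
              nperseg_s: float = WELCH_SEG_S) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (μV²/Hz) with the package's standard segmenting."""
    x = np.asarray(signal, dtype=float)
    nperseg = min(int(round(nperseg_s * fs)), x.size)
    return welch(x, fs=fs, nperseg=nperseg)


def fit_one_over_f(freqs: np.ndarray, psd: np.ndarray,
                   fit_range: tuple[float, float] = (2.0, 45.0),
                   exclude: tuple[float, float] = (7.0, 14.0)) -> np.ndarray:
    """Least-squares log-log line through the background spectrum.

    Fits ``log10(PSD) ~ log10(f)`` over ``fit_range`` excluding the μ band
    neighborhood ``exclude`` (so a μ peak does not bias its own baseline),
    and returns the fitted PSD (linear units) at every input frequency > 0.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1]) \
        & ~((freqs >= exclude[0]) & (freqs <= exclude[1])) & (psd > 0)
    if sel.sum() < 3:
        raise ValueError("too few spectral points to fit a 1/f background")
    coef = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)
    out = np.full_like(psd, np.nan)
    pos = freqs > 0
    out[pos] = 10.0 ** np.polyval(coef, np.log10(freqs[pos]))
    return out


def peak_snr_db(signal: np.ndarray, fs: float,
                band: tuple[float, float] = (8.0, 13.0),
                fit_range: tuple[float, float] = (2.0, 45.0),
                exclude: tuple[float, float] = (7.0, 14.0)) -> float:
    """Height (dB) of the in-band spectral peak over the fitted 1/f background.

    This is the μ-SNR screening statistic: the maximum over the band of
    ``10*log10(PSD_observed / PSD_fitted)``.
    """
    freqs, psd = welch_psd(signal, fs)
    fitted = fit_one_over_f(freqs, psd, fit_range=fit_range, exclude=exclude)
    sel = (freqs >= band[0]) & (freqs <= band[1]) & (psd > 0)
    if not sel.any():
        raise ValueError(f"no spectral estimates inside band {band}")
    ratio_db = 10.0 * np.log10(psd[sel] / fitted[sel])
    return float(np.max(ratio_db))
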