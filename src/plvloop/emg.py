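"""EMG trials -> analysis response variable.

The corticospinal response to each pulse is the peak-to-peak motor evoked
potential (MEP) in the FDI muscle, 20-40 ms post-pulse.  Trials with muscle
preactivation ("preinnervation", > 50 μV peak-to-peak in the detrended
pre-pulse EMG of either hand muscle) are discarded.  Raw amplitudes are then
transformed in three steps so that model residuals are roughly normal:

    alpha_j    = MEP_j ** (1/4)
    beta_j     = alpha_j - moving_median(alpha, window=301, centered)
    Response_j = (beta_j - mean(beta)) / sd(beta)      per session

The fourth root symmetrizes the lognormal-ish amplitude distribution, the
centered moving median removes slow drifts (drowsiness, coil drift), and the
z-score puts sessions on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend

#: Peak-to-peak MEP search window after the pulse, seconds (half-open (a, b]).
MEP_WINDOW = (0.020, 0.040)
#: Pre-pulse window checked for preinnervation, seconds before the pulse.
PRE_WINDOW = (-0.505, -0.005)
#: Preinnervation rejection threshold, μV peak-to-peak after detrending.
PREINNERVATION_LIMIT_UV = 50.0
#: Moving-median window, in trials, for the drift-removal step.
MEDIAN_WINDOW = 301


@dataclass
class EmgTrial:
    """Two-muscle EMG around one TMS pulse (FDI and APB, μV)."""

    fdi: np.ndarray
    apb: np.ndarray
    sample_rate: float
    pulse_time: float  # seconds from trace start
    trial_index: int = 0
    session_id: str = "S1"
    subject_id: str = "sub"

    def __post_init__(self) -> None:
        self.fdi = np.asarray(self.fdi, dtype=float)
        self.apb = np.asarray(self.apb, dtype=float)
        if self.fdi.shape != self.apb.shape:
            raise ValueError("FDI and APB traces must have equal length")

    def _slice(self, trace: np.ndarray, t0: float, t1: float,
               half_open_left: bool = False) -> np.ndarray:
        """Samples with time in [t0, t1] (or (t0, t1] if half_open_left)."""
        fs = self.sample_rate
        eps = 1e-9
        i0 = int(np.ceil((self.pulse_time + t0) * fs - eps))
        if half_open_left:
            i0 = int(np.floor((self.pulse_time + t0) * fs + eps)) + 1
        i1 = int(np.floor((self.pulse_time + t1) * fs + eps))
        if i0 < 0 or i1 >= trace.size:
            raise ValueError(
                f"window [{t0}, {t1}] s around the pulse extends beyond the "
                f"recorded trace"
            )
        return trace[i0:i1 + 1]


def mep_amplitude(trial: EmgTrial) -> float:
    """Peak-to-peak FDI amplitude (μV) in the (20 ms, 40 ms] post-pulse window."""
    seg = trial._slice(trial.fdi, *MEP_WINDOW, half_open_left=True)
    return float(seg.max() - seg.min())


def preinnervation_flag(trial: EmgTrial) -> bool:
    """True if either muscle shows > 50 μV p2p in the detrended pre-pulse window.

    The linear detrend removes electrode drift so only genuine muscle
    activity (or line noise) counts against the trial.
    """
    for trace in (trial.fdi, trial.apb):
        seg = trial._slice(trace, *PRE_WINDOW)
        seg = detrend(seg, type="linear")
        if float(np.ptp(seg)) > PREINNERVATION_LIMIT_UV:
            return True
    return False


@dataclass
class ResponseSeries:
    """Per-trial response variable and its intermediate transforms."""

    raw: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    response: np.ndarray
    session_mean: float
    session_sd: float
    meta: dict = field(default_factory=dict)


def moving_median(values: np.ndarray, window: int = MEDIAN_WINDOW,
                  edges: str = "truncate") -> np.ndarray:
    """Centered moving median; the window truncates at the series edges.

    ``edges='truncate'`` (default) takes the median over whatever part of the
    centered window exists; ``edges='nan'`` marks trials without a full
    window as NaN instead.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    min_periods = 1 if edges == "truncate" else window
    return s.rolling(window, center=True, min_periods=min_periods) \
            .median().to_numpy()


def transform_responses(amplitudes: np.ndarray, window: int = MEDIAN_WINDOW,
                        edges: str = "truncate") -> ResponseSeries:
    """Fourth root -> centered moving-median removal -> session z-score.

    ``amplitudes`` must be the raw MEP amplitudes (μV, >= 0) of a *single*
    session, in trial order, after preinnervation rejection.  If the
    de-drifted series is constant (sd = 0) the responses are defined as all
    zero and a warning is emitted.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if np.any(amps < 0):
        raise ValueError("MEP amplitudes must be non-negative")
    alpha = amps ** 0.25
    beta = alpha - moving_median(alpha, window=window, edges=edges)
    ok = np.isfinite(beta)
    mu = float(np.mean(beta[ok]))
    sd = float(np.std(beta[ok], ddof=1)) if ok.sum() > 1 else 0.0
    if sd > 0:
        response = (beta - mu) / sd
    else:
        warnings.warn("degenerate response series (sd = 0); responses set to 0")
        response = np.where(ok, 0.0, np.nan)
    return ResponseSeries(raw=amps, alpha=alpha, beta=beta, response=response,
                          session_mean=mu, session_sd=sd,
                          meta={"window": window, "edges": edges})


def transform_table(table: pd.DataFrame, amplitude_col: str = "mep_uv",
                    session_col: str = "Session",
                    window: int = MEDIAN_WINDOW) -> pd.DataFrame:
    """Apply :func:`transform_responses` per session of a trial table.

    Adds ``alpha``, ``beta`` and ``ResponseFDI`` columns; rows must already
    exclude preinnervated and timeout trials.
    """
    out = table.copy()
    for col in ("alpha", "beta", "ResponseFDI"):
        out[col] = np.nan
    for _, idx in out.groupby(session_col, sort=False).groups.items():
        rs = transform_responses(out.loc[idx, amplitude_col].to_numpy(),
                                 window=window)
        out.loc[idx, "alpha"] = rs.alpha
        out.loc[idx, "beta"] = rs.beta
        out.loc[idx, "ResponseFDI"] = rs.response
    return out
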