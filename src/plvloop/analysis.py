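"""Post-hoc analysis pipeline: predictors, mixed models, diagnostics.

The response variable (per-session z-scored, drift-corrected fourth-root MEP
amplitude; see :mod:`plvloop.emg`) is modeled with linear mixed-effects
regressions over trials, with a random intercept and condition slope per
subject.  The model family mirrors the study design:

* ``primary``        Response ~ 1 + Condition
* ``power``          Response ~ 1 + Condition * MuPowerR * MuPowerL
* ``summary``        Response ~ 1 + Condition + ISI + MuPowerR + MuPowerL
                     + Condition:ISI + Condition:MuPowerL + Condition:MuPowerR
                     + ISI:MuPowerL + MuPowerR:MuPowerL
* ``summary_phase``  summary + cos/sin of C3-Hjorth μ-phase and their
                     interactions with MuPowerL (circular-linear terms)
* ``stplv`` / ``istplv``  summary with the continuous (i)stPLV replacing
                     the categorical Condition
* ``circular``       Response ~ 1 + cos(φC3) + sin(φC3) (illustration model)

Circular predictors always enter as cosine/sine *pairs* (including their
interactions); a pair with coefficients (a, b) is one sinusoid
``s*cos(φ+δ)`` with amplitude ``s = sqrt(a² + b²)`` and phase shift
``δ = atan2(-b, a)``, and is tested jointly (2-df Wald or LR test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import detrend, filtfilt, firwin, hilbert, periodogram
from statsmodels.regression.mixed_linear_model import MixedLM

from .connectivity import LockingValue, PhaseWindow, cstplv
from .phase import POSTHOC_BAND, PhaseEstimatorConfig, estimate_phase
from .spectra import peak_snr_db

MU_BAND = (8.0, 13.0)
#: Pre-stimulus window for power and post-hoc stPLV, s relative to the pulse.
PRESTIM_WINDOW = (-0.505, -0.005)
#: Longer raw window retrieved for post-hoc phase estimation.
PHASE_WINDOW = (-0.605, -0.005)


# ---------------------------------------------------------------------------
# Trial-level predictors
# ---------------------------------------------------------------------------

def _window_slice(signal: np.ndarray, fs: float, pulse_time: float,
                  t0: float, t1: float) -> np.ndarray:
    eps = 1e-9
    i0 = int(np.ceil((pulse_time + t0) * fs - eps))
    i1 = int(np.floor((pulse_time + t1) * fs + eps))
    if i0 < 0 or i1 >= signal.size:
        raise ValueError(
            f"window [{t0}, {t1}] s around pulse at {pulse_time} s extends "
            f"beyond the signal")
    return signal[i0:i1 + 1]


def prestim_mu_power(signal: np.ndarray, pulse_time: float, fs: float,
                     band: tuple[float, float] = MU_BAND) -> float:
    """Log μ-band power of the 500 ms pre-pulse window of a Hjorth signal.

    The window [-0.505, -0.005] s is linearly detrended, the band power is
    integrated from the raw periodogram, and the natural log is returned.
    Z-scoring within (subject, session) happens at the table level with
    :func:`zscore_within`.
    """
    seg = _window_slice(signal, fs, pulse_time, *PRESTIM_WINDOW)
    seg = detrend(seg, type="linear")
    freqs, pxx = periodogram(seg, fs=fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    power = float(np.trapezoid(pxx[sel], freqs[sel]))
    if power <= 0:
        raise ValueError("non-positive band power in pre-stimulus window")
    return float(np.log(power))


def zscore_within(values: np.ndarray, groups: np.ndarray,
                  ddof: int = 1) -> np.ndarray:
    """Z-score ``values`` within each group label (session within subject)."""
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    return s.groupby(g).transform(
        lambda x: (x - x.mean()) / x.std(ddof=ddof)).to_numpy()


def _posthoc_filter_chain(seg: np.ndarray, fs: float,
                          bandpass: bool = True) -> np.ndarray:
    """Detrend -> zero-phase FIR lowpass (order 50, 250 Hz) -> decimate to
    500 Hz -> optional zero-phase FIR μ-band bandpass (8-13.5 Hz).

    The pre-pulse windows are short (300-550 samples at 500 Hz), so the
    band filter is an order-128 FIR: a forward-backward order-200 filter
    needs more padding than the window holds and rings across its whole
    length (MATLAB's filtfilt rejects that combination outright).
    """
    q = int(round(fs / 500.0))
    if abs(fs / 500.0 - q) > 1e-9:
        raise ValueError(f"sample rate {fs} must be a multiple of 500 Hz")
    x = detrend(np.asarray(seg, dtype=float), type="linear")
    lp = firwin(51, 250.0, fs=fs)
    x = filtfilt(lp, 1.0, x, padlen=min(3 * lp.size, x.size - 1))
    x = x[::q]
    if bandpass:
        bp = firwin(129, list(POSTHOC_BAND), pass_zero=False, fs=500.0)
        x = filtfilt(bp, 1.0, x, padlen=min(3 * bp.size, x.size - 1))
    return x


# Short post-hoc windows: μ-band filtering happens inside the estimator
# (its own zero-phase FIR), and a smaller edge trim leaves enough samples
# for a stable AR fit.
_POSTHOC_PHASE_CONFIG = PhaseEstimatorConfig(
    band=POSTHOC_BAND, window_len=300, edge_trim=48, forecast_len=112)


def posthoc_phase(signal: np.ndarray, pulse_time: float, fs: float,
                  config: PhaseEstimatorConfig | None = None) -> float:
    """Instantaneous μ-phase 5 ms before the pulse, re-estimated offline.

    Applies the post-hoc filter chain to the [-0.605, -0.005] s raw window
    and runs the edge-of-window phase estimator (8-13.5 Hz band) at its end.
    """
    seg = _window_slice(signal, fs, pulse_time, *PHASE_WINDOW)
    x = _posthoc_filter_chain(seg, fs, bandpass=False)
    return estimate_phase(x, config or _POSTHOC_PHASE_CONFIG)


def posthoc_stplv(signal1: np.ndarray, signal2: np.ndarray, pulse_time: float,
                  fs: float, window: int = 250) -> LockingValue:
    """Offline stPLV of the 500 ms pre-pulse window of two Hjorth signals.

    Phases across the window come from the analytic signal of the post-hoc
    filtered traces (the causal-edge AR forecast is only needed in real
    time); the last ``window`` samples at 500 Hz enter the complex stPLV.
    An extra 0.6 s of head data absorbs filter edge effects.
    """
    from .phase import _ar_forecast

    t0 = PRESTIM_WINDOW[0] - 0.6
    trim, margin = 48, 64   # estimator-style edge handling
    phases = []
    for sig in (signal1, signal2):
        seg = _window_slice(sig, fs, pulse_time, t0, PRESTIM_WINDOW[1])
        x = _posthoc_filter_chain(seg, fs)
        n = x.size
        trimmed = x[trim:n - trim]
        fc = _ar_forecast(trimmed, order=30, steps=trim + margin)
        analytic = hilbert(np.concatenate([trimmed, fc]))
        phi = np.angle(analytic)
        # sample k of the original 500 Hz window sits at position k - trim
        phases.append(phi[n - window - trim:n - trim])
    return cstplv(PhaseWindow(phases[0], phases[1], end_time=pulse_time))


def isi_covariate(isi_values: np.ndarray) -> np.ndarray:
    """Fourth root of the ISI's excess over the minimum observed ISI."""
    isi = np.asarray(isi_values, dtype=float)
    if isi.size == 0:
        raise ValueError("no ISI values")
    return (isi - isi.min()) ** 0.25


# ---------------------------------------------------------------------------
# Model designs
# ---------------------------------------------------------------------------

_FORMULAS: dict[str, list[str]] = {
    "primary": ["Condition"],
    "power": ["Condition", "MuPowerR", "MuPowerL",
              "Condition:MuPowerR", "Condition:MuPowerL",
              "MuPowerR:MuPowerL", "Condition:MuPowerR:MuPowerL"],
    "summary": ["Condition", "ISI", "MuPowerR", "MuPowerL",
                "Condition:ISI", "Condition:MuPowerL", "Condition:MuPowerR",
                "ISI:MuPowerL", "MuPowerR:MuPowerL"],
    "summary_phase": ["Condition", "ISI", "MuPowerR", "MuPowerL",
                      "Condition:ISI", "Condition:MuPowerL",
                      "Condition:MuPowerR", "ISI:MuPowerL",
                      "MuPowerR:MuPowerL",
                      "cosPhiC3", "sinPhiC3",
                      "cosPhiC3:MuPowerL", "sinPhiC3:MuPowerL"],
    "stplv": ["stPLV", "ISI", "MuPowerR", "MuPowerL",
              "stPLV:ISI", "stPLV:MuPowerL", "stPLV:MuPowerR",
              "ISI:MuPowerL", "MuPowerR:MuPowerL"],
    "istplv": ["istPLV", "ISI", "MuPowerR", "MuPowerL",
               "istPLV:ISI", "istPLV:MuPowerL", "istPLV:MuPowerR",
               "ISI:MuPowerL", "MuPowerR:MuPowerL"],
    "circular": ["cosPhiC3", "sinPhiC3"],
}

#: Condition-like predictor that also gets the subject-level random slope.
_SLOPE_FACTOR = {"primary": "Condition", "power": "Condition",
                 "summary": "Condition", "summary_phase": "Condition",
                 "stplv": "stPLV", "istplv": "istPLV", "circular": None}

_FACTOR_COLUMNS = {
    "Condition": ("Condition", lambda c: (c == "high").astype(float)),
    "MuPowerL": ("MuPowerL", None),
    "MuPowerR": ("MuPowerR", None),
    "ISI": ("ISI", None),
    "stPLV": ("stplv_ph", None),
    "istPLV": ("istplv_ph", None),
    "cosPhiC3": ("phi_c3", np.cos),
    "sinPhiC3": ("phi_c3", np.sin),
    "cosPhiC4": ("phi_c4", np.cos),
    "sinPhiC4": ("phi_c4", np.sin),
}

#: Overridable source columns for the continuous-FC designs (real-time or
#: post-hoc stPLVs can be selected by renaming columns accordingly).
_CIRCULAR_PREFIXES = ("cosPhi", "sinPhi")


@dataclass
class ModelSpec:
    """A fully materialized fixed/random design for one model formula."""

    formula_id: str
    terms: list[str]
    X: pd.DataFrame               # fixed-effect columns, no intercept
    y: pd.Series
    groups: pd.Series             # subject labels
    exog_re: pd.DataFrame         # random-effect design (intercept [+ slope])
    term_groups: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.y)


def _factor_series(table: pd.DataFrame, factor: str) -> pd.Series:
    if factor not in _FACTOR_COLUMNS:
        raise KeyError(f"unknown model factor {factor!r}")
    col, fn = _FACTOR_COLUMNS[factor]
    if col not in table.columns:
        raise KeyError(
            f"trial table lacks column {col!r} required by factor {factor!r}")
    s = table[col]
    return pd.Series(fn(s), index=table.index) if fn is not None \
        else s.astype(float)


def _is_circular(factor: str) -> bool:
    return factor.startswith(_CIRCULAR_PREFIXES)


def build_design(table: pd.DataFrame, formula_id: str) -> ModelSpec:
    """Materialize the fixed/random design matrices for a model formula.

    Condition is coded 0 = low (reference), 1 = high, so a positive
    Condition coefficient means larger responses in the high condition.
    Interaction columns are products of their factors' columns.  Circular
    cosine/sine columns are grouped so they are always tested jointly.
    """
    if formula_id not in _FORMULAS:
        raise KeyError(f"unknown formula {formula_id!r}; "
                       f"have {sorted(_FORMULAS)}")
    for col in ("ResponseFDI", "Subject"):
        if col not in table.columns:
            raise KeyError(f"trial table lacks column {col!r}")
    terms = _FORMULAS[formula_id]
    X = pd.DataFrame(index=table.index)
    for term in terms:
        factors = term.split(":")
        col = _factor_series(table, factors[0])
        for f in factors[1:]:
            col = col * _factor_series(table, f)
        X[term] = col.to_numpy()

    # group circular cos/sin pairs (incl. their interactions) for joint tests
    term_groups: dict[str, list[str]] = {}
    for term in terms:
        factors = term.split(":")
        circ = [f for f in factors if _is_circular(f)]
        if circ:
            base = circ[0][3:]  # "cosPhiC3" -> "PhiC3"
            rest = [f for f in factors if not _is_circular(f)]
            display = ":".join([base] + rest)
            term_groups.setdefault(display, []).append(term)
        else:
            term_groups[term] = [term]

    slope = _SLOPE_FACTOR[formula_id]
    exog_re = pd.DataFrame({"Intercept": np.ones(len(table))},
                           index=table.index)
    if slope is not None:
        exog_re[slope] = _factor_series(table, slope).to_numpy()
    return ModelSpec(formula_id=formula_id, terms=terms, X=X,
                     y=table["ResponseFDI"].astype(float),
                     groups=table["Subject"], exog_re=exog_re,
                     term_groups=term_groups)


# ---------------------------------------------------------------------------
# Model fitting and tests
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Mixed-model fit: estimates, Wald tests, AIC, random-effect variances."""

    formula_id: str
    params: pd.Series
    bse: pd.Series
    wald: pd.DataFrame            # index: term group; columns W, df, p
    aic: float
    llf_ml: float
    k_ml: int                     # parameter count of the ML fit
    n_obs: int
    n_groups: int
    cov_re: pd.DataFrame
    scale: float
    converged: bool
    singular: bool
    warnings: list[str] = field(default_factory=list)

    def circular_term(self, group: str) -> "CircularTerm":
        """Amplitude/phase form of a fitted cosine/sine pair."""
        cos_t, sin_t = None, None
        for t in _split_group(self, group):
            (cos_t, sin_t) = (t, sin_t) if t.split(":")[0].startswith("cos") \
                else (cos_t, t)
        if cos_t is None or sin_t is None:
            raise KeyError(f"{group!r} is not a circular pair in this model")
        return CircularTerm(a=float(self.params[cos_t]),
                            b=float(self.params[sin_t]))

    _term_groups: dict[str, list[str]] = field(default_factory=dict, repr=False)


def _split_group(fit: FitResult, group: str) -> list[str]:
    try:
        return fit._term_groups[group]
    except KeyError:
        raise KeyError(f"term group {group!r} not in model "
                       f"({sorted(fit._term_groups)})") from None


@dataclass(frozen=True)
class CircularTerm:
    """Cosine/sine coefficient pair as one sinusoid s*cos(phi + delta)."""

    a: float
    b: float
    s: float = field(init=False)
    delta: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", float(np.hypot(self.a, self.b)))
        object.__setattr__(self, "delta", float(np.arctan2(-self.b, self.a)))


def _raw_fit(spec: ModelSpec, columns: list[str], reml: bool):
    exog = pd.concat(
        [pd.Series(1.0, index=spec.X.index, name="Intercept"),
         spec.X[columns]], axis=1)
    model = MixedLM(endog=spec.y.to_numpy(), exog=exog,
                    groups=spec.groups.to_numpy(),
                    exog_re=spec.exog_re.to_numpy())
    model.data.xnames = list(exog.columns)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(reml=reml, method=["lbfgs", "bfgs", "powell"])
    msgs = [str(w.message) for w in caught]
    return res, msgs


def _joint_wald(res, names: list[str], cols: list[str]) -> float:
    idx = [names.index(c) for c in cols]
    b = np.asarray(res.fe_params)[idx]
    V = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    return float(b @ np.linalg.solve(V, b))


def _higher_order_relatives(term: str, terms: list[str]) -> list[str]:
    fs = set(term.split(":"))
    return [t for t in terms if set(t.split(":")) > fs]


def fit_model(spec: ModelSpec, reml: bool = True,
              wald_reference: str = "between-within",
              compute_aic: bool = True) -> FitResult:
    """Fit a mixed model (REML) and compute type-II Wald tests per term.

    Each term (or cosine/sine pair) is tested in the model containing all
    terms except its higher-order relatives, with a joint Wald statistic on
    its columns.  With ``wald_reference='between-within'`` (default) the
    statistic is referred to an F distribution with denominator degrees of
    freedom ``n_subjects - rank of the subject-level design``, a small-sample
    correction for the otherwise anti-conservative asymptotic test;
    ``'chi2'`` gives the plain asymptotic chi-square reference.  The AIC is
    computed from a maximum-likelihood refit.  Convergence problems are
    recorded in the result, never silenced.
    """
    res, msgs = _raw_fit(spec, spec.terms, reml=reml)
    if compute_aic:
        res_ml, msgs_ml = _raw_fit(spec, spec.terms, reml=False)
    else:
        res_ml, msgs_ml = None, []
    names = ["Intercept"] + spec.terms
    params = pd.Series(np.asarray(res.fe_params), index=names)
    with np.errstate(invalid="ignore"):  # boundary fits -> NaN SEs, kept
        bse = pd.Series(np.asarray(res.bse_fe), index=names)

    den_df = res.model.n_groups - spec.exog_re.shape[1]
    rows = {}
    for group, cols in spec.term_groups.items():
        relatives: list[str] = []
        for c in cols:
            relatives += _higher_order_relatives(c, spec.terms)
        if relatives:
            sub_terms = [t for t in spec.terms if t not in set(relatives)]
            sub_res, _ = _raw_fit(spec, sub_terms, reml=reml)
            sub_names = ["Intercept"] + sub_terms
            w = _joint_wald(sub_res, sub_names, cols)
        else:
            w = _joint_wald(res, names, cols)
        df1 = len(cols)
        if wald_reference == "between-within":
            p = float(stats.f.sf(w / df1, df1, max(den_df, 1)))
        elif wald_reference == "chi2":
            p = float(stats.chi2.sf(w, df1))
        else:
            raise ValueError(f"unknown wald_reference {wald_reference!r}")
        rows[group] = {"W": w, "df": df1, "p": p}
    wald = pd.DataFrame.from_dict(rows, orient="index")

    q = spec.exog_re.shape[1]
    k_ml = len(names) + q * (q + 1) // 2 + 1  # fixed + re-cov + residual
    aic = float(-2.0 * res_ml.llf + 2.0 * k_ml) if res_ml is not None \
        else float("nan")
    llf_ml = float(res_ml.llf) if res_ml is not None else float("nan")
    singular = any("singular" in m.lower() or "boundary" in m.lower()
                   for m in msgs + msgs_ml)
    out = FitResult(
        formula_id=spec.formula_id, params=params, bse=bse, wald=wald,
        aic=aic, llf_ml=llf_ml, k_ml=k_ml, n_obs=spec.n_obs,
        n_groups=int(res.model.n_groups),
        cov_re=pd.DataFrame(np.asarray(res.cov_re)),
        scale=float(res.scale),
        converged=bool(res.converged) and
        (res_ml is None or bool(res_ml.converged)),
        singular=singular,
        warnings=sorted(set(msgs + msgs_ml)))
    out._term_groups = dict(spec.term_groups)
    return out


def lr_test(fit_null: FitResult, fit_full: FitResult
            ) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (statistic, df, p)."""
    df = fit_full.k_ml - fit_null.k_ml
    if df <= 0:
        raise ValueError("fit_full must have more parameters than fit_null")
    stat = 2.0 * (fit_full.llf_ml - fit_null.llf_ml)
    return float(stat), int(df), float(stats.chi2.sf(max(stat, 0.0), df))


# ---------------------------------------------------------------------------
# Individual-level and diagnostic operations
# ---------------------------------------------------------------------------

def responder_split(table: pd.DataFrame, alpha: float = 0.05,
                    response_col: str = "ResponseFDI"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sided rank-sum tests of high > low per subject and per session.

    Returns ``(by_subject, by_session)`` with unadjusted one-sided p-values;
    a subject is a *responder* if its pooled-session p < ``alpha``.
    """
    def _p(sub: pd.DataFrame) -> float:
        hi = sub.loc[sub["Condition"] == "high", response_col].to_numpy()
        lo = sub.loc[sub["Condition"] == "low", response_col].to_numpy()
        if hi.size == 0 or lo.size == 0:
            return np.nan
        return float(stats.mannwhitneyu(hi, lo, alternative="greater",
                                        method="asymptotic").pvalue)

    subj = table.groupby("Subject", sort=True).apply(_p, include_groups=False) \
                .rename("p").to_frame()
    subj["responder"] = subj["p"] < alpha
    sess = table.groupby(["Subject", "Session"], sort=True) \
                .apply(_p, include_groups=False).rename("p").to_frame()
    sess["significant"] = sess["p"] < alpha
    return subj.reset_index(), sess.reset_index()


@dataclass
class PhaseHistogram2D:
    """2-D histogram of (φC3, φC4) pairs per condition, plus the contrast."""

    edges: np.ndarray
    counts_high: np.ndarray
    counts_low: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.counts_high - self.counts_low


def phase_histogram_2d(table: pd.DataFrame, bins: int = 12,
                       phase_cols: tuple[str, str] = ("phi_c3", "phi_c4")
                       ) -> PhaseHistogram2D:
    """Count trials in 2-D phase bins over [-pi, pi)^2 for each condition."""
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    out = {}
    for cond in ("high", "low"):
        sub = table[table["Condition"] == cond]
        h, _, _ = np.histogram2d(sub[phase_cols[0]], sub[phase_cols[1]],
                                 bins=[edges, edges])
        out[cond] = h
    return PhaseHistogram2D(edges=edges, counts_high=out["high"],
                            counts_low=out["low"])


def phase_concentration(args: np.ndarray) -> float:
    """Mean of cos(2*arg): 1 if locked at 0/pi, 0 if uniform, -1 at +/-pi/2.

    A value near 1 over the locking angles of many trials is the signature
    of volume conduction (a common source seen at both electrodes locks at
    zero or pi phase shift).
    """
    a = np.asarray(args, dtype=float)
    if a.size == 0:
        raise ValueError("no locking angles given")
    return float(np.mean(np.cos(2.0 * a)))


def vc_diagnostics(args_by_group: dict[str, np.ndarray],
                   bins: int = 24) -> pd.DataFrame:
    """Volume-conduction diagnostics of cstPLV locking angles per group.

    For each group (condition, subject, ...) returns the histogram of
    arguments over [-pi, pi) and the 0/pi concentration statistic.
    """
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    rows = []
    for label, args in args_by_group.items():
        a = np.asarray(args, dtype=float)
        counts, _ = np.histogram(a, bins=edges)
        rows.append({"group": label, "n": a.size,
                     "concentration": phase_concentration(a),
                     "hist": counts, "edges": edges})
    return pd.DataFrame(rows).set_index("group")


def mu_snr(signal: np.ndarray, fs: float,
           band: tuple[float, float] = MU_BAND) -> float:
    """μ-peak height (dB) over the fitted 1/f background of a resting signal.

    The screening criterion admits subjects whose C3-Hjorth resting spectrum
    shows a μ peak of at least 5 dB over the individually fitted 1/f noise.
    """
    return peak_snr_db(np.asarray(signal, dtype=float), fs, band=band)
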