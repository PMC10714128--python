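"""Synthetic EEG/EMG generator with planted ground truth.

Every downstream stage of the closed-loop system is tested against data from
this module, because no public recordings exist for this paradigm.  It
emulates the features of real sensorimotor EEG that matter for the method:

* two μ-band (8-13 Hz) oscillatory sources whose *phase-difference
  consistency* is controllable -- a stochastic pair of phase oscillators in
  which source 2 is pulled toward source 1's phase (plus a lag) with
  strength ``coupling_strength`` (κ), against independent phase noise;
* arch-shaped (non-sinusoidal) waveforms via a phase-locked second harmonic;
* 1/f background noise per electrode, with the μ peak planted at a
  configurable height (dB) over the fitted 1/f background -- the same
  definition the SNR screening uses;
* a linear volume-conduction mixing matrix onto 10-20 electrodes and
  optional 50 Hz line noise;
* stimulus-evoked EMG whose log MEP amplitude depends linearly on the
  connectivity state, μ-powers, ISI and (sinusoidally) on μ-phase, with
  lognormal noise.

A single seed fans out into per-component substreams (sources, noise, EMG)
so modules can be exercised in isolation yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emg import EmgTrial
from .recording import DEFAULT_EEG_CHANNELS, MultichannelRecording
from .spectra import fit_one_over_f, welch_psd


class SynthConfigError(ValueError):
    """Invalid synthetic-data configuration."""


def _default_mixing() -> np.ndarray:
    """Left source to the C3 electrode, right source to C4, unit gain."""
    m = np.zeros((len(DEFAULT_EEG_CHANNELS), 2))
    m[DEFAULT_EEG_CHANNELS.index("C3"), 0] = 1.0
    m[DEFAULT_EEG_CHANNELS.index("C4"), 1] = 1.0
    return m


@dataclass
class SynthConfig:
    """Parameters of a synthetic two-source EEG recording.

    ``snr_db`` is the planted height of the μ periodogram peak over the
    fitted 1/f background at a unit-gain electrode; set ``source_amp_uv``
    to bypass the calibration and fix the source amplitude directly.
    """

    sample_rate: float = 5000.0
    duration: float = 10.0
    mu_freq_left: float = 10.0
    mu_freq_right: float = 12.0
    coupling_strength: float = 0.0      # κ, rad/s pull toward the locked state
    coupling_lag: float = 0.0           # radians, planted phase lag
    phase_noise: float = 0.25           # rad/sqrt(s) diffusion of each phase
    waveform_asymmetry: float = 0.0     # 0 = sinusoid, >0 adds 2nd harmonic
    noise_exponent: float = 1.0         # 1/f^exponent background slope
    noise_rms_uv: float = 10.0          # per-electrode background RMS
    snr_db: float = 10.0
    source_amp_uv: float | None = None
    mixing: np.ndarray = field(default_factory=_default_mixing)
    channels: tuple[str, ...] = DEFAULT_EEG_CHANNELS
    line_noise_amp: float = 0.0         # μV at 50 Hz
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing = np.atleast_2d(np.asarray(self.mixing, dtype=float))
        for name, f in (("mu_freq_left", self.mu_freq_left),
                        ("mu_freq_right", self.mu_freq_right)):
            if not 8.0 <= f <= 13.0:
                raise SynthConfigError(
                    f"{name}={f} outside the μ band [8, 13] Hz")
        if not np.isfinite(self.coupling_strength) or self.coupling_strength < 0:
            raise SynthConfigError("coupling_strength must be finite and >= 0")
        if not 0.0 <= self.waveform_asymmetry < 1.0:
            raise SynthConfigError("waveform_asymmetry must be in [0, 1)")
        highest = 2 * max(self.mu_freq_left, self.mu_freq_right)
        if self.line_noise_amp > 0:
            highest = max(highest, 50.0)
        if self.sample_rate <= 2 * highest:
            raise SynthConfigError(
                f"sample_rate {self.sample_rate} must exceed twice the "
                f"highest generated frequency ({highest} Hz)")
        if self.mixing.shape[0] != len(self.channels):
            raise SynthConfigError(
                f"mixing has {self.mixing.shape[0]} rows for "
                f"{len(self.channels)} channels")
        if self.mixing.shape[1] != 2:
            raise SynthConfigError("mixing must have one column per source")

    def rng(self, stream: str) -> np.random.Generator:
        """Per-component substream of the global seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(hash(stream) % 2**31,))
        return np.random.default_rng(ss)


@dataclass
class SourceSignals:
    """Unit-amplitude source waveforms with their ground-truth phases."""

    waves: np.ndarray      # (2, n) unit-amplitude waveforms
    phases: np.ndarray     # (2, n) ground-truth phases, wrapped to [-pi, pi)
    sample_rate: float

    @property
    def n_samples(self) -> int:
        return self.waves.shape[1]


def simulate_phase_pair(n: int, dt: float, freq1: float, freq2: float,
                        kappa: float | np.ndarray, lag: float,
                        phase_noise: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Two coupled noisy phase rotators; returns unwrapped phases (2, n).

    Phase 1 advances at ``freq1`` with diffusion; phase 2 advances at
    ``freq2`` and is additionally pulled toward ``phase1 + lag`` with
    strength ``kappa`` (rad/s, scalar or per-sample array)::

        dθ2 = 2π f2 dt + κ sin(θ1 + lag - θ2) dt + σ dW
    """
    kappa_arr = np.broadcast_to(np.asarray(kappa, dtype=float), (n,))
    if not np.all(np.isfinite(kappa_arr)):
        raise SynthConfigError("coupling strength must be finite")
    sig = phase_noise * np.sqrt(dt)
    noise = rng.normal(0.0, sig, size=(2, n))
    th1 = np.empty(n)
    th2 = np.empty(n)
    th1[0] = rng.uniform(-np.pi, np.pi)
    th2[0] = rng.uniform(-np.pi, np.pi)
    # phase 1 is a free rotator: vectorized cumulative sum
    th1[1:] = th1[0] + np.cumsum(2 * np.pi * freq1 * dt + noise[0, 1:])
    if np.all(kappa_arr == 0.0):
        th2[1:] = th2[0] + np.cumsum(2 * np.pi * freq2 * dt + noise[1, 1:])
        return np.vstack([th1, th2])
    drift2 = 2 * np.pi * freq2 * dt
    k_dt = kappa_arr * dt
    n2 = noise[1]
    for i in range(1, n):
        th2[i] = (th2[i - 1] + drift2
                  + k_dt[i] * np.sin(th1[i - 1] + lag - th2[i - 1])
                  + n2[i])
    return np.vstack([th1, th2])


def _waveform(theta: np.ndarray, asymmetry: float) -> np.ndarray:
    """Unit-amplitude μ waveform; asymmetry adds a phase-locked 2nd harmonic."""
    return np.cos(theta) + asymmetry * np.cos(2 * theta)


def simulate_sources(config: SynthConfig,
                     rng: np.random.Generator | None = None) -> SourceSignals:
    """Generate the two μ sources and their ground-truth phase sequences."""
    if config.duration < 2.0:
        raise SynthConfigError("duration must be at least 2 s")
    rng = rng or config.rng("sources")
    n = int(round(config.duration * config.sample_rate))
    dt = 1.0 / config.sample_rate
    theta = simulate_phase_pair(
        n, dt, config.mu_freq_left, config.mu_freq_right,
        config.coupling_strength, config.coupling_lag,
        config.phase_noise, rng)
    waves = _waveform(theta, config.waveform_asymmetry)
    wrapped = np.angle(np.exp(1j * theta))
    return SourceSignals(waves=waves, phases=wrapped,
                         sample_rate=config.sample_rate)


def one_over_f_noise(n: int, fs: float, exponent: float, rms: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, scaled to ``rms``."""
    if rms == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    pos = freqs > 0
    shape[pos] = freqs[pos] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    return x * (rms / np.std(x))


def _calibrated_amplitude(source_wave: np.ndarray, noise_ref: np.ndarray,
                          fs: float, peak_freq: float, snr_db: float) -> float:
    """Source amplitude that plants an snr_db periodogram peak over the 1/f fit."""
    f_n, p_n = welch_psd(noise_ref, fs)
    fitted = fit_one_over_f(f_n, p_n)
    i0 = int(np.argmin(np.abs(f_n - peak_freq)))
    p_background = fitted[i0]
    f_s, p_s = welch_psd(source_wave, fs)
    near = (f_s >= peak_freq - 2.0) & (f_s <= peak_freq + 2.0)
    p_unit = float(np.max(p_s[near]))
    if p_unit <= 0:
        raise SynthConfigError("source waveform has no spectral peak")
    target = (10.0 ** (snr_db / 10.0) - 1.0) * p_background
    return float(np.sqrt(max(target, 0.0) / p_unit))


def mix_to_channels(sources: SourceSignals, config: SynthConfig,
                    rng: np.random.Generator | None = None
                    ) -> MultichannelRecording:
    """Volume-conduct the sources onto electrodes and add noise.

    Each electrode is the mixing-weighted sum of the (amplitude-calibrated)
    sources, plus independent 1/f background noise and optional 50 Hz line
    noise.  Source amplitudes are calibrated so that a unit-gain electrode
    shows a μ peak ``snr_db`` dB above its fitted 1/f background.
    """
    if config.mixing.shape[1] != sources.waves.shape[0]:
        raise SynthConfigError(
            f"mixing has {config.mixing.shape[1]} columns for "
            f"{sources.waves.shape[0]} sources")
    rng = rng or config.rng("noise")
    n = sources.n_samples
    fs = sources.sample_rate
    noise = np.vstack([
        one_over_f_noise(n, fs, config.noise_exponent, config.noise_rms_uv, rng)
        for _ in config.channels]) if config.noise_rms_uv > 0 \
        else np.zeros((len(config.channels), n))

    if config.source_amp_uv is not None:
        amps = np.full(sources.waves.shape[0], config.source_amp_uv)
    elif config.noise_rms_uv == 0.0:
        amps = np.ones(sources.waves.shape[0])
    else:
        peak_freqs = (config.mu_freq_left, config.mu_freq_right)
        amps = np.empty(sources.waves.shape[0])
        for j in range(sources.waves.shape[0]):
            ref = int(np.argmax(np.abs(config.mixing[:, j])))
            amps[j] = _calibrated_amplitude(
                sources.waves[j], noise[ref], fs, peak_freqs[j], config.snr_db)

    data = config.mixing @ (amps[:, None] * sources.waves) + noise
    if config.line_noise_amp > 0:
        t = np.arange(n) / fs
        line = config.line_noise_amp * np.sin(2 * np.pi * 50.0 * t)
        data = data + line[None, :]
    return MultichannelRecording(
        data=data, sample_rate=fs, labels=list(config.channels),
        meta={"source_amp_uv": amps.tolist(), "config_seed": config.seed})


# ---------------------------------------------------------------------------
# MEP / EMG synthesis
# ---------------------------------------------------------------------------

@dataclass
class MepModel:
    """Generative model of log MEP amplitude given the trial's brain state.

    ``log(MEP) = intercept + b_fc*FC + b_powL*PowL + b_powR*PowR + b_isi*ISI
                 + b_fc_powL*FC*PowL + b_fc_powR*FC*PowR + b_fc_isi*FC*ISI
                 + phase_amp*cos(phase_left + phase_shift) + N(0, sigma)``

    Predictors are on standardized scales; ``intercept`` is log-μV.
    """

    intercept: float = float(np.log(500.0))
    b_fc: float = 0.0
    b_powL: float = 0.0
    b_powR: float = 0.0
    b_isi: float = 0.0
    b_fc_powL: float = 0.0
    b_fc_powR: float = 0.0
    b_fc_isi: float = 0.0
    phase_amp: float = 0.0
    phase_shift: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise SynthConfigError("sigma must be >= 0")

    def log_amplitude(self, state: "TrialState",
                      rng: np.random.Generator | None = None) -> float:
        mu = (self.intercept
              + self.b_fc * state.fc
              + self.b_powL * state.mu_power_l
              + self.b_powR * state.mu_power_r
              + self.b_isi * state.isi
              + self.b_fc_powL * state.fc * state.mu_power_l
              + self.b_fc_powR * state.fc * state.mu_power_r
              + self.b_fc_isi * state.fc * state.isi
              + self.phase_amp * np.cos(state.phase_left + self.phase_shift))
        if self.sigma > 0:
            if rng is None:
                raise ValueError("rng required when sigma > 0")
            mu += rng.normal(0.0, self.sigma)
        return float(mu)


@dataclass(frozen=True)
class TrialState:
    """Latent brain state of one stimulation trial (standardized predictors)."""

    fc: float = 0.0
    mu_power_l: float = 0.0
    mu_power_r: float = 0.0
    isi: float = 0.0
    phase_left: float = 0.0


# MEP wavelet geometry: a damped biphasic deflection centered 27 ms
# post-pulse; only its peak-to-peak inside (20, 40] ms is contractual.
_MEP_CENTER_S = 0.027
_MEP_TAU_S = 0.003
_MEP_FREQ_HZ = 120.0


def _mep_wavelet(t_rel: np.ndarray) -> np.ndarray:
    u = t_rel - _MEP_CENTER_S
    return np.exp(-(u / _MEP_TAU_S) ** 2) * np.sin(2 * np.pi * _MEP_FREQ_HZ * u)


def simulate_mep(trial_state: TrialState, model: MepModel,
                 rng: np.random.Generator, fs: float = 5000.0,
                 pre_s: float = 0.6, post_s: float = 0.1,
                 preinnervation_uv: float = 0.0,
                 preinnervation_freq: float = 20.0,
                 baseline_noise_uv: float = 0.5,
                 trial_index: int = 0, session_id: str = "S1",
                 subject_id: str = "sub") -> tuple[float, EmgTrial]:
    """Draw one MEP amplitude and render the surrounding EMG trial.

    Returns ``(amplitude_uv, EmgTrial)``.  The FDI trace contains a biphasic
    deflection whose peak-to-peak inside the 20-40 ms post-pulse window
    equals the drawn amplitude; an optional preinnervation sinusoid
    (``preinnervation_uv`` peak amplitude) is added to the pre-pulse segment
    of both muscles.
    """
    amplitude = float(np.exp(model.log_amplitude(trial_state, rng)))
    n = int(round((pre_s + post_s) * fs)) + 1
    t = np.arange(n) / fs - pre_s     # time relative to the pulse
    fdi = rng.normal(0.0, baseline_noise_uv, n)
    apb = rng.normal(0.0, baseline_noise_uv, n)

    wave = _mep_wavelet(t)
    in_win = (t > 0.020) & (t <= 0.040)
    p2p = float(wave[in_win].max() - wave[in_win].min())
    fdi = fdi + wave * (amplitude / p2p)

    if preinnervation_uv > 0:
        pre_seg = (t >= -0.505) & (t <= -0.005)
        burst = preinnervation_uv * np.sin(2 * np.pi * preinnervation_freq * t)
        fdi[pre_seg] += burst[pre_seg]
        apb[pre_seg] += burst[pre_seg]

    trial = EmgTrial(fdi=fdi, apb=apb, sample_rate=fs, pulse_time=pre_s,
                     trial_index=trial_index, session_id=session_id,
                     subject_id=subject_id)
    return amplitude, trial


# ---------------------------------------------------------------------------
# Direct trial-table synthesis for the statistical pipeline
# ---------------------------------------------------------------------------

def simulate_trial_table(n_subjects: int = 15, n_trials: int = 900,
                         condition_effect: float = 0.1,
                         intercept_sd: float = 0.05, slope_sd: float = 0.1,
                         b_powL: float = 0.0, b_powR: float = 0.0,
                         b_isi: float = 0.0,
                         b_cond_powL: float = 0.0, b_cond_powR: float = 0.0,
                         b_cond_isi: float = 0.0,
                         phase_amp: float = 0.0, phase_shift: float = 0.0,
                         sigma: float = 1.0, power_corr: float = 0.317,
                         rng: np.random.Generator | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Generate a response-scale trial table with planted effects.

    Emulates the statistical structure of a full multi-subject experiment
    (two sessions per subject, interleaved high/low conditions, correlated
    left/right μ-power, subject-level random intercept and condition slope)
    without simulating EEG.  The response is on the z-score scale; per-session
    z-scoring of real data leaves little between-subject intercept variance,
    hence the small ``intercept_sd`` default, while ``slope_sd`` on the order
    of the planted effect reproduces the observed fraction of subjects with
    a sign-flipped condition effect.
    """
    rng = rng or np.random.default_rng(seed)
    half = n_trials // 2
    rows = []
    cov = np.array([[1.0, power_corr], [power_corr, 1.0]])
    chol = np.linalg.cholesky(cov)
    for s in range(n_subjects):
        b0 = rng.normal(0.0, intercept_sd)
        b1 = rng.normal(0.0, slope_sd)
        cond = np.r_[np.zeros(half), np.ones(n_trials - half)]
        cond = rng.permutation(cond)
        powers = (chol @ rng.standard_normal((2, n_trials)))
        pow_l, pow_r = powers[0], powers[1]
        isi_raw = 2.0 + rng.exponential(scale=2.0, size=n_trials)
        isi = (isi_raw - isi_raw.min()) ** 0.25
        phi_c3 = rng.uniform(-np.pi, np.pi, n_trials)
        phi_c4 = rng.uniform(-np.pi, np.pi, n_trials)
        stplv = np.where(cond == 1, rng.beta(6, 3, n_trials),
                         rng.beta(3, 6, n_trials))
        arg = rng.uniform(-np.pi, np.pi, n_trials)
        y = (b0 + (condition_effect + b1) * cond
             + b_powL * pow_l + b_powR * pow_r + b_isi * isi
             + b_cond_powL * cond * pow_l + b_cond_powR * cond * pow_r
             + b_cond_isi * cond * isi
             + phase_amp * np.cos(phi_c3 + phase_shift)
             + rng.normal(0.0, sigma, n_trials))
        session = np.where(np.arange(n_trials) < n_trials // 2, "S1", "S2")
        rows.append(pd.DataFrame({
            "Subject": f"sub{s:02d}", "Session": session,
            "Condition": np.where(cond == 1, "high", "low"),
            "ResponseFDI": y, "MuPowerL": pow_l, "MuPowerR": pow_r,
            "ISI": isi, "phi_c3": phi_c3, "phi_c4": phi_c4,
            "stplv_rt": stplv, "istplv_rt": stplv * np.abs(np.sin(arg)),
        }))
    return pd.concat(rows, ignore_index=True)
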