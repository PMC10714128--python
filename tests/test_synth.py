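"""Generator contracts: coupling, waveforms, mixing, SNR, MEP synthesis."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from plvloop.connectivity import PhaseWindow, cstplv
from plvloop.emg import mep_amplitude, preinnervation_flag
from plvloop.phase import estimate_phase, resample_to_working_rate
from plvloop.spatial import C3_HJORTH, C4_HJORTH, apply_montage
from plvloop.synth import (MepModel, SynthConfig, SynthConfigError, TrialState,
                           mix_to_channels, one_over_f_noise, simulate_mep,
                           simulate_phase_pair, simulate_sources,
                           simulate_trial_table)


def _window_stplvs(theta, window=250):
    n = theta.shape[1] // window
    return np.array([
        cstplv(PhaseWindow(theta[0, i * window:(i + 1) * window],
                           theta[1, i * window:(i + 1) * window])).stplv
        for i in range(n)])


def test_coupling_strength_monotonically_raises_locking():
    medians = []
    for i, kappa in enumerate([0.0, 0.5, 1.0, 2.0, 5.0]):
        th = simulate_phase_pair(200 * 250, 1 / 500, 10.0, 12.0, kappa, 0.0,
                                 0.25, np.random.default_rng(10 + i))
        medians.append(np.median(_window_stplvs(th)))
    rho, _ = spearmanr([0, 0.5, 1, 2, 5], medians)
    assert rho > 0.9
    assert medians[0] < medians[-1]  # uncoupled clearly below kappa=5


def test_uncoupled_locking_below_strongly_coupled():
    th0 = simulate_phase_pair(200 * 250, 1 / 500, 10.0, 12.0, 0.0, 0.0, 0.25,
                              np.random.default_rng(1))
    th5 = simulate_phase_pair(200 * 250, 1 / 500, 10.0, 12.0, 5.0, 0.0, 0.25,
                              np.random.default_rng(1))
    assert np.median(_window_stplvs(th0)) < np.median(_window_stplvs(th5))


def test_strong_coupling_no_noise_locks_exactly():
    th = simulate_phase_pair(2000, 1 / 500, 10.0, 10.0, 500.0, 0.0, 0.0,
                             np.random.default_rng(2))
    # after transient, constant phase difference -> stPLV of any window = 1
    tail = th[:, 1000:]
    lv = cstplv(PhaseWindow(tail[0, -250:], tail[1, -250:]))
    assert lv.stplv == pytest.approx(1.0, abs=1e-6)


def test_planted_lag_is_recovered():
    lag = 0.8
    th = simulate_phase_pair(5000, 1 / 500, 10.0, 10.0, 300.0, lag, 0.0,
                             np.random.default_rng(3))
    d = np.angle(np.exp(1j * (th[0, -250:] - th[1, -250:])))
    # theta2 is pulled toward theta1 + lag, so theta1 - theta2 -> -lag
    assert np.mean(d) == pytest.approx(-lag, abs=0.05)


def test_sinusoid_purity_without_asymmetry():
    cfg = SynthConfig(duration=10.0, waveform_asymmetry=0.0, phase_noise=0.0)
    src = simulate_sources(cfg)
    spec = np.abs(np.fft.rfft(src.waves[0])) ** 2
    freqs = np.fft.rfftfreq(src.n_samples, 1 / cfg.sample_rate)
    fundamental = (freqs > 9.0) & (freqs < 11.0)
    assert spec[~fundamental].sum() / spec.sum() < 0.01


def test_asymmetry_adds_second_harmonic():
    cfg = SynthConfig(duration=10.0, waveform_asymmetry=0.4, phase_noise=0.0)
    src = simulate_sources(cfg)
    spec = np.abs(np.fft.rfft(src.waves[0])) ** 2
    freqs = np.fft.rfftfreq(src.n_samples, 1 / cfg.sample_rate)
    h2 = spec[(freqs > 19.0) & (freqs < 21.0)].sum()
    h1 = spec[(freqs > 9.0) & (freqs < 11.0)].sum()
    assert h2 / h1 == pytest.approx(0.4 ** 2, rel=0.05)


def test_identity_mixing_zero_noise_passes_sources_through():
    cfg = SynthConfig(duration=2.0, noise_rms_uv=0.0, source_amp_uv=1.0,
                      mixing=np.eye(2), channels=("C3", "C4"))
    src = simulate_sources(cfg)
    rec = mix_to_channels(src, cfg)
    assert np.array_equal(rec.channel("C3"), src.waves[0])
    assert np.array_equal(rec.channel("C4"), src.waves[1])


def test_mixing_dimension_mismatch_raises():
    with pytest.raises(SynthConfigError, match="rows"):
        SynthConfig(mixing=np.ones((3, 2)), channels=("C3", "C4"))


def test_invalid_frequency_rejected():
    with pytest.raises(SynthConfigError, match="μ band"):
        SynthConfig(mu_freq_left=20.0)


def test_common_source_locks_at_zero_after_hjorth():
    # one source volume-conducted into both hemisphere montages with
    # positive gains -> locking angle of the Hjorth pair concentrates at 0
    labels = C3_HJORTH.channels + C4_HJORTH.channels
    mixing = np.zeros((10, 2))
    mixing[0:5, 0] = [1.0, 0.4, 0.4, 0.4, 0.4]   # C3 region, source 1
    mixing[5:10, 0] = [0.8, 0.3, 0.3, 0.3, 0.3]  # C4 region, same source
    cfg = SynthConfig(duration=102.0, mixing=mixing, channels=labels,
                      noise_rms_uv=1.0, source_amp_uv=30.0, seed=5)
    src = simulate_sources(cfg)
    rec = mix_to_channels(src, cfg)
    c3 = resample_to_working_rate(apply_montage(rec, C3_HJORTH), 5000.0)
    c4 = resample_to_working_rate(apply_montage(rec, C4_HJORTH), 5000.0)
    from scipy.signal import hilbert

    p3 = np.angle(hilbert(c3))
    p4 = np.angle(hilbert(c4))
    args = []
    for i in range(100):
        sl = slice(500 + i * 250, 500 + (i + 1) * 250)
        args.append(cstplv(PhaseWindow(p3[sl], p4[sl])).arg)
    mean_arg = np.angle(np.mean(np.exp(1j * np.array(args))))
    assert abs(mean_arg) < 0.2


def test_noise_only_has_low_locking():
    cfg = SynthConfig(duration=52.0, mixing=np.zeros((2, 2)),
                      channels=("C3", "C4"), seed=6, source_amp_uv=1.0)
    src = simulate_sources(cfg)
    rec = mix_to_channels(src, cfg)
    from scipy.signal import hilbert, filtfilt, firwin

    taps = firwin(129, [8, 15], pass_zero=False, fs=500.0)
    vals = []
    for i in range(100):
        sl = slice(i * 250, (i + 2) * 250)
        p = []
        for ch in ("C3", "C4"):
            x = resample_to_working_rate(rec.channel(ch), 5000.0)[sl]
            p.append(np.angle(hilbert(filtfilt(taps, 1, x)))[-250:])
        vals.append(cstplv(PhaseWindow(p[0], p[1])).stplv)
    assert np.median(vals) < 0.5


def test_snr_calibration_round_trip():
    from plvloop.analysis import mu_snr

    cfg = SynthConfig(duration=60.0, snr_db=10.0, seed=3,
                      mixing=np.eye(2), channels=("C3", "C4"))
    rec = mix_to_channels(simulate_sources(cfg), cfg)
    assert mu_snr(rec.channel("C3"), 5000.0) == pytest.approx(10.0, abs=2.0)


def test_pure_one_over_f_noise_has_no_mu_peak():
    from plvloop.analysis import mu_snr

    vals = [mu_snr(one_over_f_noise(120 * 500, 500.0, 1.0, 10.0,
                                    np.random.default_rng(s)), 500.0)
            for s in range(25)]
    assert np.all(np.abs(vals) < 2.5)
    assert abs(np.median(vals)) < 1.0


def test_doubling_mu_amplitude_adds_six_db():
    from plvloop.analysis import mu_snr

    cfg1 = SynthConfig(duration=60.0, seed=9, source_amp_uv=3.0,
                       phase_noise=0.1, mixing=np.eye(2),
                       channels=("C3", "C4"))
    cfg2 = SynthConfig(duration=60.0, seed=9, source_amp_uv=6.0,
                       phase_noise=0.1, mixing=np.eye(2),
                       channels=("C3", "C4"))
    snr1 = mu_snr(mix_to_channels(simulate_sources(cfg1), cfg1).channel("C3"),
                  5000.0)
    snr2 = mu_snr(mix_to_channels(simulate_sources(cfg2), cfg2).channel("C3"),
                  5000.0)
    assert snr2 - snr1 == pytest.approx(20 * np.log10(2), abs=1.5)


def test_clean_sources_phase_estimates_match_ground_truth():
    """High-SNR μ sources: estimator within 15 deg at >= 95% of timepoints."""
    errs = []
    for trial in range(60):
        cfg = SynthConfig(duration=3.0, snr_db=40.0, seed=300 + trial,
                          mixing=np.eye(2), channels=("C3", "C4"))
        src = simulate_sources(cfg)
        rec = mix_to_channels(src, cfg)
        x = resample_to_working_rate(rec.channel("C3"), 5000.0)
        gt = src.phases[0][::10]
        k = x.size - 1
        est = estimate_phase(x[k - 499:k + 1])
        errs.append(np.degrees(np.angle(np.exp(1j * (est - gt[k])))))
    frac = np.mean(np.abs(errs) <= 15.0)
    assert frac >= 0.95


def test_generation_is_bit_reproducible():
    cfg1 = SynthConfig(duration=2.5, seed=77)
    cfg2 = SynthConfig(duration=2.5, seed=77)
    r1 = mix_to_channels(simulate_sources(cfg1), cfg1)
    r2 = mix_to_channels(simulate_sources(cfg2), cfg2)
    assert np.array_equal(r1.data, r2.data)
    t1 = simulate_trial_table(n_subjects=2, n_trials=40, seed=5)
    t2 = simulate_trial_table(n_subjects=2, n_trials=40, seed=5)
    assert t1.equals(t2)


# -- MEP synthesis ----------------------------------------------------------

def test_all_slopes_zero_gives_exact_intercept(rng):
    model = MepModel(intercept=np.log(200.0), sigma=0.0)
    amp, _ = simulate_mep(TrialState(), model, rng)
    assert amp == pytest.approx(200.0, rel=1e-12)


def test_fc_slope_shifts_log_amplitude_by_construction(rng):
    model = MepModel(b_fc=0.3, sigma=0.0)
    hi, _ = simulate_mep(TrialState(fc=1.0), model, rng)
    lo, _ = simulate_mep(TrialState(fc=-1.0), model, rng)
    assert np.log(hi) - np.log(lo) == pytest.approx(0.6, abs=1e-12)


def test_negative_sigma_rejected():
    with pytest.raises(SynthConfigError):
        MepModel(sigma=-0.1)


def test_mep_amplitude_round_trip(rng):
    model = MepModel(intercept=np.log(400.0), sigma=0.3)
    for _ in range(10):
        amp, trial = simulate_mep(TrialState(), model, rng)
        assert mep_amplitude(trial) == pytest.approx(amp, rel=0.01)


def test_injected_preinnervation_is_flagged(rng):
    model = MepModel(sigma=0.0)
    _, clean = simulate_mep(TrialState(), model, rng)
    _, dirty = simulate_mep(TrialState(), model, rng, preinnervation_uv=60.0)
    assert not preinnervation_flag(clean)
    assert preinnervation_flag(dirty)
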