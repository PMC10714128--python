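"""Predictors, model designs, mixed fits, responder split, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from plvloop.analysis import (build_design, fit_model, isi_covariate, lr_test,
                              phase_concentration, phase_histogram_2d,
                              posthoc_phase, posthoc_stplv, prestim_mu_power,
                              responder_split, vc_diagnostics, zscore_within)
from plvloop.synth import simulate_trial_table

FS = 5000.0


def _pulse_signal(amp=10.0, freq=10.0, dur=1.5, noise=0.0, seed=0):
    t = np.arange(int(dur * FS)) / FS
    x = amp * np.cos(2 * np.pi * freq * t)
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, t.size)
    return x, dur - 0.2  # pulse 0.2 s before the end


# -- predictors -------------------------------------------------------------

def test_doubling_amplitude_quadruples_power():
    x1, pt = _pulse_signal(amp=10.0)
    x2, _ = _pulse_signal(amp=20.0)
    lp1 = prestim_mu_power(x1, pt, FS)
    lp2 = prestim_mu_power(x2, pt, FS)
    assert lp2 - lp1 == pytest.approx(np.log(4.0), abs=1e-9)


def test_out_of_band_signal_leaks_little():
    x10, pt = _pulse_signal(freq=10.0)
    x30, _ = _pulse_signal(freq=30.0)
    p10 = np.exp(prestim_mu_power(x10, pt, FS))
    p30 = np.exp(prestim_mu_power(x30, pt, FS))
    assert p30 <= 0.01 * p10


def test_prestim_power_matches_brute_force_periodogram():
    x, pt = _pulse_signal(noise=2.0, seed=1)
    got = prestim_mu_power(x, pt, FS)
    # brute-force oracle: detrend, mean-removed one-sided periodogram,
    # trapezoidal band integration
    i0 = int(np.ceil((pt - 0.505) * FS - 1e-9))
    i1 = int(np.floor((pt - 0.005) * FS + 1e-9))
    seg = x[i0:i1 + 1].copy()
    k = np.arange(seg.size)
    a, b = np.polyfit(k, seg, 1)
    seg = seg - (a * k + b)
    seg = seg - seg.mean()
    spec = np.fft.rfft(seg)
    psd = 2.0 * np.abs(spec) ** 2 / (FS * seg.size)
    psd[0] /= 2.0
    if seg.size % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(seg.size, 1 / FS)
    sel = (freqs >= 8.0) & (freqs <= 13.0)
    oracle = np.log(np.trapezoid(psd[sel], freqs[sel]))
    assert got == pytest.approx(oracle, rel=1e-9)


def test_zscore_within_sessions():
    vals = np.r_[np.random.default_rng(0).normal(5, 2, 50),
                 np.random.default_rng(1).normal(-3, 0.5, 60)]
    groups = np.r_[np.zeros(50), np.ones(60)]
    z = zscore_within(vals, groups)
    for g in (0, 1):
        assert z[groups == g].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[groups == g].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_posthoc_phase_tracks_clean_source():
    for phase0 in (0.0, 1.0, -2.0):
        t = np.arange(int(1.5 * FS)) / FS
        x = 15.0 * np.cos(2 * np.pi * 10.0 * t + phase0)
        pt = 1.3
        est = posthoc_phase(x, pt, FS)
        true = (2 * np.pi * 10.0 * (pt - 0.005) + phase0) % (2 * np.pi)
        err = np.degrees(np.angle(np.exp(1j * (est - true))))
        assert abs(err) < 10.0


def test_posthoc_phase_amplitude_invariant():
    x, pt = _pulse_signal(noise=1.0, seed=2)
    assert posthoc_phase(10 * x, pt, FS) == pytest.approx(
        posthoc_phase(x, pt, FS), abs=1e-9)


def test_posthoc_stplv_constant_difference_is_one():
    t = np.arange(int(2.0 * FS)) / FS
    x1 = 10.0 * np.cos(2 * np.pi * 10 * t)
    x2 = 10.0 * np.cos(2 * np.pi * 10 * t - 1.0)
    lv = posthoc_stplv(x1, x2, 1.8, FS)
    assert lv.stplv == pytest.approx(1.0, abs=1e-3)


def test_posthoc_stplv_independent_noise_is_low():
    rng = np.random.default_rng(4)
    vals = []
    for _ in range(20):
        x1 = rng.normal(0, 10, int(2.0 * FS))
        x2 = rng.normal(0, 10, int(2.0 * FS))
        vals.append(posthoc_stplv(x1, x2, 1.8, FS).stplv)
    assert np.median(vals) < 0.5


def test_isi_covariate_examples():
    isi = np.array([2.0, 3.0, 18.0])
    cov = isi_covariate(isi)
    assert cov[0] == 0.0
    assert cov[2] == pytest.approx(2.0)  # (18-2)^(1/4)
    assert np.all(np.diff(cov) > 0)


# -- designs and fits -------------------------------------------------------

def test_primary_design_columns_and_coding():
    tb = simulate_trial_table(n_subjects=2, n_trials=10, seed=0)
    spec = build_design(tb, "primary")
    assert spec.terms == ["Condition"]
    assert list(spec.exog_re.columns) == ["Intercept", "Condition"]
    assert set(np.unique(spec.X["Condition"])) == {0.0, 1.0}
    high = tb["Condition"] == "high"
    assert np.array_equal(spec.X["Condition"].to_numpy(),
                          high.astype(float).to_numpy())


def test_two_trial_design_matches_hand_matrix():
    tb = pd.DataFrame({
        "Subject": ["s1", "s1"], "Session": ["S1", "S1"],
        "Condition": ["low", "high"], "ResponseFDI": [0.1, -0.2],
        "MuPowerL": [1.0, 2.0], "MuPowerR": [0.5, -0.5],
        "ISI": [0.0, 1.0],
    })
    spec = build_design(tb, "summary")
    hand = {
        "Condition": [0.0, 1.0], "ISI": [0.0, 1.0],
        "MuPowerR": [0.5, -0.5], "MuPowerL": [1.0, 2.0],
        "Condition:ISI": [0.0, 1.0], "Condition:MuPowerL": [0.0, 2.0],
        "Condition:MuPowerR": [0.0, -0.5], "ISI:MuPowerL": [0.0, 2.0],
        "MuPowerR:MuPowerL": [0.5, -1.0],
    }
    for term, col in hand.items():
        assert np.allclose(spec.X[term], col), term


def test_circular_pair_always_grouped():
    tb = simulate_trial_table(n_subjects=2, n_trials=10, seed=0)
    spec = build_design(tb, "summary_phase")
    assert spec.term_groups["PhiC3"] == ["cosPhiC3", "sinPhiC3"]
    assert spec.term_groups["PhiC3:MuPowerL"] == \
        ["cosPhiC3:MuPowerL", "sinPhiC3:MuPowerL"]


def test_missing_column_error_names_it():
    tb = simulate_trial_table(n_subjects=2, n_trials=10, seed=0)
    with pytest.raises(KeyError, match="stplv_ph"):
        build_design(tb, "stplv")
    with pytest.raises(KeyError, match="unknown formula"):
        build_design(tb, "nope")


def test_planted_interaction_recovered_in_summary_model():
    tb = simulate_trial_table(seed=21, n_subjects=10, n_trials=400,
                              condition_effect=0.1, b_powL=0.12,
                              b_cond_powL=0.3)
    fit = fit_model(build_design(tb, "summary"), compute_aic=False)
    assert fit.params["Condition:MuPowerL"] == pytest.approx(0.3, abs=0.08)
    assert fit.wald.loc["Condition:MuPowerL", "p"] < 0.01
    assert fit.params["MuPowerL"] == pytest.approx(0.12, abs=0.08)


def test_aic_prefers_generating_model():
    tb = simulate_trial_table(seed=22, n_subjects=8, n_trials=300,
                              condition_effect=0.3)
    f_prim = fit_model(build_design(tb, "primary"))
    f_sum = fit_model(build_design(tb, "summary"))
    # no power/ISI effects planted: the simpler generating model wins on AIC
    assert f_prim.aic < f_sum.aic
    stat, df, p = lr_test(f_prim, f_sum)
    assert df == 8
    assert p > 0.001  # extra terms do not significantly improve the model


def test_responder_split_oracles():
    n = 450
    hi = np.full(n, 1.0) + np.arange(n) * 1e-4
    lo = np.full(n, -1.0) - np.arange(n) * 1e-4
    tb = pd.DataFrame({
        "Subject": ["s1"] * (2 * n), "Session": ["S1"] * n + ["S2"] * n,
        "Condition": ["high"] * n + ["low"] * n,
        "ResponseFDI": np.r_[hi, lo],
    })
    subj, sess = responder_split(tb)
    assert subj.loc[0, "p"] < 1e-10
    assert bool(subj.loc[0, "responder"])

    tb2 = tb.assign(ResponseFDI=np.zeros(2 * n))
    subj2, _ = responder_split(tb2)
    assert subj2.loc[0, "p"] >= 0.4
    assert not bool(subj2.loc[0, "responder"])


def test_phase_histogram_single_bin_and_conservation(rng):
    tb = simulate_trial_table(n_subjects=3, n_trials=100, seed=3)
    hist = phase_histogram_2d(tb)
    n_high = (tb["Condition"] == "high").sum()
    n_low = (tb["Condition"] == "low").sum()
    assert hist.counts_high.sum() == n_high
    assert hist.counts_low.sum() == n_low
    assert hist.difference.sum() == n_high - n_low

    tb0 = tb.copy()
    tb0["phi_c3"] = 0.0
    tb0["phi_c4"] = 0.0
    h0 = phase_histogram_2d(tb0)
    assert (h0.counts_high > 0).sum() == 1


def test_uniform_phases_fill_bins_multinomially(rng):
    n = 13500
    tb = pd.DataFrame({
        "Condition": ["high"] * n,
        "phi_c3": rng.uniform(-np.pi, np.pi, n),
        "phi_c4": rng.uniform(-np.pi, np.pi, n),
    })
    hist = phase_histogram_2d(tb, bins=12)
    expected = n / 144
    sd = np.sqrt(n * (1 / 144) * (1 - 1 / 144))
    assert np.all(np.abs(hist.counts_high - expected) <= 5 * sd)


def test_phase_concentration_extremes(rng):
    assert phase_concentration(np.zeros(100)) == 1.0
    assert phase_concentration(np.full(100, np.pi)) == pytest.approx(1.0)
    assert phase_concentration(np.full(100, np.pi / 2)) == pytest.approx(-1.0)
    u = rng.uniform(-np.pi, np.pi, 10_000)
    assert abs(phase_concentration(u)) < 3 / np.sqrt(10_000)


def test_vc_diagnostics_table(rng):
    diag = vc_diagnostics({"high": np.zeros(50),
                           "low": rng.uniform(-np.pi, np.pi, 500)})
    assert diag.loc["high", "concentration"] == 1.0
    assert abs(diag.loc["low", "concentration"]) < 0.2
    assert diag.loc["low", "hist"].sum() == 500
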