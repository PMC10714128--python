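"""End-to-end simulated sessions: phase dynamics -> trigger loop -> EMG -> table.

Ties the generator, trigger engine and EMG processing together at the phase
level: the interhemispheric coupling strength follows a two-state telegraph
process (uncoupled vs. strongly coupled epochs), the loop triggers on the
resulting stPLV fluctuations, and each condition pulse evokes an MEP whose
log amplitude depends on the planted brain-state model.  This is the
fastest faithful path to a full trial table with known ground truth; the
EEG-level path (synthesize electrodes, stream phases through the estimator)
is available via :func:`plvloop.phase.stream_phases` and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import emg as emg_mod
from .analysis import isi_covariate
from .loop import (BlockResult, CriteriaBuffer, LoopParams,
                   init_buffer_from_rest, make_condition_sequence, run_block)
from .synth import MepModel, TrialState, simulate_mep, simulate_phase_pair


def telegraph_kappa(n: int, dt: float, kappa_low: float, kappa_high: float,
                    mean_epoch_s: float, rng: np.random.Generator
                    ) -> np.ndarray:
    """Two-state coupling strength switching with exponential epoch lengths."""
    k = np.empty(n)
    state = bool(rng.integers(2))
    i = 0
    while i < n:
        length = max(1, int(rng.exponential(mean_epoch_s) / dt))
        k[i:i + length] = kappa_high if state else kappa_low
        state = not state
        i += length
    return k


@dataclass
class SessionResult:
    """One simulated closed-loop session with planted ground truth."""

    table: pd.DataFrame            # analysis-ready trial table
    block: BlockResult
    buffer: CriteriaBuffer
    rest_mean: float               # resting stPLV distribution moments
    rest_sd: float
    ground_truth: dict = field(default_factory=dict)


def simulate_session(seed: int = 0, n_low: int = 30, n_high: int = 30,
                     mep_model: MepModel | None = None,
                     subject_id: str = "sub00", session_id: str = "S1",
                     rate: float = 500.0, freq_left: float = 10.0,
                     freq_right: float = 12.0, phase_noise: float = 0.25,
                     kappa_high: float = 15.0, mean_epoch_s: float = 2.0,
                     block_duration_s: float | None = None,
                     preinnervation_fraction: float = 0.0,
                     params: LoopParams | None = None) -> SessionResult:
    """Simulate rest (criteria acquisition) plus one stimulation block.

    The MEP model's ``fc`` predictor receives the deciding stPLV
    standardized against the resting distribution; ``mu_power_l/r`` are
    correlated standard-normal draws; ``isi`` is the transformed covariate.
    """
    mep_model = mep_model or MepModel(sigma=0.5)
    params = params or LoopParams(rate=rate, trigger_latency=0.0)
    root = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(5)]
    r_rest, r_block, r_seq, r_state, r_emg = rngs
    dt = 1.0 / rate

    # resting state: 1000 non-overlapping windows of `window` samples
    n_rest = 1000 * params.window
    k_rest = telegraph_kappa(n_rest, dt, 0.0, kappa_high, mean_epoch_s, r_rest)
    th = simulate_phase_pair(n_rest, dt, freq_left, freq_right, k_rest,
                             0.0, phase_noise, r_rest)
    buffer = init_buffer_from_rest(th[0], th[1], window=params.window)
    rest_mean = float(buffer.values.mean())
    rest_sd = float(buffer.values.std(ddof=1))

    # stimulation block
    n_trials = n_low + n_high
    dur = block_duration_s or (5.0 + 6.0 * n_trials)
    n_blk = int(round(dur * rate))
    k_blk = telegraph_kappa(n_blk, dt, 0.0, kappa_high, mean_epoch_s, r_block)
    th_b = simulate_phase_pair(n_blk, dt, freq_left, freq_right, k_blk,
                               0.0, phase_noise, r_block)
    sequence = make_condition_sequence(r_seq, n_low=n_low, n_high=n_high)
    block = run_block(th_b[0], th_b[1], sequence, buffer, params)

    rows = []
    cov = np.array([[1.0, 0.317], [0.317, 1.0]])
    chol = np.linalg.cholesky(cov)
    cond_events = block.condition_events
    raw_isis = np.array([ev.isi for ev in cond_events])
    isi_cov = isi_covariate(raw_isis) if len(cond_events) else np.array([])
    for j, ev in enumerate(cond_events):
        pl, pr = chol @ r_state.standard_normal(2)
        fc_std = (ev.deciding_stplv - rest_mean) / rest_sd
        phi_l = float(ev.phase_window.phi1[-1])
        phi_r = float(ev.phase_window.phi2[-1])
        state = TrialState(fc=fc_std, mu_power_l=float(pl),
                           mu_power_r=float(pr), isi=float(isi_cov[j]),
                           phase_left=phi_l)
        pre_uv = 60.0 if r_emg.uniform() < preinnervation_fraction else 0.0
        amp, trial = simulate_mep(
            state, mep_model, r_emg, preinnervation_uv=pre_uv,
            trial_index=j, session_id=session_id, subject_id=subject_id)
        rows.append({
            "Subject": subject_id, "Session": session_id, "trial": j,
            "time": ev.time, "Condition": ev.kind,
            "stplv_rt": ev.deciding_stplv, "fc_std": fc_std,
            "MuPowerL": float(pl), "MuPowerR": float(pr),
            "isi_raw": ev.isi, "ISI": float(isi_cov[j]),
            "phi_c3": phi_l, "phi_c4": phi_r,
            "mep_uv": amp,
            "preinnervated": emg_mod.preinnervation_flag(trial),
        })
    table = pd.DataFrame(rows)
    if len(table):
        kept = table[~table["preinnervated"]].reset_index(drop=True)
        kept = emg_mod.transform_table(kept)
    else:
        kept = table
    return SessionResult(table=kept, block=block, buffer=buffer,
                         rest_mean=rest_mean, rest_sd=rest_sd,
                         ground_truth={"kappa_high": kappa_high,
                                       "seed": seed,
                                       "mep_model": mep_model,
                                       "n_dropped": int(len(table) - len(kept))})
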