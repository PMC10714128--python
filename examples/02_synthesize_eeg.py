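"""Generate synthetic μ-band EEG with planted coupling and check its SNR.

Two noisy 10/12 Hz phase oscillators are mixed onto 10-20 electrodes with
1/f background noise; the left-μ periodogram peak is planted at a chosen
height (dB) over the fitted 1/f background -- the same statistic used to
screen participants for a usable μ-rhythm.
"""

import numpy as np

from plvloop import SynthConfig, mix_to_channels, simulate_sources
from plvloop.analysis import mu_snr
from plvloop.edf import write_edf

cfg = SynthConfig(duration=30.0, snr_db=10.0, coupling_strength=5.0,
                  coupling_lag=0.6, seed=1)
sources = simulate_sources(cfg)
rec = mix_to_channels(sources, cfg)

snr = mu_snr(rec.channel("C3"), rec.sample_rate)
print(f"channels: {rec.labels}")
print(f"duration: {rec.duration:.0f} s at {rec.sample_rate:.0f} Hz")
print(f"planted u-peak SNR: {cfg.snr_db:.1f} dB, measured: {snr:.1f} dB")

write_edf("scratch_recording.edf", rec, record_duration=0.1)
print("wrote scratch_recording.edf (uV, 16-bit EDF)")
print()
print("The measured SNR recovers the planted value because the generator "
      "calibrates the source amplitude against the same Welch/1-f-fit "
      "statistic the screening uses; 5 dB is the study's inclusion bar.")
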