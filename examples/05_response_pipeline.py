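"""From raw EMG trials to the analysis response variable.

MEP amplitude is the peak-to-peak of the FDI trace 20-40 ms post-pulse.
Trials with >50 uV activity in the detrended pre-pulse EMG of either hand
muscle are rejected (preinnervation).  Surviving amplitudes are transformed:
fourth root -> centered 301-trial moving-median removal -> per-session
z-score.
"""

import numpy as np

from plvloop import (MepModel, TrialState, mep_amplitude, preinnervation_flag,
                     simulate_mep, transform_responses)

rng = np.random.default_rng(5)
model = MepModel(intercept=np.log(400.0), sigma=0.5)

amps, flags = [], 0
for j in range(600):
    pre = 60.0 if rng.uniform() < 0.15 else 0.0   # 15% preinnervated
    amp, trial = simulate_mep(TrialState(), model, rng, preinnervation_uv=pre)
    if preinnervation_flag(trial):
        flags += 1
        continue
    amps.append(mep_amplitude(trial))

rs = transform_responses(np.array(amps))
drift = rs.alpha - rs.beta   # the moving median that was subtracted

print(f"trials simulated  : 600, rejected for preinnervation: {flags}")
print(f"raw MEP (uV)      : median {np.median(rs.raw):.0f}, "
      f"range {rs.raw.min():.0f}-{rs.raw.max():.0f}")
print(f"fourth root alpha : median {np.median(rs.alpha):.2f}")
print(f"moving median     : spans {drift.min():.2f}-{drift.max():.2f}")
print(f"response z-score  : mean {rs.response.mean():.2e}, "
      f"sd {rs.response.std(ddof=1):.3f}")
print()
print("The response column is exactly mean-0/SD-1 within the session; the "
      "fourth root tames the lognormal amplitude tail and the moving "
      "median removes slow excitability drifts before z-scoring.")
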