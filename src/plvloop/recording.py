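"""In-memory container for sampled multichannel EEG/EMG data.

All signal amplitudes in this package are microvolts (μV) and all times are
seconds relative to the start of the recording, unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 10–20 channel labels used by the default synthetic montage, in order.
DEFAULT_EEG_CHANNELS = (
    "C3", "FC1", "FC5", "CP1", "CP5",
    "C4", "FC2", "FC6", "CP2", "CP6",
)

#: Label prefixes that mark EMG channels in a mixed recording.
EMG_PREFIXES = ("EMG",)


@dataclass
class MultichannelRecording:
    """Sampled EEG (and optionally EMG) matrix with rate and channel labels.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)`` in μV.
    sample_rate:
        Sampling rate in Hz.
    labels:
        One label per channel (10–20 names for EEG, ``EMG_*`` for EMG).
    units:
        Physical unit of ``data``; only ``"uV"`` is supported.
    """

    data: np.ndarray
    sample_rate: float
    labels: list[str]
    units: str = "uV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if self.units != "uV":
            raise ValueError(f"unsupported units {self.units!r}; expected 'uV'")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the trace of a single channel by label."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not present (have {self.labels})"
            ) from None
        return self.data[idx]

    def has_channel(self, label: str) -> bool:
        return label in self.labels

    @property
    def eeg_labels(self) -> list[str]:
        return [l for l in self.labels if not l.startswith(EMG_PREFIXES)]

    @property
    def emg_labels(self) -> list[str]:
        return [l for l in self.labels if l.startswith(EMG_PREFIXES)]

    def time_to_index(self, t: float) -> int:
        """Index of the sample at time ``t`` (rounded to nearest sample)."""
        return int(round(t * self.sample_rate))
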