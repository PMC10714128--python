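"""Hjorth (surface-Laplacian) spatial montages.

A Hjorth montage isolates local activity under a center electrode by
subtracting the mean of its (typically four) nearest neighbors:
weight +1 on the center and -1/4 on each neighbor.  The weights sum to
zero, so any signal common to all five electrodes cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import MultichannelRecording


@dataclass(frozen=True)
class Montage:
    """Zero-sum weighted electrode combination."""

    name: str
    center: str
    neighbors: tuple[str, ...]
    center_weight: float = 1.0
    neighbor_weight: float | None = None  # default: -center/len(neighbors)
    #: True when the neighbor set is an assumption (e.g. the premotor and
    #: occipital control montages) rather than an established definition;
    #: propagated into output metadata so results flag it.
    assumed: bool = False

    def __post_init__(self) -> None:
        if not self.neighbors:
            raise ValueError("montage needs at least one neighbor")
        if self.center in self.neighbors:
            raise ValueError("center electrode cannot be its own neighbor")
        if len(set(self.neighbors)) != len(self.neighbors):
            raise ValueError("duplicate neighbor labels")
        if self.neighbor_weight is None:
            object.__setattr__(
                self, "neighbor_weight",
                -self.center_weight / len(self.neighbors),
            )
        total = self.center_weight + len(self.neighbors) * self.neighbor_weight
        if abs(total) > 1e-12:
            raise ValueError(
                f"montage weights must sum to zero (got {total:g})"
            )

    @property
    def channels(self) -> tuple[str, ...]:
        return (self.center,) + self.neighbors


def hjorth(center: str, neighbors: tuple[str, ...],
           name: str | None = None, assumed: bool = False) -> Montage:
    """Standard Hjorth montage: +1 center, -1/len(neighbors) each neighbor."""
    return Montage(name=name or f"{center}-Hjorth", center=center,
                   neighbors=neighbors, assumed=assumed)


#: C3-Hjorth over left sensorimotor cortex, C4-Hjorth mirrored on the right.
C3_HJORTH = hjorth("C3", ("FC1", "FC5", "CP1", "CP5"))
C4_HJORTH = hjorth("C4", ("FC2", "FC6", "CP2", "CP6"))

# Premotor and occipital control montages.  The four diagonal 10-20/10-10
# neighbors of each center are an assumption (hence ``assumed=True``) and
# user-overridable in the config file.
ASSUMED_CONTROL_MONTAGES = {
    "F3-Hjorth": hjorth("F3", ("AF3", "F1", "F5", "FC3"), assumed=True),
    "FC3-Hjorth": hjorth("FC3", ("F3", "FC1", "FC5", "C3"), assumed=True),
    "F4-Hjorth": hjorth("F4", ("AF4", "F2", "F6", "FC4"), assumed=True),
    "FC4-Hjorth": hjorth("FC4", ("F4", "FC2", "FC6", "C4"), assumed=True),
    "O1-Hjorth": hjorth("O1", ("PO3", "PO7", "Oz", "P5"), assumed=True),
    "O2-Hjorth": hjorth("O2", ("PO4", "PO8", "Oz", "P6"), assumed=True),
}


def apply_montage(recording: MultichannelRecording,
                  montage: Montage) -> np.ndarray:
    """Spatially filter a recording down to a single Hjorth trace (μV).

    output[k] = center_weight * center[k] + neighbor_weight * sum(neighbors[k])

    Raises
    ------
    KeyError
        If any montage electrode is missing from the recording, naming it.
    """
    for label in montage.channels:
        if not recording.has_channel(label):
            raise KeyError(
                f"montage {montage.name!r} requires channel {label!r}, "
                f"which is not in the recording"
            )
    out = montage.center_weight * recording.channel(montage.center)
    acc = np.zeros_like(out)
    for label in montage.neighbors:
        acc += recording.channel(label)
    return out + montage.neighbor_weight * acc
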