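"""Single-trial phase-locking between two phase sequences.

The single-trial phase-locking value (stPLV) of a window of instantaneous
phases ``phi1[k]``, ``phi2[k]`` (k = 1..N) is the magnitude of the mean
unit-length phasor of the phase differences::

    cstPLV = (1/N) * sum_k exp(i * (phi1[k] - phi2[k]))
    stPLV  = |cstPLV|
    istPLV = |Im cstPLV|

stPLV is ~1 when the two signals keep a consistent phase difference within
the window and ~0 when the difference is inconsistent.  istPLV discards
locking at 0/180 deg phase shift and therefore the component most easily
inflated by volume conduction (a single source seen by both electrodes).
The complex average itself (cstPLV) retains the locking angle, which is what
the volume-conduction diagnostics inspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default window length: 500 ms of phase estimates at 500 Hz.
DEFAULT_N = 250


@dataclass(frozen=True)
class PhaseWindow:
    """Two aligned instantaneous-phase sequences ending at ``end_time``."""

    phi1: np.ndarray
    phi2: np.ndarray
    end_time: float = 0.0

    def __post_init__(self) -> None:
        phi1 = np.asarray(self.phi1, dtype=float)
        phi2 = np.asarray(self.phi2, dtype=float)
        object.__setattr__(self, "phi1", phi1)
        object.__setattr__(self, "phi2", phi2)
        if phi1.ndim != 1 or phi2.ndim != 1:
            raise ValueError("phase sequences must be 1-D")
        if phi1.shape != phi2.shape:
            raise ValueError(
                f"length mismatch: {phi1.shape[0]} vs {phi2.shape[0]}"
            )
        if phi1.shape[0] < 2:
            raise ValueError("need at least 2 phase samples")
        for name, phi in (("phi1", phi1), ("phi2", phi2)):
            bad = np.flatnonzero(~np.isfinite(phi))
            if bad.size:
                raise ValueError(
                    f"non-finite phase in {name} at index {bad[0]}"
                )

    @property
    def n(self) -> int:
        return self.phi1.shape[0]


@dataclass(frozen=True)
class LockingValue:
    """Complex mean phasor of a phase window and its derived statistics."""

    c: complex
    stplv: float = field(init=False)
    istplv: float = field(init=False)
    arg: float = field(init=False)

    def __post_init__(self) -> None:
        c = complex(self.c)
        object.__setattr__(self, "c", c)
        # numpy's hypot keeps |c| bit-identical with batch recomputations
        # of the form np.abs(np.mean(np.exp(1j*d)))
        object.__setattr__(self, "stplv", float(np.abs(np.complex128(c))))
        object.__setattr__(self, "istplv", abs(c.imag))
        # angle in (-pi, pi]; ties at -pi mapped to +pi for stable histograms
        a = float(np.angle(c))
        if a == -np.pi:
            a = np.pi
        object.__setattr__(self, "arg", a)


def cstplv(window: PhaseWindow) -> LockingValue:
    """Complex single-trial PLV of a phase window.

    The phase-difference convention is channel 1 minus channel 2
    (C3-Hjorth minus C4-Hjorth in the standard montage pair), so a positive
    locking angle means channel 1 leads.
    """
    d = window.phi1 - window.phi2
    c = np.exp(1j * d).mean()
    return LockingValue(c=c)


def stplv_of(phi1: np.ndarray, phi2: np.ndarray) -> float:
    """Convenience: stPLV of two raw phase arrays."""
    return cstplv(PhaseWindow(phi1=phi1, phi2=phi2)).stplv
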