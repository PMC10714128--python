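"""Closed-loop trigger engine with dynamic empirical criteria.

The system waits for the current condition (low or high interhemispheric
phase-locking), polling the most recent 500 ms of phase estimates every
~100 ms.  The criteria are the lower and upper quartiles of a FIFO of the
last 1000 stPLVs, so they track slow drifts in the subject's connectivity
distribution.  A pulse is triggered when the current stPLV falls strictly
below the lower quartile (low condition) or strictly above the upper
quartile (high condition).  Every pulse is followed by a minimum
inter-stimulus interval during which no stPLVs are computed (post-pulse
blanking); if no pulse occurs for ``timeout`` seconds a timeout pulse keeps
the subject habituated without consuming a condition.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .connectivity import DEFAULT_N, PhaseWindow, cstplv

BUFFER_CAPACITY = 1000


class CriteriaBuffer:
    """FIFO of the most recent stPLVs with quartile condition criteria.

    Quartiles use linear interpolation between order statistics (numpy's
    default); the convention is recorded in ``quantile_method`` for the log.
    """

    quantile_method = "linear"

    def __init__(self, values, capacity: int = BUFFER_CAPACITY):
        vals = [float(v) for v in values]
        if len(vals) != capacity:
            raise ValueError(
                f"buffer must be initialized with exactly {capacity} values "
                f"(got {len(vals)})")
        if not all(np.isfinite(vals)):
            raise ValueError("buffer values must be finite")
        self.capacity = capacity
        self._values: deque[float] = deque(vals, maxlen=capacity)
        self._recompute()

    def _recompute(self) -> None:
        arr = np.fromiter(self._values, dtype=float)
        self.q_low = float(np.quantile(arr, 0.25))
        self.q_high = float(np.quantile(arr, 0.75))

    def __len__(self) -> int:
        return len(self._values)

    @property
    def values(self) -> np.ndarray:
        return np.fromiter(self._values, dtype=float)

    def update(self, stplv: float) -> None:
        """Evict the oldest value, append the new one, recompute quartiles.

        Callers must compare against the *old* criteria before updating;
        the engine below does so.
        """
        if not np.isfinite(stplv):
            raise ValueError(f"rejecting non-finite stPLV {stplv!r}")
        self._values.append(float(stplv))
        self._recompute()


def evaluate_condition(stplv: float, condition: str,
                       buffer: CriteriaBuffer) -> bool:
    """Strict quartile comparison: low => stPLV < Q1, high => stPLV > Q3.

    "Below"/"above" are read literally, so a value equal to the criterion
    does not trigger.
    """
    if condition == "low":
        return stplv < buffer.q_low
    if condition == "high":
        return stplv > buffer.q_high
    raise ValueError(f"unknown condition {condition!r} (expected low|high)")


def make_condition_sequence(rng: np.random.Generator, n_low: int = 450,
                            n_high: int = 450) -> list[str]:
    """Seeded random permutation of the session's interleaved conditions."""
    seq = ["low"] * n_low + ["high"] * n_high
    return list(rng.permutation(seq))


def init_buffer_from_rest(phi1: np.ndarray, phi2: np.ndarray,
                          window: int = DEFAULT_N,
                          capacity: int = BUFFER_CAPACITY) -> CriteriaBuffer:
    """Fill the criteria buffer from resting-state phase streams.

    stPLVs are computed over non-overlapping ``window``-sample windows
    (500 ms cadence at the default geometry) until ``capacity`` values have
    been collected.
    """
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    need = capacity * window
    if phi1.size < need or phi2.size < need:
        raise ValueError(
            f"resting stream too short: need {need} phase samples "
            f"({need / 500:.0f} s at 500 Hz) for {capacity} non-overlapping "
            f"windows, have {min(phi1.size, phi2.size)}")
    vals = []
    for k in range(capacity):
        sl = slice(k * window, (k + 1) * window)
        vals.append(cstplv(PhaseWindow(phi1[sl], phi2[sl])).stplv)
    return CriteriaBuffer(vals, capacity=capacity)


@dataclass(frozen=True)
class StimEvent:
    """One delivered pulse: a condition trigger or a timeout."""

    time: float                      # delivery time (incl. trigger latency), s
    kind: str                        # "low" | "high" | "timeout"
    isi: float                       # s since the previous pulse (or block start)
    deciding_stplv: float | None = None
    phase_window: PhaseWindow | None = None
    decision_time: float | None = None  # end of the deciding phase window


@dataclass
class LoopParams:
    """Timing parameters of the trigger engine (all seconds)."""

    poll_interval: float = 0.1
    min_isi: float = 2.0
    timeout: float = 8.0
    blank_after_pulse: float = 2.0
    trigger_latency: float = 0.085
    poll_jitter: float = 0.0          # uniform [0, jitter) added per poll
    skip_first_poll_after_pause: bool = False
    window: int = DEFAULT_N
    rate: float = 500.0


@dataclass
class BlockResult:
    """Events emitted by one stimulation block plus the final buffer state."""

    events: list[StimEvent]
    buffer: CriteriaBuffer
    completed: bool
    n_polls: int = 0
    remaining_conditions: list[str] = field(default_factory=list)

    @property
    def condition_events(self) -> list[StimEvent]:
        return [e for e in self.events if e.kind != "timeout"]

    @property
    def timeout_events(self) -> list[StimEvent]:
        return [e for e in self.events if e.kind == "timeout"]


def run_block(phi1: np.ndarray, phi2: np.ndarray, sequence: list[str],
              buffer: CriteriaBuffer, params: LoopParams | None = None,
              rng: np.random.Generator | None = None) -> BlockResult:
    """Run the trigger state machine over a block of phase streams.

    ``phi1``/``phi2`` are aligned phase streams at ``params.rate``; the block
    starts at stream time 0, which is treated as a pseudo-pulse so that the
    timeout clock is defined from the start.  Every computed stPLV feeds the
    criteria buffer *after* the comparison that used the old criteria; no
    stPLVs are computed during the post-pulse blanking period.  If the
    streams end before the sequence is exhausted the partial result is
    returned with ``completed=False``.
    """
    p = params or LoopParams()
    if not sequence:
        raise ValueError("condition sequence is empty")
    if len(buffer) != buffer.capacity:
        raise ValueError("criteria buffer must be full before a block starts")
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    n = min(phi1.size, phi2.size)

    events: list[StimEvent] = []
    seq_idx = 0
    last_pulse_t = 0.0            # decision-clock time of the last pulse
    last_delivery_t = 0.0
    # first poll: earliest multiple of poll_interval with a full window
    t = np.ceil((p.window / p.rate) / p.poll_interval) * p.poll_interval
    armed = not p.skip_first_poll_after_pause
    n_polls = 0
    completed = False

    while seq_idx < len(sequence):
        if rng is not None and p.poll_jitter > 0:
            t_poll = t + rng.uniform(0.0, p.poll_jitter)
        else:
            t_poll = t
        k = int(round(t_poll * p.rate))
        if k >= n:
            break  # stream exhausted -> flagged partial result
        if t_poll - last_pulse_t < p.blank_after_pulse - 1e-9:
            t += p.poll_interval
            continue
        win = PhaseWindow(phi1[k - p.window + 1:k + 1],
                          phi2[k - p.window + 1:k + 1], end_time=t_poll)
        lv = cstplv(win)
        n_polls += 1
        condition = sequence[seq_idx]
        met = evaluate_condition(lv.stplv, condition, buffer)
        can_fire = (t_poll - last_pulse_t >= p.min_isi - 1e-9)
        fired = False
        if met and can_fire and armed:
            delivery = t_poll + p.trigger_latency
            events.append(StimEvent(
                time=delivery, kind=condition,
                isi=delivery - last_delivery_t, deciding_stplv=lv.stplv,
                phase_window=win, decision_time=t_poll))
            seq_idx += 1
            last_pulse_t = t_poll
            last_delivery_t = delivery
            armed = not p.skip_first_poll_after_pause
            fired = True
        elif not met:
            armed = True
        if not fired and t_poll - last_pulse_t >= p.timeout - 1e-9:
            delivery = t_poll + p.trigger_latency
            events.append(StimEvent(
                time=delivery, kind="timeout",
                isi=delivery - last_delivery_t, decision_time=t_poll))
            last_pulse_t = t_poll
            last_delivery_t = delivery
            armed = not p.skip_first_poll_after_pause
        buffer.update(lv.stplv)   # always, after the comparison
        t += p.poll_interval
    else:
        completed = True

    return BlockResult(events=events, buffer=buffer, completed=completed,
                       n_polls=n_polls,
                       remaining_conditions=list(sequence[seq_idx:]))
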