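"""Minimal EDF (European Data Format) writer/reader for continuous recordings.

EDF stores 16-bit samples with a per-channel linear physical/digital
mapping.  This module implements the subset needed to interchange the
package's μV EEG/EMG recordings: one continuous recording, equal sampling
rate across channels, no annotations.  When the data are integral and fit
the 16-bit range, the physical range is chosen equal to the digital range so
the round trip is sample-exact.

Recordings whose length is not a whole number of data records are
zero-padded to the record boundary (EDF stores whole records only).
"""

from __future__ import annotations

import math
from datetime import datetime

import numpy as np

from .recording import MultichannelRecording

_HDR = 256
_SIG_HDR = 256
_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    s = f"{value:.10g}"[:width]
    return _field(s, width)


def write_edf(path, recording: MultichannelRecording,
              record_duration: float = 1.0,
              start: datetime | None = None) -> None:
    """Write a recording to an EDF file (μV, equal rate on all channels)."""
    fs = recording.sample_rate
    spr = fs * record_duration
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError(
            f"record_duration {record_duration} s does not give an integer "
            f"number of samples at {fs} Hz")
    spr = int(round(spr))
    data = recording.data
    n_ch, n = data.shape
    n_rec = math.ceil(n / spr)
    if n_rec * spr > n:
        pad = np.zeros((n_ch, n_rec * spr - n))
        data = np.concatenate([data, pad], axis=1)

    phys_min = np.empty(n_ch)
    phys_max = np.empty(n_ch)
    digital = np.empty_like(data, dtype=np.int16)
    for i in range(n_ch):
        x = data[i]
        integral = np.all(x == np.round(x)) and x.min() >= _DIG_MIN \
            and x.max() <= _DIG_MAX
        if integral:
            phys_min[i], phys_max[i] = float(_DIG_MIN), float(_DIG_MAX)
            digital[i] = x.astype(np.int16)
        else:
            lo, hi = float(x.min()), float(x.max())
            if hi == lo:
                lo, hi = lo - 1.0, hi + 1.0
            phys_min[i], phys_max[i] = lo, hi
            gain = (_DIG_MAX - _DIG_MIN) / (hi - lo)
            digital[i] = np.clip(
                np.round((x - lo) * gain) + _DIG_MIN,
                _DIG_MIN, _DIG_MAX).astype(np.int16)

    start = start or datetime(2000, 1, 1)
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))
        fh.write(_field("Startdate X X X X", 80))
        fh.write(_field(start.strftime("%d.%m.%y"), 8))
        fh.write(_field(start.strftime("%H.%M.%S"), 8))
        fh.write(_num(_HDR + n_ch * _SIG_HDR, 8))
        fh.write(_field("", 44))
        fh.write(_num(n_rec, 8))
        fh.write(_num(record_duration, 8))
        fh.write(_num(n_ch, 4))
        for label in recording.labels:
            fh.write(_field(label, 16))
        for _ in range(n_ch):
            fh.write(_field("", 80))          # transducer
        for _ in range(n_ch):
            fh.write(_field("uV", 8))
        for i in range(n_ch):
            fh.write(_num(phys_min[i], 8))
        for i in range(n_ch):
            fh.write(_num(phys_max[i], 8))
        for _ in range(n_ch):
            fh.write(_num(_DIG_MIN, 8))
        for _ in range(n_ch):
            fh.write(_num(_DIG_MAX, 8))
        for _ in range(n_ch):
            fh.write(_field("", 80))          # prefiltering
        for _ in range(n_ch):
            fh.write(_num(spr, 8))
        for _ in range(n_ch):
            fh.write(_field("", 32))
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            for i in range(n_ch):
                fh.write(digital[i, sl].astype("<i2").tobytes())


def read_edf(path) -> MultichannelRecording:
    """Read an EDF file into a μV recording.

    Raises on unknown physical units or missing channel labels; channels
    whose unit field is empty or not μV are rejected rather than guessed.
    """
    with open(path, "rb") as fh:
        hdr = fh.read(_HDR)
        n_rec = int(hdr[236:244].decode("ascii").strip())
        rec_dur = float(hdr[244:252].decode("ascii").strip())
        n_ch = int(hdr[252:256].decode("ascii").strip())
        sig = fh.read(n_ch * _SIG_HDR)

        def col(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [sig[base + i * width: base + (i + 1) * width]
                    .decode("ascii").strip() for i in range(n_ch)]

        labels = col(0, 16)
        units = [sig[96 * n_ch + i * 8: 96 * n_ch + (i + 1) * 8]
                 .decode("ascii").strip() for i in range(n_ch)]
        off = 96 * n_ch + 8 * n_ch
        phys_min = [float(v) for v in _strided(sig, off, 8, n_ch)]
        off += 8 * n_ch
        phys_max = [float(v) for v in _strided(sig, off, 8, n_ch)]
        off += 8 * n_ch
        dig_min = [float(v) for v in _strided(sig, off, 8, n_ch)]
        off += 8 * n_ch
        dig_max = [float(v) for v in _strided(sig, off, 8, n_ch)]
        off += 8 * n_ch + 80 * n_ch
        spr = [int(float(v)) for v in _strided(sig, off, 8, n_ch)]

        if any(not l for l in labels):
            raise ValueError("EDF file has unlabeled channels")
        bad = [u for u in units if u not in ("uV", "μV")]
        if bad:
            raise ValueError(f"unsupported physical units in EDF: {bad}")
        if len(set(spr)) != 1:
            raise ValueError("channels with differing sampling rates")

        raw = np.frombuffer(fh.read(), dtype="<i2")

    s = spr[0]
    expected = n_rec * n_ch * s
    if raw.size != expected:
        raise ValueError(
            f"EDF data size mismatch: {raw.size} samples, expected {expected}")
    raw = raw.reshape(n_rec, n_ch, s)
    data = np.empty((n_ch, n_rec * s))
    for i in range(n_ch):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[i] = (raw[:, i, :].reshape(-1) - dig_min[i]) * gain + phys_min[i]
    fs = s / rec_dur
    return MultichannelRecording(data=data, sample_rate=fs, labels=labels)


def _strided(buf: bytes, offset: int, width: int, n: int) -> list[str]:
    return [buf[offset + i * width: offset + (i + 1) * width]
            .decode("ascii").strip() for i in range(n)]
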