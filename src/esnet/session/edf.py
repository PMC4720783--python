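"""Minimal reader/writer for standard 16-bit EDF files.

Only the subset of EDF needed here is supported: identical sampling rate on
all signals, 1-second data records, no annotations channel. Values survive a
write/read round trip up to the 16-bit quantization step of each channel.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

_HEADER_FIXED = 256
_HEADER_PER_SIGNAL = 256


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def _num(value: float, width: int) -> bytes:
    # shortest exact-ish ascii representation that fits the fixed-width field
    for fmt in (f"{value:g}", f"{value:.{max(width - 7, 0)}e}"):
        if len(fmt) <= width:
            return _pad(fmt, width)
    raise ValueError(f"cannot encode {value} in {width} ascii chars")


def write_edf(path: str | Path, samples: np.ndarray, rate: float,
              channel_names: list[str]) -> None:
    """Write a channels x samples array as a standard EDF file.

    Trailing samples that do not fill a whole 1-second record are dropped.
    """
    samples = np.asarray(samples, dtype=float)
    n_ch, n_samp = samples.shape
    spr = int(round(rate))
    if abs(spr - rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = n_samp // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one 1-second EDF record")
    data = samples[:, : n_rec * spr]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    header = bytearray()
    header += _pad("0", 8)
    header += _pad("X", 80)
    header += _pad("X", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(_HEADER_FIXED + _HEADER_PER_SIGNAL * n_ch), 8)
    header += _pad("", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(n_ch), 4)
    for field_width, values in (
        (16, channel_names),
        (80, [""] * n_ch),
        (8, ["uV"] * n_ch),
    ):
        for v in values:
            header += _pad(v, field_width)
    for arr in (pmin, pmax):
        for v in arr:
            header += _num(float(v), 8)
    for v in ([dmin] * n_ch, [dmax] * n_ch):
        for x in v:
            header += _pad(str(x), 8)
    for v in [""] * n_ch:
        header += _pad(v, 80)
    for _ in range(n_ch):
        header += _pad(str(spr), 8)
    for _ in range(n_ch):
        header += _pad("", 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # records: per record, each signal's samples contiguously
        chunks = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(chunks).tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (samples, rate, channel_names).

    All signals must share one sampling rate.
    """
    with open(path, "rb") as fh:
        fixed = fh.read(_HEADER_FIXED)
        if len(fixed) < _HEADER_FIXED:
            raise ValueError("truncated EDF header")
        n_rec = int(fixed[236:244].decode("ascii").strip())
        rec_dur = float(fixed[244:252].decode("ascii").strip())
        n_ch = int(fixed[252:256].decode("ascii").strip())

        per = fh.read(_HEADER_PER_SIGNAL * n_ch)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [
                per[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = fields(0, 16)
        pmin = np.array([float(x) for x in fields(16 + 80 + 8, 8)])
        pmax = np.array([float(x) for x in fields(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(x) for x in fields(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(x) for x in fields(16 + 80 + 8 + 24, 8)])
        spr = [int(x) for x in fields(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("signals with differing samples/record are unsupported")
        spr0 = spr[0]
        rate = spr0 / rec_dur

        raw = np.frombuffer(fh.read(2 * n_ch * spr0 * n_rec), dtype="<i2")

    digital = raw.reshape(n_rec, n_ch, spr0).transpose(1, 0, 2).reshape(n_ch, -1)
    gain = (pmax - pmin) / (dmax - dmin)
    samples = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    if not math.isfinite(rate) or rate <= 0:
        raise ValueError("invalid sampling rate in EDF header")
    return samples, rate, labels
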