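"""Minimal EDF+C writer for synthetic recordings.

Writes standard 16-bit EDF with one ``EDF Annotations`` signal carrying
trial events as time-stamped annotation lists (TALs), so files round-trip
through any EDF+ reader (the test suite round-trips through ``mne``).
Scope is deliberately small: continuous recordings, one sampling rate for
all signals, annotation descriptions that are short ASCII strings.
"""

from __future__ import annotations

from math import ceil, gcd
from pathlib import Path

import numpy as np

from .eeg_io import RawRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width} bytes")
    return b.ljust(width)


def _phys_str(v: float) -> str:
    """Physical-range header field: 8 ASCII chars, round-trippable."""
    for fmt in ("%.8g", "%.6g", "%.4g", "%.2g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot encode physical bound {v} in 8 chars")


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a :class:`RawRecording` (µV) plus its events to EDF+C.

    The data-record duration is chosen as the largest value that tiles
    the signal exactly (``gcd(n_samples, fs)`` samples per record), so no
    padding is introduced and the read-back length equals the written
    length.  Requires an integer sampling rate.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape

    spr = gcd(n_samp, fs)  # samples per record per signal
    n_records = n_samp // spr
    record_dur = spr / fs

    # physical scaling per channel; header strings are parsed back so the
    # int16 quantisation uses exactly the bounds stored in the file
    phys_lo_s, phys_hi_s = [], []
    for ch in range(n_ch):
        lo, hi = float(rec.data[ch].min()), float(rec.data[ch].max())
        if hi - lo < 1e-6:
            lo, hi = lo - 1.0, hi + 1.0
        phys_lo_s.append(_phys_str(lo))
        phys_hi_s.append(_phys_str(hi))
    phys_lo = np.array([float(s) for s in phys_lo_s])
    phys_hi = np.array([float(s) for s in phys_hi_s])

    # annotation payload per record: leading timekeeping TAL, then events
    events_by_record: list[list[bytes]] = [[] for _ in range(n_records)]
    for sample, code in rec.events:
        onset = sample / fs
        r = min(int(onset / record_dur), n_records - 1)
        tal = b"+" + (b"%.4f" % onset) + b"\x14" + str(code).encode("ascii") + b"\x14\x00"
        events_by_record[r].append(tal)
    annot_records = []
    for r in range(n_records):
        payload = b"+" + (b"%.4f" % (r * record_dur)) + b"\x14\x14\x00"
        payload += b"".join(events_by_record[r])
        annot_records.append(payload)
    annot_spr = max(8, ceil(max(len(p) for p in annot_records) / 2))

    n_sig = n_ch + 1
    header = b""
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)
    header += _ascii("Startdate 01-JAN-2001 X X X", 80)
    header += _ascii("01.01.01", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(str(256 * (1 + n_sig)), 8)
    header += _ascii("EDF+C", 44)
    header += _ascii(str(n_records), 8)
    dur_s = ("%d" % record_dur) if record_dur == int(record_dur) else ("%.6f" % record_dur).rstrip("0")
    header += _ascii(dur_s, 8)
    header += _ascii(str(n_sig), 4)

    labels = list(rec.channel_labels) + ["EDF Annotations"]
    header += b"".join(_ascii(lbl, 16) for lbl in labels)
    header += b"".join(_ascii("", 80) for _ in range(n_sig))                      # transducer
    header += b"".join(_ascii(u, 8) for u in ["uV"] * n_ch + [""])                # phys dim
    header += b"".join(_ascii(s, 8) for s in phys_lo_s + ["-1"])
    header += b"".join(_ascii(s, 8) for s in phys_hi_s + ["1"])
    header += b"".join(_ascii(str(_DIG_MIN), 8) for _ in range(n_sig))
    header += b"".join(_ascii(str(_DIG_MAX), 8) for _ in range(n_sig))
    header += b"".join(_ascii("", 80) for _ in range(n_sig))                      # prefiltering
    header += b"".join(_ascii(str(n), 8) for n in [spr] * n_ch + [annot_spr])
    header += b"".join(_ascii("", 32) for _ in range(n_sig))

    scale = (_DIG_MAX - _DIG_MIN) / (phys_hi - phys_lo)
    digital = np.round((rec.data - phys_lo[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # signal-major within record
            fh.write(annot_records[r].ljust(2 * annot_spr, b"\x00"))
    return path
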