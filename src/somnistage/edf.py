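"""Minimal European Data Format (EDF) reader/writer for five-channel PSG records.

EDF stores a fixed-layout ASCII header followed by little-endian int16 data
records; each signal is linearly mapped between its digital and physical
ranges.  The writer uses 1 s data records (so sampling rates must be integer)
and a symmetric digital range (-32767..32767) for an exact mid-tread mapping.

The declared physical acquisition maximum of each channel — the quantity the
downstream QC thresholds derive from — is stored in the 80-character
transducer header field as ``acq_max=<value>uV``.  The stored physical
min/max are widened beyond the declared maximum when a signal (e.g. an
injected saturation artifact) exceeds it, so saturated amplitudes survive the
round trip instead of being clipped; the reader recovers the declared maximum
from the transducer annotation, falling back to the header physical maximum
for files produced elsewhere.
"""

from __future__ import annotations

import re

import numpy as np

from .record import EPOCH_SECONDS, ROLES, ChannelMeta, PSGRecord

_DIG_MAX = 32767


def _fixed(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> bytes:
    for fmt in ("%g", "%.5g", "%.4g", "%.3g"):
        s = fmt % x
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {x} in {width} chars")


def write_edf(record: PSGRecord, path) -> None:
    """Write a :class:`~somnistage.record.PSGRecord` to an EDF file.

    All channels must share a common whole-second duration and have integer
    sampling rates (1 s data records are used).
    """
    n_seconds = record.duration
    if abs(n_seconds - round(n_seconds)) > 1e-9:
        raise ValueError("record duration must be a whole number of seconds")
    n_records = int(round(n_seconds))

    roles = list(ROLES)
    rates = []
    for role in roles:
        fs = record.meta[role].sampling_rate
        if abs(fs - round(fs)) > 1e-9:
            raise ValueError(f"channel {role}: EDF writer requires an integer sampling rate")
        rates.append(int(round(fs)))

    phys_lims = []
    for role in roles:
        x = record.channels[role]
        declared = record.meta[role].physical_max
        actual = float(np.max(np.abs(x))) if len(x) else 0.0
        lim = max(declared, actual * (1 + 1e-9))
        phys_lims.append(lim)

    ns = len(roles)
    header = b""
    header += _fixed("0", 8)
    header += _fixed("X X X X", 80)
    header += _fixed("Startdate X X X X", 80)
    header += _fixed("01.01.00", 8)
    header += _fixed("00.00.00", 8)
    header += _fixed(str(256 * (ns + 1)), 8)
    header += _fixed("", 44)
    header += _fixed(str(n_records), 8)
    header += _fixed("1", 8)  # record duration, seconds
    header += _fixed(str(ns), 4)

    header += b"".join(_fixed(r, 16) for r in roles)
    header += b"".join(
        _fixed(f"acq_max={record.meta[r].physical_max:g}uV", 80) for r in roles
    )
    header += b"".join(_fixed("uV", 8) for _ in roles)
    header += b"".join(_fmt_float(-lim) for lim in phys_lims)
    header += b"".join(_fmt_float(lim) for lim in phys_lims)
    header += b"".join(_fixed(str(-_DIG_MAX), 8) for _ in roles)
    header += b"".join(_fixed(str(_DIG_MAX), 8) for _ in roles)
    header += b"".join(_fixed("", 80) for _ in roles)
    header += b"".join(_fixed(str(fs), 8) for fs in rates)
    header += b"".join(_fixed("", 32) for _ in roles)
    assert len(header) == 256 * (ns + 1)

    digital = []
    for role, lim in zip(roles, phys_lims):
        x = np.asarray(record.channels[role], dtype=float)
        d = np.rint(x / lim * _DIG_MAX).astype("<i2")
        digital.append(d.reshape(n_records, -1))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for d in digital:
                fh.write(d[rec].tobytes())


_ACQ_RE = re.compile(r"acq_max=([0-9.eE+-]+)uV")


def read_edf(path) -> PSGRecord:
    """Read an EDF file into a :class:`~somnistage.record.PSGRecord`.

    Raises ``ValueError`` naming any required channel role absent from the
    file.  A trailing partial 30 s epoch is truncated.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("malformed EDF header: file shorter than 256 bytes")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"malformed EDF header: {exc}") from exc
        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise ValueError("malformed EDF header: truncated signal headers")

        def field(width, offset):
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        # cumulative byte offsets of the per-signal header blocks
        labels = field(16, 0)
        transducers = [
            sig_head[16 * ns + i * 80 : 16 * ns + (i + 1) * 80].decode("ascii").strip()
            for i in range(ns)
        ]
        off = 16 * ns + 80 * ns + 8 * ns  # past labels, transducers, dimensions
        phys_min = [float(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns
        phys_max = [float(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns
        dig_min = [int(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns
        dig_max = [int(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(ns)]
        off += 8 * ns + 80 * ns  # past prefiltering
        spr = [int(sig_head[off + i * 8 : off + (i + 1) * 8]) for i in range(ns)]

        data = np.frombuffer(fh.read(2 * sum(spr) * n_records), dtype="<i2")

    expected = sum(spr) * n_records
    if len(data) < expected:
        n_records = len(data) // sum(spr)
        data = data[: sum(spr) * n_records]

    missing = [r for r in ROLES if r not in labels]
    if missing:
        raise ValueError(f"EDF file is missing required channel roles: {missing}")

    rec_matrix = data.reshape(n_records, sum(spr))
    starts = np.concatenate([[0], np.cumsum(spr)])
    channels: dict[str, np.ndarray] = {}
    meta: dict[str, ChannelMeta] = {}
    for i, label in enumerate(labels):
        if label not in ROLES:
            continue
        dig = rec_matrix[:, starts[i] : starts[i + 1]].reshape(-1).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        channels[label] = phys_min[i] + (dig - dig_min[i]) * gain
        m = _ACQ_RE.search(transducers[i])
        declared = float(m.group(1)) if m else max(abs(phys_min[i]), abs(phys_max[i]))
        meta[label] = ChannelMeta(label, spr[i] / record_dur, declared)

    record = PSGRecord(channels, meta)
    return record.truncate_to_epoch_grid()
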