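"""Minimal European Data Format (EDF) writer/reader.

Plain EDF (not EDF+): fixed 256-byte header, one 256-byte signal-header
block per channel, then 16-bit little-endian integer data records.  Epoched
data is laid out as one data record per epoch (record duration =
epoch length), so the epoch structure survives a round trip.  Physical
values are scaled to the full digital range per channel.

The format is simple enough that reading it back with an independent EDF
implementation (e.g. ``mne.io.read_raw_edf``) is used as a validity check
in the test suite.
"""

from __future__ import annotations

import datetime

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    data: np.ndarray,
    channel_labels,
    srate: int,
    physical_dim: str = "uV",
    patient_id: str = "X X X X",
    recording_id: str = "Startdate X X X X",
) -> None:
    """Write ``data`` of shape (n_records, n_channels, samples_per_record)."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("data must be (n_records, n_channels, samples_per_record)")
    n_rec, n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels length must match data")
    if n_samp % srate != 0:
        raise ValueError("samples per record must be a whole number of seconds")
    record_dur = n_samp // srate

    # per-channel physical range (symmetric, nonzero)
    phys_max = np.maximum(np.abs(data).max(axis=(0, 2)), 1e-6)
    phys_min = -phys_max
    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - phys_min[None, :, None]) / scale[None, :, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header_bytes = 256 * (1 + n_ch)
    head = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(header_bytes), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field(str(record_dur), 8),
            _field(str(n_ch), 4),
        ]
    )

    def sig_block(values, width):
        return b"".join(_field(v, width) for v in values)

    head += sig_block(channel_labels, 16)
    head += sig_block([""] * n_ch, 80)                       # transducer
    head += sig_block([physical_dim] * n_ch, 8)
    head += sig_block([f"{v:.6g}" for v in phys_min], 8)
    head += sig_block([f"{v:.6g}" for v in phys_max], 8)
    head += sig_block([str(_DIG_MIN)] * n_ch, 8)
    head += sig_block([str(_DIG_MAX)] * n_ch, 8)
    head += sig_block([""] * n_ch, 80)                       # prefiltering
    head += sig_block([str(n_samp)] * n_ch, 8)
    head += sig_block([""] * n_ch, 32)                       # reserved

    with open(path, "wb") as fh:
        fh.write(head)
        # record-major, signal-contiguous layout required by EDF
        digital.tofile(fh)


def read_edf(path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file; returns (data (n_rec, n_ch, n_samp), labels, srate)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode("ascii").strip())
        record_dur = float(head[244:252].decode("ascii").strip())
        n_ch = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * n_ch)

        def fields(offset, width):
            base = offset * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = fields(0, 16)
        phys_min = np.array([float(v) for v in fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in fields(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)])
        # samples-per-record field sits after the two 80-char text blocks
        samp_field_offset = 16 + 80 + 8 + 8 + 8 + 8 + 8 + 80
        n_samp = int(fields(samp_field_offset, 8)[0])
        raw = np.fromfile(fh, dtype="<i2", count=n_rec * n_ch * n_samp)

    digital = raw.reshape(n_rec, n_ch, n_samp).astype(np.float64)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[None, :, None]) * scale[None, :, None] + phys_min[None, :, None]
    srate = n_samp / record_dur
    return data, labels, srate
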