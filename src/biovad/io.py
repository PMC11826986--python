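"""Raw-signal and feature-table I/O.

Raw recordings are exchanged as EDF, one file per device (belt respiration,
impedance, accelerometer/gyroscope unit), with protocol-block annotations in
a JSON sidecar.  EDF reading goes through :mod:`mne`; writing uses a minimal
plain-EDF writer (16-bit, per-signal sampling rates) since no EDF writer is
otherwise available.  Feature tables are written as CSV or Parquet.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import Condition, Posture, ProtocolBlock
from .recording import Channel, MultiChannelRecording

__all__ = [
    "write_edf",
    "read_edf",
    "save_recording",
    "load_recording",
    "write_csv_long",
    "write_feature_table",
    "read_feature_table",
    "DEVICE_CHANNELS",
]

#: channel grouping into physical devices (one EDF file per device)
DEVICE_CHANNELS: dict[str, tuple[str, ...]] = {
    "belt": ("rip_thorax", "rip_abdomen"),
    "imp": ("imp",),
    "accgyro": ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"),
}

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def write_edf(path, channels: dict[str, Channel], *, patient_id: str = "X") -> None:
    """Write channels to a plain EDF file (16-bit quantization).

    Record duration is 1 s, so every channel's sampling rate must be a
    positive integer and all channels must span the same whole-second
    duration.
    """
    path = Path(path)
    names = list(channels)
    fss = []
    durs = set()
    for name in names:
        ch = channels[name]
        if ch.fs != int(ch.fs) or ch.fs <= 0:
            raise ValueError(f"channel {name}: EDF export needs integer fs, got {ch.fs}")
        fss.append(int(ch.fs))
        durs.add(len(ch.samples) / ch.fs)
    if len(durs) != 1:
        raise ValueError("all channels in one EDF file must have equal duration")
    duration = durs.pop()
    if duration != int(duration):
        raise ValueError("EDF export needs a whole-second duration")
    n_records = int(duration)
    ns = len(names)

    pmins, pmaxs, digital = [], [], []
    for name, fs in zip(names, fss):
        x = np.asarray(channels[name].samples, dtype=float)
        pmin, pmax = float(x.min()), float(x.max())
        if pmax == pmin:
            pmax = pmin + 1.0
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        d = np.round((x - pmin) * gain + _DIG_MIN).astype("<i2")
        pmins.append(pmin)
        pmaxs.append(pmax)
        digital.append(d.reshape(n_records, fs))

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(patient_id, 80),
            _ascii("biovad", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (1 + ns)), 8),
            _ascii("", 44),
            _ascii(str(n_records), 8),
            _ascii("1", 8),
            _ascii(str(ns), 4),
        ]
    )
    sig = b"".join(_ascii(n, 16) for n in names)
    sig += b"".join(_ascii("", 80) for _ in names)
    sig += b"".join(_ascii("", 8) for _ in names)  # physical dimension: arbitrary units
    sig += b"".join(_ascii(f"{p:.6g}", 8) for p in pmins)
    sig += b"".join(_ascii(f"{p:.6g}", 8) for p in pmaxs)
    sig += b"".join(_ascii(str(_DIG_MIN), 8) for _ in names)
    sig += b"".join(_ascii(str(_DIG_MAX), 8) for _ in names)
    sig += b"".join(_ascii("", 80) for _ in names)
    sig += b"".join(_ascii(str(fs), 8) for fs in fss)
    sig += b"".join(_ascii("", 32) for _ in names)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            for d in digital:
                fh.write(d[r].tobytes())


def read_edf(path) -> dict[str, Channel]:
    """Read an EDF file into named channels (via ``mne.io.read_raw_edf``)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    return {
        name: Channel(np.asarray(data[i], dtype=float), fs)
        for i, name in enumerate(raw.ch_names)
    }


def _annotations_payload(rec: MultiChannelRecording) -> dict:
    return {
        "subject_id": rec.subject_id,
        "blocks": [
            {
                "start_s": start,
                "condition": b.condition.value,
                "posture": b.posture.value,
                "speech": bool(b.speech),
                "duration_s": b.duration_s,
            }
            for start, b in rec.annotations
        ],
        "ground_truth": np.asarray(rec.ground_truth).tolist(),
    }


def save_recording(rec: MultiChannelRecording, outdir) -> dict[str, Path]:
    """Write one EDF per device plus a JSON annotation sidecar.

    Returns the written paths keyed by device / ``"annotations"``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for device, names in DEVICE_CHANNELS.items():
        present = {n: rec.channels[n] for n in names if n in rec.channels}
        if not present:
            continue
        p = outdir / f"{rec.subject_id}_{device}.edf"
        write_edf(p, present, patient_id=rec.subject_id)
        written[device] = p
    p = outdir / f"{rec.subject_id}_annotations.json"
    with open(p, "w") as fh:
        json.dump(_annotations_payload(rec), fh, indent=1)
    written["annotations"] = p
    return written


def load_recording(outdir, subject_id: str) -> MultiChannelRecording:
    """Load a recording previously written by :func:`save_recording`."""
    outdir = Path(outdir)
    channels: dict[str, Channel] = {}
    for device in DEVICE_CHANNELS:
        p = outdir / f"{subject_id}_{device}.edf"
        if p.exists():
            channels.update(read_edf(p))
    with open(outdir / f"{subject_id}_annotations.json") as fh:
        meta = json.load(fh)
    annotations = [
        (
            b["start_s"],
            ProtocolBlock(
                Condition(b["condition"]),
                Posture(b["posture"]),
                bool(b["speech"]),
                b["duration_s"],
            ),
        )
        for b in meta["blocks"]
    ]
    return MultiChannelRecording(
        subject_id=meta["subject_id"],
        channels=channels,
        annotations=annotations,
        ground_truth=np.asarray(meta["ground_truth"]),
    )


def write_csv_long(rec: MultiChannelRecording, path) -> None:
    """Write a recording as long-format CSV (subject, channel, t, value)."""
    frames = []
    for name, ch in rec.channels.items():
        frames.append(
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "channel": name,
                    "t": np.arange(len(ch.samples)) / ch.fs,
                    "value": ch.samples,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)
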