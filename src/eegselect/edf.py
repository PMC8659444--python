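"""EDF ingestion (via MNE) and a minimal EDF writer for the simulator.

Reading goes through :func:`mne.io.read_raw_edf`, which handles EDF/EDF+
headers, per-channel scaling and annotations.  Writing implements the plain
EDF layout (ASCII header + 16-bit little-endian data records) directly; it
exists so synthetic recordings can be exported in the same container real
scalp EEG ships in, and is limited to a uniform sampling rate and one
physical range for all channels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .signal_model import ChannelMontage, EegRecording

__all__ = ["read_edf", "write_edf"]


def read_edf(
    path: str | Path,
    montage: ChannelMontage,
    onsets: Sequence[float] = (),
    patient_id: str = "",
) -> EegRecording:
    """Read an EDF file and return channels ordered per the montage.

    Channel labels are matched case- and whitespace-insensitively; a label
    occurring several times in the montage (as "T8-P8" does in CHB-MIT) is
    matched to file channels in order of appearance.

    Raises FileNotFoundError for a missing file and ValueError when montage
    labels cannot all be matched or channels disagree on sampling rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")

    def norm(s: str) -> str:
        return "".join(s.split()).upper()

    available: dict[str, list[int]] = {}
    dedup: dict[str, list[int]] = {}
    for i, name in enumerate(raw.ch_names):
        key = norm(name)
        available.setdefault(key, []).append(i)
        # MNE renames duplicate EDF labels to "<label>-0", "<label>-1", ...
        base, dash, suffix = key.rpartition("-")
        if dash and suffix.isdigit():
            dedup.setdefault(base, []).append(i)
    order, unmatched = [], []
    for _, label in montage.entries:
        pool = available.get(norm(label)) or dedup.get(norm(label), [])
        if pool:
            order.append(pool.pop(0))
        else:
            unmatched.append(label)
    if unmatched:
        raise ValueError(f"EDF is missing montage channels: {unmatched}")
    data = raw.get_data(picks=order) * 1e6  # MNE loads volts; store microvolts
    return EegRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        seizure_onsets=tuple(onsets),
        montage=montage,
        patient_id=patient_id or path.stem,
    )


def write_edf(
    path: str | Path,
    rec: EegRecording,
    phys_min: float = -1000.0,
    phys_max: float = 1000.0,
) -> None:
    """Write a recording as plain 16-bit EDF (1-s data records).

    Samples outside [phys_min, phys_max] microvolts are clipped.  The
    trailing partial second, if any, is dropped (EDF stores whole records).
    """
    n_ch = rec.n_channels
    spr = int(round(rec.fs))  # samples per 1-s record
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    dig_min, dig_max = -32768, 32767

    def pad(v, width: int) -> bytes:
        s = str(v)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad(rec.patient_id or "X", 80),
            pad("Startdate X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 + n_ch * 256, 8),
            b" " * 44,
            pad(n_rec, 8),
            pad("1", 8),
            pad(n_ch, 4),
        ]
    )
    fields = [
        (rec.montage.labels, 16),
        ([""] * n_ch, 80),          # transducer
        (["uV"] * n_ch, 8),
        ([f"{phys_min:g}"] * n_ch, 8),
        ([f"{phys_max:g}"] * n_ch, 8),
        ([dig_min] * n_ch, 8),
        ([dig_max] * n_ch, 8),
        ([""] * n_ch, 80),          # prefiltering
        ([spr] * n_ch, 8),
        ([""] * n_ch, 32),          # reserved
    ]
    header += b"".join(pad(v, w) for vals, w in fields for v in vals)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    clipped = np.clip(rec.samples, phys_min, phys_max)
    digital = np.round((clipped - phys_min) * scale + dig_min).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())
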