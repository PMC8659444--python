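"""Recordings, montage, and the windowing/labeling/sampling rules.

The study design fixes a 10-minute seizure prediction horizon (SPH): the
10 minutes preceding each seizure onset are the *pre-ictal* period, tiled
into non-overlapping 2.8-s analysis windows.  *Normal* windows of the same
length are drawn at random, one per clock hour by default, from time that is
neither pre-ictal nor post-ictal (the 30 minutes following an onset).  To
keep classification honest on recordings where normal time vastly dominates,
the normal:pre-ictal ratio is capped (10:1 by default).  Train/test splits
are chronological at the seizure level: a model never trains on seizures
that occur after the ones it is tested on.

Times are seconds from recording start; sample indices are 0-based with
half-open intervals.  At 256 Hz a 2.8-s window is round(2.8*256) = 717
samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CHBMIT_LABELS",
    "ChannelMontage",
    "EegRecording",
    "WindowingConfig",
    "LabeledWindow",
    "extract_preictal_windows",
    "sample_normal_windows",
    "enforce_ratio",
    "chronological_split",
]

#: The 23 bipolar derivations of the CHB-MIT scalp montage, in recording
#: order.  Note "T8-P8" legitimately appears twice (indices 15 and 23).
CHBMIT_LABELS = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1", "FP1-F3", "F3-C3", "C3-P3",
    "P3-O1", "FP2-F4", "F4-C4", "C4-P4", "P4-O2", "FP2-F8", "F8-T8",
    "T8-P8", "P8-O2", "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9", "FT9-FT10",
    "FT10-T8", "T8-P8",
)


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered (index, label) channel list; identity is the pair.

    Labels need not be unique (the CHB-MIT montage repeats "T8-P8"), so
    channels are addressed by their 1-based index.
    """

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        indices = [i for i, _ in self.entries]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("montage indices must be 1..n in order")

    @classmethod
    def chbmit(cls) -> "ChannelMontage":
        return cls(tuple((i + 1, lab) for i, lab in enumerate(CHBMIT_LABELS)))

    @classmethod
    def generic(cls, n_channels: int) -> "ChannelMontage":
        return cls(tuple((i + 1, f"CH{i + 1:02d}") for i in range(n_channels)))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, lab in self.entries)

    def index_of(self, label: str) -> int:
        """1-based index of the first channel with this label."""
        key = label.strip().upper()
        for i, lab in self.entries:
            if lab.strip().upper() == key:
                return i
        raise KeyError(label)


@dataclass
class EegRecording:
    """A continuous multichannel recording with seizure-onset annotations.

    samples : [n_channels, n_samples] in microvolts
    fs : sampling rate in Hz
    seizure_onsets : onset times in seconds, strictly increasing
    """

    samples: np.ndarray
    fs: float
    seizure_onsets: tuple[float, ...]
    montage: ChannelMontage
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be [n_channels, n_samples]")
        if self.samples.shape[0] != len(self.montage):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but montage has "
                f"{len(self.montage)} entries"
            )
        self.seizure_onsets = tuple(float(t) for t in self.seizure_onsets)
        if any(b <= a for a, b in zip(self.seizure_onsets, self.seizure_onsets[1:])):
            raise ValueError("seizure onsets must be strictly increasing")
        dur = self.duration_s
        if any(not (0 <= t < dur) for t in self.seizure_onsets):
            raise ValueError("every onset must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class WindowingConfig:
    """SPH windowing parameters (defaults follow the study design)."""

    sph_minutes: float = 10.0
    window_seconds: float = 2.8
    postictal_minutes: float = 30.0
    max_normal_to_preictal_ratio: float = 10.0

    def __post_init__(self) -> None:
        if min(self.sph_minutes, self.window_seconds, self.postictal_minutes) <= 0:
            raise ValueError("durations must be positive")
        if self.max_normal_to_preictal_ratio < 1:
            raise ValueError("ratio must be >= 1")

    @property
    def sph_s(self) -> float:
        return self.sph_minutes * 60.0

    @property
    def postictal_s(self) -> float:
        return self.postictal_minutes * 60.0

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_seconds * fs))


@dataclass
class LabeledWindow:
    """One analysis window: [n_channels, w] samples plus provenance."""

    data: np.ndarray
    label: Literal["preictal", "normal"]
    start_s: float
    patient_id: str = ""
    seizure_index: int | None = None

    def __post_init__(self) -> None:
        if self.label not in ("preictal", "normal"):
            raise ValueError(f"bad label {self.label!r}")
        if self.label == "preictal" and self.seizure_index is None:
            raise ValueError("pre-ictal windows must carry a seizure_index")


def _exclusion_zones(rec: EegRecording, cfg: WindowingConfig) -> list[tuple[float, float]]:
    """[onset - SPH, onset + post-ictal] intervals, in seconds."""
    return [(t - cfg.sph_s, t + cfg.postictal_s) for t in rec.seizure_onsets]


def extract_preictal_windows(
    rec: EegRecording, cfg: WindowingConfig = WindowingConfig()
) -> list[LabeledWindow]:
    """Tile each seizure's SPH with non-overlapping windows ending at onset.

    Windows anchor at the onset and tile backward; the fractional leftover
    at the far end of the horizon is discarded.  The horizon is truncated at
    the recording start and at the previous seizure's post-ictal boundary,
    so no pre-ictal window overlaps another seizure's post-ictal period.
    """
    w = cfg.window_samples(rec.fs)
    out: list[LabeledWindow] = []
    for k, onset in enumerate(rec.seizure_onsets):
        lo = max(0.0, onset - cfg.sph_s)
        if k > 0:
            lo = max(lo, rec.seizure_onsets[k - 1] + cfg.postictal_s)
        end = int(np.floor(onset * rec.fs))  # last sample at or before onset
        lo_samp = int(np.ceil(lo * rec.fs))
        n_win = max(0, (end - lo_samp) // w)
        for j in range(n_win, 0, -1):
            start = end - j * w
            out.append(
                LabeledWindow(
                    data=rec.samples[:, start : start + w],
                    label="preictal",
                    start_s=start / rec.fs,
                    patient_id=rec.patient_id,
                    seizure_index=k + 1,
                )
            )
    return out


def _admissible_starts(
    rec: EegRecording, cfg: WindowingConfig, hour: int
) -> list[tuple[int, int]]:
    """Half-open ranges of admissible window start samples within one hour."""
    fs = rec.fs
    w = cfg.window_samples(fs)
    h0 = int(round(hour * 3600 * fs))
    h1 = min(int(round((hour + 1) * 3600 * fs)), rec.n_samples)
    # window must fit inside the hour (and the recording)
    ranges = [(h0, h1 - w + 1)]
    for a, b in _exclusion_zones(rec, cfg):
        a_s = int(np.floor(a * fs)) - w + 1  # starts whose window touches [a, b]
        b_s = int(np.ceil(b * fs)) + 1
        ranges = [
            piece
            for lo, hi in ranges
            for piece in ((lo, min(hi, a_s)), (max(lo, b_s), hi))
            if piece[0] < piece[1]
        ]
    return [r for r in ranges if r[0] < r[1]]


def sample_normal_windows(
    rec: EegRecording,
    cfg: WindowingConfig = WindowingConfig(),
    rng: np.random.Generator | None = None,
    per_hour: int = 1,
) -> list[LabeledWindow]:
    """Randomly place normal-period windows in each clock hour.

    Each complete hour contributes ``per_hour`` windows (default one, the
    study's sampling rule) with start samples uniform over the admissible
    positions — those whose window lies inside the hour and intersects no
    [onset - SPH, onset + post-ictal] exclusion zone.  Hours with no
    admissible position contribute nothing.
    """
    if rng is None:
        rng = np.random.default_rng()
    w = cfg.window_samples(rec.fs)
    n_hours = int(rec.duration_s // 3600)
    out: list[LabeledWindow] = []
    for hour in range(n_hours):
        ranges = _admissible_starts(rec, cfg, hour)
        total = sum(hi - lo for lo, hi in ranges)
        if total <= 0:
            continue
        for _ in range(per_hour):
            pos = int(rng.integers(total))
            for lo, hi in ranges:
                if pos < hi - lo:
                    start = lo + pos
                    break
                pos -= hi - lo
            out.append(
                LabeledWindow(
                    data=rec.samples[:, start : start + w],
                    label="normal",
                    start_s=start / rec.fs,
                    patient_id=rec.patient_id,
                )
            )
    return out


def enforce_ratio(
    normal: Sequence[LabeledWindow],
    preictal: Sequence[LabeledWindow],
    ratio: float = 10.0,
    rng: np.random.Generator | None = None,
) -> list[LabeledWindow]:
    """Uniformly subsample the normal windows to at most ratio x |preictal|."""
    if len(preictal) == 0:
        raise ValueError("cannot enforce a normal:pre-ictal ratio with no pre-ictal windows")
    cap = int(ratio * len(preictal))
    if len(normal) <= cap:
        return list(normal)
    if rng is None:
        rng = np.random.default_rng()
    keep = rng.choice(len(normal), size=cap, replace=False)
    return [normal[i] for i in sorted(keep)]


def chronological_split(
    windows: Sequence[LabeledWindow],
    n_train_seizures: int,
    cfg: WindowingConfig = WindowingConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Split at the seizure level: earliest seizures train, the rest test.

    Pre-ictal windows follow their seizure.  Normal windows are split by
    time at the start of the first test seizure's SPH, so training normal
    data strictly precedes the test period.  The normal:pre-ictal cap is
    re-applied within each partition.
    """
    windows = sorted(windows, key=lambda w: w.start_s)
    seizure_ids = sorted({w.seizure_index for w in windows if w.label == "preictal"})
    if not 1 <= n_train_seizures < len(seizure_ids):
        raise ValueError(
            f"n_train_seizures must be in [1, {len(seizure_ids) - 1}], "
            f"got {n_train_seizures}"
        )
    train_ids = set(seizure_ids[:n_train_seizures])
    first_test_id = seizure_ids[n_train_seizures]
    boundary = min(
        w.start_s for w in windows
        if w.label == "preictal" and w.seizure_index == first_test_id
    )
    if rng is None:
        rng = np.random.default_rng()
    train, test = [], []
    for w in windows:
        if w.label == "preictal":
            (train if w.seizure_index in train_ids else test).append(w)
        else:
            (train if w.start_s < boundary else test).append(w)

    def recap(part: list[LabeledWindow]) -> list[LabeledWindow]:
        pre = [w for w in part if w.label == "preictal"]
        nor = [w for w in part if w.label == "normal"]
        nor = enforce_ratio(nor, pre, cfg.max_normal_to_preictal_ratio, rng)
        return sorted(pre + nor, key=lambda w: w.start_s)

    return recap(train), recap(test)
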