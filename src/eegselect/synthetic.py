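"""Synthetic multichannel EEG with planted pre-ictal structure.

The generator produces recordings shaped like clinical scalp EEG (23
bipolar channels, 256 Hz, seizure onsets in seconds) but with a *known*
answer for channel selection: every channel carries broadband Gaussian
noise, and during the 10 minutes before each planted onset a configurable
subset of "informative" channels mixes in a regular narrowband oscillation.
Permutation entropy of noise is near its maximum, while the oscillation is
ordinally near-deterministic, so informative channels show a PE drop in
pre-ictal windows and non-informative channels are statistically identical
across classes.  That is exactly the contract a PE-based channel selector
assumes — nothing more: no 1/f spectral shape, no artifacts, no sleep
staging.

The regular component is a sinusoid whose instantaneous frequency performs
a slow reflected random walk inside 3–12 Hz (theta/alpha range), scaled to
the same RMS as the background noise, and the mixture is

    x = (1 - lambda) * noise + lambda * regular

with ``lambda = preictal_regularity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import (
    ChannelMontage,
    EegRecording,
    LabeledWindow,
    WindowingConfig,
    chronological_split,
    enforce_ratio,
    extract_preictal_windows,
    sample_normal_windows,
)

__all__ = ["SyntheticCohortSpec", "generate_recording", "generate_labeled_cohort"]

#: frequency band of the pre-ictal regular component, Hz
_BAND = (3.0, 12.0)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one synthetic patient recording.

    preictal_regularity is the oscillation-to-noise mixing weight lambda in
    (0, 1]: 0 would leave pre-ictal windows pure noise, 1 makes informative
    channels purely oscillatory during the SPH.  noise_sd is the background
    amplitude in microvolts (scalp EEG is a few tens of microvolts).
    """

    n_channels: int = 23
    fs: float = 256.0
    hours: float = 4.0
    n_seizures: int = 4
    informative_channels: frozenset[int] = frozenset({4, 7, 16})
    preictal_regularity: float = 0.8
    noise_sd: float = 15.0
    seed: int = 0
    patient_id: str = "synthetic"

    def __post_init__(self) -> None:
        bad = set(self.informative_channels) - set(range(1, self.n_channels + 1))
        if bad:
            raise ValueError(f"informative channels out of range: {sorted(bad)}")
        if not 0 < self.preictal_regularity <= 1:
            raise ValueError("preictal_regularity must be in (0, 1]")


def _plan_onsets(spec: SyntheticCohortSpec, cfg: WindowingConfig) -> list[float]:
    """Evenly spaced onsets, one per equal block, each preceded by a full SPH.

    Raises ValueError when the requested count cannot be spaced further than
    SPH + post-ictal apart within the recording.
    """
    total = spec.hours * 3600.0
    block = total / spec.n_seizures
    if block <= cfg.sph_s + cfg.postictal_s:
        raise ValueError(
            f"{spec.n_seizures} seizures in {spec.hours} h cannot be spaced "
            f"more than SPH + post-ictal ({(cfg.sph_s + cfg.postictal_s) / 60:.0f} min) apart"
        )
    # onset at 3/4 of its block: a full SPH precedes even the first onset
    return [block * (k + 0.75) for k in range(spec.n_seizures)]


def _regular_component(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS sinusoid with a slow reflected-random-walk frequency."""
    lo, hi = _BAND
    steps = rng.normal(0.0, 0.05 / np.sqrt(fs), size=n).cumsum()
    f0 = rng.uniform(lo, hi)
    span = hi - lo
    freq = lo + np.abs((f0 - lo + steps * span) % (2 * span) - span)  # reflect
    phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    return np.sqrt(2.0) * np.sin(phase)


def generate_recording(
    spec: SyntheticCohortSpec, cfg: WindowingConfig = WindowingConfig()
) -> EegRecording:
    """Simulate one recording with planted pre-ictal structure.

    Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.hours * 3600.0 * spec.fs))
    onsets = _plan_onsets(spec, cfg)
    samples = rng.normal(0.0, spec.noise_sd, size=(spec.n_channels, n_samples))
    samples = samples.astype(np.float32)
    lam = spec.preictal_regularity
    for onset in onsets:
        a = int(round(max(0.0, onset - cfg.sph_s) * spec.fs))
        b = int(round(onset * spec.fs))
        for ch in sorted(spec.informative_channels):
            reg = _regular_component(b - a, spec.fs, rng) * spec.noise_sd
            samples[ch - 1, a:b] = (
                (1.0 - lam) * samples[ch - 1, a:b] + lam * reg.astype(np.float32)
            )
    montage = (
        ChannelMontage.chbmit()
        if spec.n_channels == 23
        else ChannelMontage.generic(spec.n_channels)
    )
    return EegRecording(
        samples=samples,
        fs=spec.fs,
        seizure_onsets=tuple(onsets),
        montage=montage,
        patient_id=spec.patient_id,
    )


def generate_labeled_cohort(
    spec: SyntheticCohortSpec,
    cfg: WindowingConfig = WindowingConfig(),
    n_train_seizures: int | None = None,
    normal_per_hour: int = 1,
):
    """Recording → windows → ratio cap → chronological split, with truth.

    Returns ``(train, test, ground_truth)`` where ground_truth is the set of
    planted informative channel indices.  ``normal_per_hour`` densifies the
    normal sampling beyond the one-per-hour clinical rule so short simulated
    recordings can still yield balanced classes.
    """
    if spec.n_seizures < 2:
        raise ValueError("a labeled cohort needs at least 2 seizures to split")
    if n_train_seizures is None:
        n_train_seizures = spec.n_seizures // 2
    rec = generate_recording(spec, cfg)
    rng = np.random.default_rng(spec.seed + 1)
    pre = extract_preictal_windows(rec, cfg)
    nor = sample_normal_windows(rec, cfg, rng, per_hour=normal_per_hour)
    nor = enforce_ratio(nor, pre, cfg.max_normal_to_preictal_ratio, rng)
    train, test = chronological_split(pre + nor, n_train_seizures, cfg, rng)
    return train, test, set(spec.informative_channels)
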