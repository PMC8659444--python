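"""On-disk layout for windowed datasets: matrices + a JSON manifest.

A window directory holds ``windows.npz`` (one [n_channels, w] array per
window, keyed ``w000000``, ``w000001``, ...) and ``manifest.json`` carrying
labels, start times, seizure indices, the windowing configuration and the
seed that produced the sampling, so any downstream result can be traced to
its exact inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .signal_model import LabeledWindow, WindowingConfig

__all__ = ["save_windows", "load_windows"]


def save_windows(
    directory: str | Path,
    windows: list[LabeledWindow],
    cfg: WindowingConfig,
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"w{i:06d}": np.asarray(w.data) for i, w in enumerate(windows)}
    np.savez_compressed(directory / "windows.npz", **arrays)
    manifest = {
        "n_windows": len(windows),
        "windows": [
            {
                "key": f"w{i:06d}",
                "label": w.label,
                "start_s": w.start_s,
                "patient_id": w.patient_id,
                "seizure_index": w.seizure_index,
            }
            for i, w in enumerate(windows)
        ],
        "config": asdict(cfg),
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_windows(directory: str | Path) -> tuple[list[LabeledWindow], WindowingConfig]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg = WindowingConfig(**manifest["config"])
    with np.load(directory / "windows.npz") as npz:
        windows = [
            LabeledWindow(
                data=npz[m["key"]],
                label=m["label"],
                start_s=m["start_s"],
                patient_id=m["patient_id"],
                seizure_index=m["seizure_index"],
            )
            for m in manifest["windows"]
        ]
    return windows, cfg
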