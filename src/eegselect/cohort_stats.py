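"""Cohort-level statistics over paired per-patient evaluation results.

Each patient contributes a paired measurement (selected channels vs all
channels) of four metrics: event-level prediction rate, window accuracy,
sensitivity and specificity, all in percent.  The cohort summary reports
N, sum, mean and *sample* standard deviation per column, the relative
improvement of the selected-channel means over the all-channel means, and a
two-condition repeated-measures ANOVA per metric (patient as the blocking
factor; with two conditions its F equals the squared paired t statistic).

A 22-patient reference cohort of published per-patient scalp-EEG results is
shipped with the package (``load_reference_cohort``), so the statistics
stage is exercisable without any recordings.  In that cohort one patient's
selection includes the non-montage channel "CP2-Ref"; it is carried as a
labeled extra but excluded from the 1–23 channel-frequency counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "SummaryStats",
    "load_reference_cohort",
    "summarize",
    "relative_improvement",
    "rm_anova_paired",
    "channel_frequency",
    "cohort_report",
]

logger = logging.getLogger(__name__)

#: paired metric columns of a cohort table
METRIC_COLUMNS = (
    "pred_sel", "pred_all",
    "acc_sel", "acc_all",
    "sens_sel", "sens_all",
    "spec_sel", "spec_all",
)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    sum: float
    mean: float
    sd: float


def load_reference_cohort(path=None) -> pd.DataFrame:
    """Load a cohort table (the shipped 22-patient reference by default).

    Columns: patient_id, the eight METRIC_COLUMNS in percent, and
    channels_sel (semicolon-joined selected-channel tokens; integer indices
    1–23 plus possible extra labels).
    """
    if path is None:
        path = resources.files("eegselect.data") / "table3_cohort.csv"
    df = pd.read_csv(path, dtype={"patient_id": str, "channels_sel": str})
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    return df


def summarize(values: Sequence[float]) -> SummaryStats:
    """N, sum, mean and sample SD (n-1 denominator) of one metric column."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return SummaryStats(
        n=len(v), sum=float(v.sum()), mean=float(v.mean()), sd=float(v.std(ddof=1))
    )


def relative_improvement(mean_selected: float, mean_all: float) -> float:
    """Percent change of the selected-channel mean over the all-channel mean."""
    if mean_all <= 0:
        raise ValueError("all-channel baseline mean must be positive")
    return 100.0 * (mean_selected - mean_all) / mean_all


def rm_anova_paired(
    selected: Sequence[float], all_channels: Sequence[float]
) -> tuple[float, float]:
    """Two-condition repeated-measures ANOVA (patient as block): (F, p).

    The condition effect is tested on (1, n-1) degrees of freedom and
    equals the squared paired t statistic.
    """
    a = np.asarray(selected, dtype=float)
    b = np.asarray(all_channels, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must be paired (equal length)")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing pairs are not allowed")
    if np.array_equal(a, b):
        return 0.0, 1.0  # no condition effect at all; F is 0 by convention
    n = len(a)
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "condition": np.repeat(["selected", "all"], n),
            "value": np.concatenate([a, b]),
        }
    )
    table = AnovaRM(df, depvar="value", subject="subject", within=["condition"]).fit()
    row = table.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


def channel_frequency(
    selections: Sequence[Sequence[object]], n_channels: int = 23
) -> tuple[np.ndarray, dict[str, int]]:
    """How often each channel index 1..n was selected across patients.

    Non-integer tokens (e.g. a reference-electrode channel outside the
    bipolar montage) are tallied separately and logged, not counted in the
    per-index array.  Returns (counts indexed 0..n-1 for channels 1..n,
    extra-label counts).
    """
    counts = np.zeros(n_channels, dtype=int)
    extras: dict[str, int] = {}
    for sel in selections:
        for token in sel:
            try:
                idx = int(token)
            except (TypeError, ValueError):
                extras[str(token)] = extras.get(str(token), 0) + 1
                continue
            if not 1 <= idx <= n_channels:
                raise ValueError(f"channel index {idx} outside 1..{n_channels}")
            counts[idx - 1] += 1
    if extras:
        logger.info("non-montage channel labels excluded from counts: %s", extras)
    return counts, extras


def parse_channel_tokens(cell: str) -> list[str]:
    """Split a semicolon-joined channels_sel cell into tokens."""
    return [t.strip() for t in str(cell).split(";") if t.strip()]


def cohort_report(df: pd.DataFrame) -> dict:
    """Full cohort summary: per-column stats, improvements, ANOVAs, counts."""
    out: dict = {"columns": {}, "improvement_pct": {}, "anova": {}}
    for col in METRIC_COLUMNS:
        s = summarize(df[col].to_numpy())
        out["columns"][col] = {"n": s.n, "sum": s.sum, "mean": s.mean, "sd": s.sd}
    for metric in ("pred", "acc", "sens", "spec"):
        m_sel = out["columns"][f"{metric}_sel"]["mean"]
        m_all = out["columns"][f"{metric}_all"]["mean"]
        out["improvement_pct"][metric] = relative_improvement(m_sel, m_all)
        F, p = rm_anova_paired(df[f"{metric}_sel"], df[f"{metric}_all"])
        out["anova"][metric] = {"F": F, "p": p}
    selections = [parse_channel_tokens(c) for c in df["channels_sel"]]
    counts, extras = channel_frequency(selections)
    out["channel_frequency"] = {str(i + 1): int(c) for i, c in enumerate(counts)}
    out["non_montage_selections"] = extras
    return out
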