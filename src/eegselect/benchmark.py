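"""A standard synthetic benchmark for the whole selection pipeline.

One reproducible "patient": 23 channels at 256 Hz, 4 hours, 4 planted
seizures, informative channels {4, 7, 16} (P7-O1, C3-P3, P8-O2 in the
clinical montage) with pre-ictal regularity 0.8.  Normal sampling is
densified beyond the one-per-hour clinical rule so the recording stays
short enough to simulate while both classes reach useful sizes; the
genetic search is fed a balanced 200-windows-per-class training subset.
"""

from __future__ import annotations

import numpy as np

from .entropy import PeConfig, pe_feature_matrix
from .selection import GaConfig, KnnConfig, SelectionResult, run_knn_ga
from .signal_model import WindowingConfig
from .svm_eval import EvaluationReport, run_validation
from .synthetic import SyntheticCohortSpec, generate_labeled_cohort

__all__ = ["BenchmarkData", "make_benchmark", "GROUND_TRUTH"]

GROUND_TRUTH = frozenset({4, 7, 16})
_WINDOWS_PER_CLASS = 200


class BenchmarkData:
    """Cohort windows plus PE feature matrices, ready for selection/SVM."""

    def __init__(self, seed: int = 7):
        self.seed = seed
        spec = SyntheticCohortSpec(
            n_channels=23,
            fs=256.0,
            hours=4.0,
            n_seizures=4,
            informative_channels=GROUND_TRUTH,
            preictal_regularity=0.8,
            seed=seed,
            patient_id=f"bench{seed}",
        )
        cfg = WindowingConfig()
        self.train, self.test, self.ground_truth = generate_labeled_cohort(
            spec, cfg, n_train_seizures=2, normal_per_hour=110
        )
        pe_cfg = PeConfig()
        self.X_train, self.y_train = pe_feature_matrix(self.train, pe_cfg)
        self.X_test, self.y_test = pe_feature_matrix(self.test, pe_cfg)
        # balanced GA input: first 200 windows of each class, in time order
        idx = np.r_[
            np.where(self.y_train == "preictal")[0][:_WINDOWS_PER_CLASS],
            np.where(self.y_train == "normal")[0][:_WINDOWS_PER_CLASS],
        ]
        self.X_ga, self.y_ga = self.X_train[idx], self.y_train[idx]

    def run_selection(self, seed: int) -> SelectionResult:
        return run_knn_ga(
            self.X_ga, self.y_ga, GaConfig(seed=seed), KnnConfig()
        )

    def paired_validation(
        self, channels, seed: int
    ) -> tuple[EvaluationReport, EvaluationReport]:
        """Evaluate a channel subset and the all-channels baseline on
        bit-identical test windows with the same seed."""
        args = (self.X_train, self.y_train, self.X_test, self.y_test)
        sel = run_validation(self.train, self.test, sorted(channels), *args, seed=seed)
        allc = run_validation(self.train, self.test, None, *args, seed=seed)
        return sel, allc


def make_benchmark(seed: int = 7) -> BenchmarkData:
    return BenchmarkData(seed)
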