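import numpy as np
import pytest

import eegselect as es

# Small, fast synthetic "patients" for unit tests run at a reduced sampling
# rate: permutation entropy is rank-based, so the planted ordinal contrast
# survives downsampling while recordings shrink by 4x.


@pytest.fixture(scope="session")
def small_spec():
    return es.SyntheticCohortSpec(
        n_channels=8,
        fs=64.0,
        hours=2.0,
        n_seizures=2,
        informative_channels=frozenset({2, 5}),
        preictal_regularity=0.8,
        seed=11,
        patient_id="unit",
    )


@pytest.fixture(scope="session")
def small_recording(small_spec):
    return es.generate_recording(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    train, test, truth = es.generate_labeled_cohort(
        small_spec, es.WindowingConfig(), normal_per_hour=60
    )
    return train, test, truth


@pytest.fixture(scope="session")
def small_features(small_cohort):
    train, test, truth = small_cohort
    X, y = es.pe_feature_matrix(train, es.PeConfig())
    return X, y, truth


def make_recording(
    n_channels=2, fs=256.0, duration_s=7200.0, onsets=(), seed=0, montage=None
):
    """Plain white-noise recording helper for windowing tests."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    if montage is None:
        montage = es.ChannelMontage.generic(n_channels)
    return es.EegRecording(
        samples=rng.normal(0, 15, size=(n_channels, n)).astype(np.float32),
        fs=fs,
        seizure_onsets=tuple(onsets),
        montage=montage,
        patient_id="test",
    )


@pytest.fixture(scope="session")
def benchmark():
    """Full-scale synthetic benchmark (23 ch, 256 Hz); built once per run."""
    from eegselect.benchmark import make_benchmark

    return make_benchmark(seed=7)


@pytest.fixture(scope="session")
def benchmark_selections(benchmark):
    """Ten seeded genetic-search runs on the benchmark's balanced subset."""
    return [benchmark.run_selection(seed) for seed in range(10)]
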