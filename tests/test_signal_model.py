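"""Windowing, labeling and sampling rules of the SPH scheme."""

import numpy as np
import pytest

import eegselect as es
from conftest import make_recording


def test_chbmit_montage():
    m = es.ChannelMontage.chbmit()
    assert len(m) == 23
    assert [i for i, _ in m.entries] == list(range(1, 24))
    # the montage legitimately repeats "T8-P8" at indices 15 and 23
    assert m.labels[14] == m.labels[22] == "T8-P8"
    assert m.index_of("p7-o1") == 4  # case-insensitive lookup, first match


def test_montage_requires_consecutive_indices():
    with pytest.raises(ValueError):
        es.ChannelMontage(((1, "A"), (3, "B")))


def test_recording_invariants():
    rec = make_recording(duration_s=10.0)
    assert rec.n_samples == round(10.0 * 256)
    assert rec.duration_s == pytest.approx(10.0)
    with pytest.raises(ValueError, match="increasing"):
        make_recording(duration_s=3600, onsets=(100.0, 100.0))
    with pytest.raises(ValueError, match="within"):
        make_recording(duration_s=3600, onsets=(4000.0,))
    with pytest.raises(ValueError, match="montage"):
        es.EegRecording(
            samples=np.zeros((3, 100)),
            fs=256,
            seizure_onsets=(),
            montage=es.ChannelMontage.generic(2),
        )


def test_window_sample_length_is_rounded():
    cfg = es.WindowingConfig()
    assert cfg.window_samples(256) == 717  # round(2.8 * 256) = round(716.8)
    assert cfg.window_samples(100) == 280


@pytest.mark.parametrize(
    "onset, expected",
    [(3600.0, 214), (300.0, 107)],  # full horizon: floor(600/2.8); truncated at t=0
)
def test_preictal_tiling_counts(onset, expected):
    rec = make_recording(duration_s=onset + 10, onsets=(onset,))
    wins = es.extract_preictal_windows(rec)
    assert len(wins) == expected
    w = 717
    # back-to-back, ending exactly at onset
    assert wins[-1].start_s == pytest.approx(onset - w / 256)
    starts = [win.start_s for win in wins]
    np.testing.assert_allclose(np.diff(starts), w / 256)
    assert all(win.label == "preictal" and win.seizure_index == 1 for win in wins)
    assert all(win.data.shape == (2, w) for win in wins)


def test_no_seizures_gives_no_preictal_windows():
    rec = make_recording(duration_s=3600)
    assert es.extract_preictal_windows(rec) == []


def test_preictal_respects_previous_postictal_zone():
    # second onset 35 min after the first: its horizon collides with the
    # first seizure's 30-min post-ictal zone and must be truncated to 5 min
    rec = make_recording(duration_s=7200, onsets=(3600.0, 5700.0))
    wins = es.extract_preictal_windows(rec)
    second = [w for w in wins if w.seizure_index == 2]
    assert len(second) == int(300 // 2.8)
    assert min(w.start_s for w in second) >= 3600 + 1800


def test_windowing_invariants_on_randomized_recordings():
    rng = np.random.default_rng(0)
    cfg = es.WindowingConfig()
    for trial in range(5):
        onsets = np.sort(rng.uniform(1000, 13000, size=rng.integers(1, 4)))
        onsets = tuple(t for i, t in enumerate(onsets) if i == 0 or t - onsets[i - 1] > 2500)
        rec = make_recording(n_channels=1, duration_s=14400, onsets=onsets, seed=trial)
        pre = es.extract_preictal_windows(rec, cfg)
        nor = es.sample_normal_windows(rec, cfg, np.random.default_rng(trial))
        w_s = 717 / 256
        for win in pre:
            t = rec.seizure_onsets[win.seizure_index - 1]
            assert t - 600 - 1e-9 <= win.start_s and win.start_s + w_s <= t + 1e-9
        for win in nor:
            for t in rec.seizure_onsets:
                assert win.start_s + w_s <= t - 600 or win.start_s >= t + 1800


def test_normal_sampling_one_per_hour_and_determinism():
    rec = make_recording(n_channels=1, duration_s=10 * 3600)
    a = es.sample_normal_windows(rec, rng=np.random.default_rng(9))
    b = es.sample_normal_windows(rec, rng=np.random.default_rng(9))
    assert len(a) == 10
    assert [w.start_s for w in a] == [w.start_s for w in b]
    # each window sits inside its own hour
    for hour, w in enumerate(a):
        assert hour * 3600 <= w.start_s and w.start_s + 717 / 256 <= (hour + 1) * 3600


def test_fully_excluded_hour_contributes_nothing():
    # two exclusion zones [3600, 6000] and [6000, 8400] jointly blanket hour 1
    rec = make_recording(n_channels=1, duration_s=3 * 3600, onsets=(4200.0, 6600.0))
    wins = es.sample_normal_windows(rec, rng=np.random.default_rng(1))
    hours = {int(w.start_s // 3600) for w in wins}
    assert 1 not in hours
    assert len(wins) == 2


def test_enforce_ratio():
    rec = make_recording(n_channels=1, duration_s=60)
    win = lambda lab, t, si=None: es.LabeledWindow(
        data=rec.samples[:, :717], label=lab, start_s=t, seizure_index=si
    )
    normal = [win("normal", float(i)) for i in range(500)]
    pre = [win("preictal", float(i), 1) for i in range(40)]
    kept = es.enforce_ratio(normal, pre, 10, np.random.default_rng(0))
    assert len(kept) == 400
    assert set(id(w) for w in kept) <= set(id(w) for w in normal)
    # already under the cap -> untouched
    assert es.enforce_ratio(normal[:50], pre, 10, np.random.default_rng(0)) == normal[:50]
    with pytest.raises(ValueError):
        es.enforce_ratio(normal, [], 10, np.random.default_rng(0))


def test_chronological_split():
    cfg = es.WindowingConfig()
    rec = make_recording(
        n_channels=1, duration_s=8 * 3600,
        onsets=tuple(3600.0 * k + 1800 for k in range(7)),
    )
    pre = es.extract_preictal_windows(rec, cfg)
    nor = es.sample_normal_windows(rec, rng=np.random.default_rng(2))
    train, test = es.chronological_split(pre + nor, 4, cfg, np.random.default_rng(3))
    tr_ids = {w.seizure_index for w in train if w.label == "preictal"}
    te_ids = {w.seizure_index for w in test if w.label == "preictal"}
    assert tr_ids == {1, 2, 3, 4} and te_ids == {5, 6, 7}
    assert tr_ids.isdisjoint(te_ids)
    boundary = min(w.start_s for w in test if w.label == "preictal")
    assert all(w.start_s < boundary for w in train if w.label == "normal")
    for part in (train, test):
        n_pre = sum(w.label == "preictal" for w in part)
        n_nor = sum(w.label == "normal" for w in part)
        assert n_nor <= 10 * n_pre
    # order invariance: shuffled input gives the same split
    shuffled = list(pre + nor)
    np.random.default_rng(4).shuffle(shuffled)
    train2, test2 = es.chronological_split(shuffled, 4, cfg, np.random.default_rng(3))
    assert [w.start_s for w in train2] == [w.start_s for w in train]
    assert [w.start_s for w in test2] == [w.start_s for w in test]


def test_chronological_split_range_errors():
    cfg = es.WindowingConfig()
    rec = make_recording(n_channels=1, duration_s=2 * 3600, onsets=(1800.0, 5400.0))
    wins = es.extract_preictal_windows(rec, cfg)
    for bad in (0, 2, 5):
        with pytest.raises(ValueError):
            es.chronological_split(wins, bad, cfg, np.random.default_rng(0))


def test_preictal_windows_require_seizure_index():
    with pytest.raises(ValueError):
        es.LabeledWindow(data=np.zeros((1, 10)), label="preictal", start_s=0.0)
    with pytest.raises(ValueError):
        es.LabeledWindow(data=np.zeros((1, 10)), label="ictal", start_s=0.0)
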