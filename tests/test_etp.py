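"""Extraction-transformation process: sample mapping, epoch cutting,
trimming arithmetic and min-max normalization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from vdep_eeg import Epoch, extract_epochs, map_second_to_samples, normalize_epoch, normalize_epochs
from vdep_eeg.annotations import IntervalSet
from vdep_eeg.etp import EpochError, EpochSet
from vdep_eeg.synthetic import RecordingSet


def make_interval_set(intervals, vdep="colour"):
    df = pd.DataFrame(intervals, columns=["video", "start", "end", "cls"])
    return IntervalSet(vdep=vdep, intervals=df)


def ramp_recordings(n_participants=1, n_trials=1):
    """Recording whose sample values equal their sample index."""
    ramp = np.arange(8064, dtype=np.float32)
    data = np.broadcast_to(ramp, (n_participants, n_trials, 40, 8064)).copy()
    return RecordingSet(data=data, fs=128, channel_names=[str(i) for i in range(40)],
                        baseline_s=3, n_tagged=n_trials)


class TestSampleMapping:
    @pytest.mark.parametrize("second, expected", [(0, (384, 512)), (59, (7936, 8064))])
    def test_baseline_offset_arithmetic(self, second, expected):
        assert map_second_to_samples(second, fs=128, baseline_s=3) == expected

    @pytest.mark.parametrize("second", [-1, 60, 100])
    def test_out_of_range_rejected(self, second):
        with pytest.raises(EpochError):
            map_second_to_samples(second)


class TestExtraction:
    @pytest.mark.parametrize("length, expected", [(1, 0), (2, 1), (3, 2), (5, 4), (10, 9)])
    def test_interval_length_to_epoch_count(self, length, expected):
        es = extract_epochs(ramp_recordings(), make_interval_set([(0, 0, length, 1)]))
        assert len(es) == expected

    def test_one_second_yields_one_epoch_per_participant(self):
        # a 2-s interval survives trimming as exactly one 1-s epoch,
        # replicated across the participant pool
        es = extract_epochs(ramp_recordings(n_participants=32),
                            make_interval_set([(0, 10, 12, 2)]))
        assert len(es) == 32
        assert es.meta["participant"].nunique() == 32
        assert (es.meta["second"] == 10).all()

    def test_epoch_samples_start_half_second_into_interval(self):
        es = extract_epochs(ramp_recordings(), make_interval_set([(0, 5, 8, 1)]))
        # epoch k of interval [5, 8) starts at (3 + 5 + k) * 128 + 64
        starts = sorted(e[0, 0] for e in es.data)
        assert starts == [(3 + 5 + k) * 128 + 64 for k in range(2)]
        assert es.data.shape[1:] == (128, 32)  # peripheral channels dropped

    def test_epochs_never_touch_baseline_or_cross_intervals(self):
        es = extract_epochs(ramp_recordings(), make_interval_set([(0, 0, 60, 1)]))
        first = es.data[:, 0, 0]
        last = es.data[:, -1, 0]
        assert first.min() >= 3 * 128  # baseline excluded
        assert last.max() < 8064

    def test_missing_trial_skipped_with_warning(self, caplog):
        iv = make_interval_set([(0, 0, 5, 1), (7, 0, 5, 2)])
        with caplog.at_level("WARNING"):
            es = extract_epochs(ramp_recordings(n_trials=1), iv)
        assert len(es) == 4  # only the present trial contributed
        assert "skipped" in caplog.text

    @given(st.lists(st.tuples(st.integers(0, 1),      # video
                              st.integers(0, 55),     # start
                              st.integers(1, 10),     # length
                              st.sampled_from([1, 2])),
                    min_size=1, max_size=8))
    def test_count_matches_brute_force_enumerator(self, raw):
        # brute-force oracle: per interval, per participant, one epoch
        # for every second s with [s+0.5, s+1.5) inside the interval
        intervals, occupied = [], {0: set(), 1: set()}
        for video, start, length, cls in raw:
            end = min(start + length, 60)
            if occupied[video] & set(range(start, end)):
                continue  # keep intervals disjoint within a trial
            occupied[video].update(range(start, end))
            intervals.append((video, start, end, cls))
        n_p = 2
        rec = ramp_recordings(n_participants=n_p, n_trials=2)
        es = extract_epochs(rec, make_interval_set(intervals))
        oracle = n_p * sum(
            sum(1 for s in range(start, end) if s + 2 <= end)
            for _, start, end, _ in intervals
        )
        assert len(es) == oracle


class TestNormalization:
    def test_hand_computed_example(self):
        e = Epoch(np.array([[0.0, 5.0], [10.0, 5.0]]), 0, 0, 0, "colour", 1)
        out = normalize_epoch(e)
        assert np.allclose(out.data, [[0.0, 0.5], [1.0, 0.5]])
        assert out.normalized

    @given(hnp.arrays(np.float64, (16, 4),
                      elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_bounds_and_affine_invariance(self, mat):
        e = Epoch(mat, 0, 0, 0, "colour", 1)
        out = normalize_epoch(e)
        assert out.data.min() >= 0 and out.data.max() <= 1
        if np.ptp(mat) > 1e-6 * max(1.0, np.abs(mat).max()):
            assert np.isclose(out.data.min(), 0) and np.isclose(out.data.max(), 1)
            scaled = normalize_epoch(Epoch(3.5 * mat + 11.0, 0, 0, 0, "colour", 1))
            assert np.allclose(out.data, scaled.data, atol=1e-9)

    def test_constant_epoch_becomes_zeros_with_warning(self, caplog):
        e = Epoch(np.full((8, 2), 4.2), 0, 0, 0, "colour", 1)
        with caplog.at_level("WARNING"):
            out = normalize_epoch(e)
        assert np.all(out.data == 0)
        assert "degenerate" in caplog.text

    def test_renormalizing_is_a_contract_error(self, small_epochs):
        normed = normalize_epochs(small_epochs)
        with pytest.raises(EpochError):
            normalize_epochs(normed)

    def test_epoch_set_normalization_matches_single(self, small_epochs):
        normed = normalize_epochs(small_epochs)
        one = normalize_epoch(Epoch(small_epochs.data[0].astype(np.float64),
                                    0, 0, 0, "colour", 1))
        assert np.allclose(normed.data[0], one.data, atol=1e-6)
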