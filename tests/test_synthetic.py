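"""Generator contracts: shapes, determinism, run structure, injected
band effects and the annotator corruption model."""
import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from vdep_eeg import (
    BAND_NAMES,
    ConfigError,
    SimConfig,
    VDEPS,
    build_intervals,
    extract_epochs,
    make_expert_tags,
    make_recordings,
    make_truth,
    resolve_tags,
)
from vdep_eeg.synthetic import band_center_frequencies, expected_keep_probability


def _run_lengths(table: pd.DataFrame) -> np.ndarray:
    """Run-length oracle over the latent class sequences."""
    out = []
    for (_, _), grp in table.groupby(["video", "vdep"]):
        cls = grp.sort_values("second")["cls"].to_numpy()
        changes = np.flatnonzero(np.diff(cls) != 0)
        bounds = np.concatenate([[-1], changes, [len(cls) - 1]])
        out.append(np.diff(bounds))
    return np.concatenate(out)


class TestTruth:
    def test_timestamp_count_matches_tagged_videos(self):
        # 26 one-minute videos -> 1560 annotated (video, second) pairs
        cfg = SimConfig(n_participants=1, n_videos=26, n_trials=40, seed=0)
        truth = make_truth(cfg)
        for vdep in VDEPS:
            assert (truth.table["vdep"] == vdep).sum() == 1560
        assert truth.table["second"].between(0, 59).all()

    def test_deterministic_under_seed(self, small_cfg):
        t1, t2 = make_truth(small_cfg), make_truth(small_cfg)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        t3 = make_truth(SimConfig(**{**small_cfg.__dict__, "seed": 8}))
        assert not t1.table.equals(t3.table)

    def test_unit_mean_run_gives_alternating_classes(self):
        cfg = SimConfig(n_participants=1, n_videos=5, n_trials=5, mean_run_s=1.0, seed=3)
        lengths = _run_lengths(make_truth(cfg).table)
        assert (lengths == 1).all()

    def test_run_lengths_follow_geometric_law(self):
        # interior truncation bias is negligible at 60 s per video
        cfg = SimConfig(n_participants=1, n_videos=300, n_trials=300, mean_run_s=2.0, seed=5)
        lengths = _run_lengths(make_truth(cfg).table)
        frac_ge2 = (lengths >= 2).mean()
        # geometric(p=1/2): P(L >= 2) = 1/2
        assert abs(frac_ge2 - 0.5) < 0.02
        assert abs(lengths.mean() - 2.0) < 0.05

    def test_invalid_run_length_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(mean_run_s=0.5)


class TestRecordings:
    def test_shape_is_trials_by_channels_by_samples(self, small_world):
        rec = small_world["rec"]
        assert rec.data.shape == (2, 4, 40, 63 * 128)

    def test_default_geometry_yields_40x40x8064(self):
        cfg = SimConfig(n_participants=1, seed=1)
        rec = make_recordings(cfg, make_truth(cfg))
        assert rec.data.shape[1:] == (40, 40, 8064)

    def test_bit_identical_under_seed(self, small_cfg, small_world):
        rec2 = make_recordings(small_cfg, small_world["truth"])
        assert np.array_equal(small_world["rec"].data, rec2.data)

    def test_unknown_band_gain_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(band_gains={1: {"mu": 2.0}, 2: {}})
        with pytest.raises(ConfigError):
            SimConfig(gain_vdeps=["colour", "texture"])

    def test_band_centers_are_bin_aligned(self):
        for f in band_center_frequencies().values():
            assert f == int(f) and 1 <= f < 45


def _epoch_band_power_oracle(es, lo, hi):
    """Independent periodogram integration, per epoch."""
    f, pxx = periodogram(es.data.astype(float), fs=es.fs, axis=1,
                         window="boxcar", detrend=False)
    m = (f >= lo) & (f < hi)
    m[0] = m[-1] = False
    return pxx[:, m, :].sum(axis=1).mean(axis=1)


class TestInjectedEffects:
    def _epochs(self, gains, seed=11, **kw):
        cfg = SimConfig(n_participants=4, n_videos=4, n_trials=4, seed=seed,
                        band_gains=gains, gain_vdeps=["colour"],
                        annot_agreement=1.0, annot_unclear=0.0, **kw)
        truth = make_truth(cfg)
        rec = make_recordings(cfg, truth)
        a, b = make_expert_tags(cfg, truth)
        tl = resolve_tags(a, b)
        return extract_epochs(rec, build_intervals(tl, "colour"))

    def test_null_gains_give_equal_class_powers(self):
        es = self._epochs({1: {}, 2: {}})
        alpha = _epoch_band_power_oracle(es, 8, 13)
        cls = es.labels
        ratio = alpha[cls == 1].mean() / alpha[cls == 2].mean()
        assert 0.95 < ratio < 1.05

    def test_doubled_alpha_amplitude_quadruples_alpha_power(self):
        # power scales with amplitude squared; low noise isolates the tone
        es = self._epochs({1: {"alpha": 2.0}, 2: {}}, noise_std=0.1)
        assert len(es) >= 500
        alpha = _epoch_band_power_oracle(es, 8, 13)
        cls = es.labels
        ratio = alpha[cls == 1].mean() / alpha[cls == 2].mean()
        assert abs(ratio - 4.0) < 0.2
        # the other bands are untouched
        for lo, hi in [(1, 4), (4, 8), (13, 30), (30, 45)]:
            other = _epoch_band_power_oracle(es, lo, hi)
            r = other[cls == 1].mean() / other[cls == 2].mean()
            assert abs(r - 1.0) < 0.05

    def test_band_power_monotone_in_gain(self):
        means = []
        for g in (1.0, 1.5, 2.0):
            es = self._epochs({1: {"alpha": g}, 2: {}}, noise_std=0.5)
            alpha = _epoch_band_power_oracle(es, 8, 13)
            assert len(es) >= 500
            means.append(alpha[es.labels == 1].mean())
        assert means[0] < means[1] < means[2]


class TestExpertTags:
    def test_noiseless_experts_reproduce_truth(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "annot_agreement": 1.0, "annot_unclear": 0.0})
        truth = make_truth(cfg)
        a, b = make_expert_tags(cfg, truth)
        for tags in (a, b):
            merged = truth.table.merge(tags, on=["video", "second", "vdep"])
            assert (merged["cls"] == merged["label"]).all()

    def test_all_unclear_empties_the_timeline(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "annot_unclear": 1.0})
        truth = make_truth(cfg)
        tl = resolve_tags(*make_expert_tags(cfg, truth))
        assert len(tl.records) == 0
        assert (tl.discarded["reason"] == "unclear").all()

    def test_discard_fraction_matches_corruption_model(self):
        cfg = SimConfig(n_participants=1, n_videos=420, n_trials=420, seed=21,
                        annot_agreement=0.9, annot_unclear=0.05)
        truth = make_truth(cfg)
        tl = resolve_tags(*make_expert_tags(cfg, truth))
        keep = len(tl.records) / (len(tl.records) + len(tl.discarded))
        expected = expected_keep_probability(cfg)
        n = len(truth.table)
        assert n >= 100_000
        tol = 4 * np.sqrt(expected * (1 - expected) / n)
        assert abs(keep - expected) < tol
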