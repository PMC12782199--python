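import numpy as np
import pytest

from ssvepipe.preprocess import (
    bin_trial,
    detect_bad_channels,
    interpolate_bad_channels,
    preprocess_trial,
    reject_bins,
    rereference_common_average,
)
from ssvepipe.protocol import ProtocolConfig
from ssvepipe.simulate import EffectSpec, SensorTrial, make_montage, simulate_trial
from ssvepipe.experiments import reduced_protocol


def _trial(data, montage=None):
    return SensorTrial("S1", "OD", "ON", 0, data, 500.0, montage)


class TestBadChannels:
    def test_flagged_above_threshold(self):
        data = np.zeros((3, 100))
        data[0, :20] = 35.0  # 20% of samples above 30 µV
        flags = detect_bad_channels(_trial(data))
        assert flags.tolist() == [True, False, False]

    def test_all_zero_not_flagged(self):
        assert not detect_bad_channels(_trial(np.zeros((4, 50)))).any()

    def test_boundary_is_strict(self):
        """Exactly 15.0% of samples exceeding → kept ('over 15%' is strict)."""
        data = np.zeros((1, 100))
        data[0, :15] = 31.0
        assert not detect_bad_channels(_trial(data)).any()
        data[0, 15] = 31.0  # 16%
        assert detect_bad_channels(_trial(data)).all()

    def test_negative_excursions_count(self):
        data = np.zeros((1, 100))
        data[0, :20] = -35.0
        assert detect_bad_channels(_trial(data)).all()

    def test_empty_trial_rejected(self):
        with pytest.raises(ValueError):
            detect_bad_channels(_trial(np.zeros((0, 0))))


class TestInterpolation:
    def test_constant_neighbors(self, montage16):
        data = np.zeros((16, 50))
        flags = np.zeros(16, dtype=bool)
        flags[3] = True
        nbrs = montage16.nearest_neighbors(3, 6, candidates=np.flatnonzero(~flags))
        data[nbrs] = 5.0
        out = interpolate_bad_channels(_trial(data, montage16), flags)
        np.testing.assert_allclose(out.data[3], 5.0)

    def test_no_flags_is_identity(self, montage16):
        data = np.random.default_rng(0).normal(size=(16, 50))
        out = interpolate_bad_channels(_trial(data, montage16), np.zeros(16, bool))
        np.testing.assert_array_equal(out.data, data)

    def test_matches_brute_force_neighbor_mean(self):
        m = make_montage(8, seed=3)
        rng = np.random.default_rng(1)
        data = rng.normal(size=(8, 30))
        flags = np.zeros(8, bool)
        flags[2] = True
        out = interpolate_bad_channels(_trial(data, m), flags)
        d = np.linalg.norm(m.positions - m.positions[2], axis=1)
        order = [i for i in np.argsort(d) if i != 2 and not flags[i]][:6]
        np.testing.assert_allclose(out.data[2], data[order].mean(axis=0))
        unflagged = np.flatnonzero(~flags)
        np.testing.assert_array_equal(out.data[unflagged], data[unflagged])

    def test_too_few_good_channels(self, montage16):
        flags = np.ones(16, bool)
        flags[:5] = False
        with pytest.raises(ValueError):
            interpolate_bad_channels(_trial(np.zeros((16, 10)), montage16), flags)


class TestRereference:
    def test_balanced_pair_unchanged(self):
        data = np.array([[1.0, 1.0], [-1.0, -1.0]])
        out = rereference_common_average(_trial(data))
        np.testing.assert_array_equal(out.data, data)

    def test_constant_offset_removed(self):
        out = rereference_common_average(_trial(np.full((5, 10), 10.0)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_column_means_zero(self):
        data = np.random.default_rng(2).normal(size=(32, 200))
        out = rereference_common_average(_trial(data))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10


class TestBinning:
    def test_partition(self):
        p = ProtocolConfig(n_channels=8)
        data = np.arange(8 * 6600, dtype=float).reshape(8, 6600)
        bins = bin_trial(_trial(data), p)
        assert bins.shape == (12, 8, 550)
        # concatenating the usable bins (2..11) reproduces samples 551–6050 (1-based)
        usable = np.concatenate([bins[b] for b in range(1, 11)], axis=1)
        np.testing.assert_array_equal(usable, data[:, 550:6050])

    def test_short_trial_rejected(self):
        p = ProtocolConfig(n_channels=2)
        with pytest.raises(ValueError):
            bin_trial(_trial(np.zeros((2, 6599))), p)


class TestRejection:
    def _bins(self, n_bins=4, n_ch=128, m=550):
        return np.zeros((n_bins, n_ch, m))

    def test_whole_bin_five_percent_rule(self):
        bins = self._bins()
        bins[1, :7, 0] = 61.0  # 7/128 = 5.47% > 5% → rejected
        bins[2, :6, 0] = 61.0  # 6/128 = 4.69% → kept
        mask = reject_bins(bins)
        assert mask.rejected_bins[1]
        assert not mask.rejected_bins[2]
        # whole-bin rejection implies all channel-bins rejected
        assert mask.rejected_channel_bins[1].all()

    def test_channel_bin_ten_percent_rule(self):
        bins = self._bins()
        n_exceed = int(0.11 * 550)
        bins[1, 5, :n_exceed] = 31.0
        mask = reject_bins(bins)
        assert mask.rejected_channel_bins[1, 5]
        assert not mask.rejected_bins[1]
        assert mask.rejected_channel_bins[1].sum() == 1

    def test_edge_bins_always_rejected(self):
        mask = reject_bins(self._bins())
        assert mask.rejected_bins[0] and mask.rejected_bins[-1]
        assert not mask.rejected_bins[1:-1].any()

    def test_rejection_monotone_in_amplitude(self):
        """Adding amplitude never un-rejects anything."""
        rng = np.random.default_rng(4)
        bins = rng.normal(scale=25.0, size=(4, 32, 100))
        before = reject_bins(bins)
        louder = bins + np.sign(bins) * 10.0
        after = reject_bins(louder)
        assert (after.rejected_bins | ~before.rejected_bins).all()
        assert (after.rejected_channel_bins | ~before.rejected_channel_bins).all()


class TestPipelineOrder:
    def test_artifact_free_trial_keeps_all_inner_bins(self, montage16, quiet_effect, control_state):
        p = reduced_protocol()
        effect = EffectSpec()  # noise 2 µV, no artifacts
        trial = simulate_trial(p, effect, control_state, "ON", montage16, seed=10)
        bins, mask = preprocess_trial(trial, p, montage=montage16)
        assert not mask.bad_channels.any()
        assert mask.rejected_bins.tolist() == [True, False, False, True]
        assert not mask.rejected_channel_bins[1:-1].any()

    def test_artifacts_trip_thresholds(self, montage16, control_state):
        p = reduced_protocol()
        effect = EffectSpec(blink_rate=3.0, muscle_rate=3.0)
        tripped = 0
        for seed in range(5):
            trial = simulate_trial(p, effect, control_state, "ON", montage16, seed=seed)
            _, mask = preprocess_trial(trial, p, montage=montage16)
            inner = slice(1, p.n_bins - 1)
            tripped += mask.rejected_bins[inner].any() or mask.rejected_channel_bins[inner].any()
        assert tripped >= 4  # high artifact rates must actually cause rejections

    def test_bad_channel_detected_and_substituted(self, montage16, control_state):
        p = reduced_protocol()
        effect = EffectSpec(bad_channel_rate=1.0)
        trial = simulate_trial(p, effect, control_state, "ON", montage16, seed=1)
        bad = detect_bad_channels(trial)
        assert bad.sum() == 1
        fixed = interpolate_bad_channels(trial, bad, montage16)
        assert not detect_bad_channels(fixed).any()
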