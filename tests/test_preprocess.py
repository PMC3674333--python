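"""Filtering, trimming, epoching, artifact thresholds, referencing, baseline."""

import numpy as np
import pytest

from muerd.conditions import ConditionKey
from muerd.errors import DegenerateDataError, ParameterError
from muerd.io import Recording
from muerd.preprocess import (
    ArtifactThresholds,
    average_reference,
    bandpass_filter,
    baseline_correct,
    detect_artifacts,
    epoch,
    trim_and_concatenate,
)
from tests.conftest import make_epochset


def _rec(data, sfreq=250.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Recording(data, sfreq, list(range(1, data.shape[0] + 1)))


class TestBandpassFilter:
    def test_dc_removed(self):
        rec = _rec(np.full((2, 5000), 50.0))
        out = bandpass_filter(rec)
        assert np.abs(out.data).max() < 0.5  # < 1% of the 50 uV input

    @pytest.mark.parametrize(
        "freq, lo, hi",
        [(10.0, 0.90, 1.10), (50.0, 0.0, 0.10)],
        ids=["passband-10Hz", "stopband-50Hz"],
    )
    def test_frequency_response(self, freq, lo, hi):
        t = np.arange(20 * 250) / 250.0
        out = bandpass_filter(_rec(np.sin(2 * np.pi * freq * t)))
        amp = np.abs(out.data[0, 1000:-1000]).max()
        assert lo <= amp <= hi

    def test_high_corner_above_nyquist_rejected(self):
        with pytest.raises(ParameterError, match="Nyquist"):
            bandpass_filter(_rec(np.zeros((1, 100)), sfreq=50.0), high=30.0)

    def test_shape_preserved(self):
        rec = _rec(np.random.default_rng(0).normal(size=(3, 2000)))
        assert bandpass_filter(rec).data.shape == rec.data.shape


class TestTrimConcat:
    def test_two_80s_trials_give_120s(self):
        sf = 50.0
        trials = [_rec(np.ones((2, int(80 * sf))), sf) for _ in range(2)]
        seg = trim_and_concatenate(trials, 10.0)
        assert seg.n_samples == int(120 * sf)

    def test_single_30s_trial_gives_10s(self):
        sf = 50.0
        seg = trim_and_concatenate([_rec(np.ones((1, int(30 * sf))), sf)], 10.0)
        assert seg.n_samples == int(10 * sf)

    def test_nothing_left_is_degenerate(self):
        sf = 50.0
        with pytest.raises(DegenerateDataError, match="nothing"):
            trim_and_concatenate([_rec(np.ones((1, int(20 * sf))), sf)], 10.0)

    def test_provenance_points_into_source(self):
        sf = 10.0
        trials = [_rec(np.ones((1, 300)), sf), _rec(np.ones((1, 300)), sf)]
        seg = trim_and_concatenate(trials, 5.0, source_offsets=[0, 300])
        # first retained sample of trial 1 sits at source sample 300 + 50
        first_t1 = np.flatnonzero(seg.source_trial == 1)[0]
        assert seg.source_index[first_t1] == 350


class TestEpoch:
    def test_120s_gives_60_epochs(self):
        sf = 50.0
        seg = trim_and_concatenate(
            [_rec(np.ones((1, int(80 * sf))), sf) for _ in range(2)], 10.0
        )
        assert epoch(seg, 2.0).n_epochs == 60

    def test_trailing_remainder_dropped(self):
        sf = 10.0
        seg = trim_and_concatenate([_rec(np.ones((1, 610)), sf)], 0.0)
        assert epoch(seg, 2.0).n_epochs == 30

    def test_no_epoch_spans_trial_seam(self):
        sf = 10.0
        # trial index encoded in the samples themselves: 0s then 1s
        trials = [_rec(np.zeros((1, 30)), sf), _rec(np.ones((1, 30)), sf)]
        eps = epoch(trim_and_concatenate(trials, 0.5, source_offsets=[0, 30]), 1.0)
        assert eps.n_epochs == 4  # 2.5 s per trial -> 2 whole epochs each
        for i in range(eps.n_epochs):
            vals = np.unique(eps.epochs[i])
            assert len(vals) == 1, "epoch mixes samples from two trials"
            assert vals[0] == eps.source_trials[i]


class TestDetectArtifacts:
    def test_clean_epoch_retained(self, layout21):
        eps = make_epochset(np.zeros((1, 21, 100)), 100.0)
        out = detect_artifacts(eps, layout21)
        assert out.retained.all()
        assert out.reject_reasons[0] == ()

    def test_amplitude_rule(self, layout21):
        data = np.zeros((1, 21, 100))
        data[0, 0, 50] = 300.0
        out = detect_artifacts(make_epochset(data, 100.0), layout21)
        assert out.reject_reasons[0] == ("amplitude",)

    def test_veog_rule(self, layout21):
        above, below = layout21.veog_pairs[0]
        data = np.zeros((1, 21, 100))
        data[0, above - 1, 10] = 90.0
        data[0, below - 1, 10] = -60.0  # difference 150 > 140
        out = detect_artifacts(make_epochset(data, 100.0), layout21)
        assert out.reject_reasons[0] == ("veog",)

    def test_heog_rule(self, layout21):
        left, right = layout21.heog_pair
        data = np.zeros((1, 21, 100))
        data[0, left - 1, :] = 30.0
        data[0, right - 1, :] = -30.0  # difference 60 > 55
        out = detect_artifacts(make_epochset(data, 100.0), layout21)
        assert out.reject_reasons[0] == ("heog",)

    def test_peak_to_peak_mode(self, layout21):
        data = np.zeros((1, 21, 100))
        data[0, 0, 10], data[0, 0, 20] = 110.0, -110.0  # p2p 220, abs max 110
        eps = make_epochset(data, 100.0)
        assert detect_artifacts(eps, layout21).retained[0]
        assert not detect_artifacts(eps, layout21, mode="peak-to-peak").retained[0]

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ParameterError):
            ArtifactThresholds(veog_diff=0.0)


class TestAverageReference:
    def test_balanced_pair_unchanged(self):
        eps = make_epochset(np.array([[[5.0], [-5.0]]]), 100.0)
        out = average_reference(eps)
        np.testing.assert_allclose(out.epochs, eps.epochs)

    def test_common_offset_removed(self):
        eps = make_epochset(np.full((1, 4, 10), 7.0), 100.0)
        np.testing.assert_allclose(average_reference(eps).epochs, 0.0)

    def test_scalp_mean_is_zero_and_idempotent(self, layout21):
        rng = np.random.default_rng(0)
        eps = make_epochset(rng.normal(size=(3, 21, 50)), 100.0)
        once = average_reference(eps, layout21)
        rows = [i for i, c in enumerate(once.channel_ids) if c in layout21.scalp_channels]
        np.testing.assert_allclose(
            once.epochs[:, rows, :].mean(axis=1), 0.0, atol=1e-9 * np.abs(eps.epochs).max()
        )
        twice = average_reference(once, layout21)
        np.testing.assert_allclose(twice.epochs, once.epochs, atol=1e-12)


class TestBaselineCorrect:
    def test_constant_window_shifts_epoch(self):
        source = _rec(np.full((1, 1000), 3.0), 100.0)
        eps = make_epochset(np.zeros((1, 1, 100)), 100.0, source_offset=500)
        out = baseline_correct(eps, source, 200.0)
        np.testing.assert_allclose(out.epochs, -3.0)

    def test_zero_mean_window_leaves_epoch(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(1, 1000))
        data[0, 480:500] = np.tile([1.0, -1.0], 10)  # zero-mean baseline window
        source = _rec(data, 100.0)
        eps = make_epochset(np.ones((1, 1, 100)), 100.0, source_offset=500)
        out = baseline_correct(eps, source, 200.0)
        np.testing.assert_allclose(out.epochs, 1.0)

    def test_ramp_closed_form(self):
        """On x[t] = t the corrected epoch mean is (L-1)/2 + (nb+1)/2."""
        sf, L, nb = 100.0, 100, 20
        ramp = np.arange(3000, dtype=float)
        source = _rec(ramp[None, :], sf)
        onsets = np.array([500, 1200, 2100])
        epochs = np.stack([ramp[None, o : o + L] for o in onsets])
        eps = make_epochset(epochs, sf, source_offset=0)
        eps.source_onsets = onsets
        out = baseline_correct(eps, source, baseline_ms=1000 * nb / sf)
        expected = (L - 1) / 2 + (nb + 1) / 2
        np.testing.assert_allclose(out.epochs.mean(axis=-1).ravel(), expected)

    def test_no_preceding_data_is_degenerate(self):
        source = _rec(np.zeros((1, 200)), 100.0)
        eps = make_epochset(np.zeros((1, 1, 100)), 100.0, source_offset=10)
        with pytest.raises(DegenerateDataError, match="epoch 0"):
            baseline_correct(eps, source, 200.0)


class TestPipelineOrder:
    def test_detection_before_rereferencing_matters(self, layout21):
        """A 205-uV burst shared by 8 of 15 scalp channels trips the amplitude
        rule before re-referencing but not after: swapping steps (3) and (4)
        changes the rejection count."""
        rng = np.random.default_rng(0)
        data = rng.normal(scale=5.0, size=(4, 21, 100))
        data[0, :8, 40:60] += 205.0
        eps = make_epochset(data, 100.0)
        canonical = detect_artifacts(eps, layout21)
        scrambled = detect_artifacts(average_reference(eps, layout21), layout21)
        assert (~canonical.retained).sum() != (~scrambled.retained).sum()
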