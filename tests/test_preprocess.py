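"""Epoch conditioning: filtering, baseline, cropping, rejection, scaling."""

import numpy as np
import pytest

from eegdecode.montage import default_montage
from eegdecode.preprocess import (
    balance_classes,
    bandpass_filter,
    baseline_correct,
    crop_model_window,
    drop_channels,
    normalize_subject,
    reject_artifacts,
    standard_pipeline,
)
from eegdecode.simulate import SimulationConfig, simulate_epochs
from eegdecode.schedule import make_trial_schedule

from conftest import make_epochs


def sine_epochs(montage, freq, fs=250.0, n_sec=40.0, amp=10.0):
    # long traces: the 0.3 Hz high-pass edge transient spans seconds, so
    # steady-state gain is only measurable away from the epoch boundaries
    t = np.arange(int(n_sec * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (1, montage.n_channels, 1)).astype(np.float32)
    return make_epochs(data, montage, sampling_rate=fs)


class TestBandpass:
    def test_dc_removed(self, tiny_montage):
        es = make_epochs(np.full((1, 6, 1000), 10.0, np.float32), tiny_montage)
        out = bandpass_filter(es, 0.3, 50.0)
        assert np.abs(out.data[:, :, 200:-200]).max() < 0.5

    def test_inband_preserved(self, tiny_montage):
        out = bandpass_filter(sine_epochs(tiny_montage, 10.0), 0.3, 50.0)
        mid = out.data[0, 0, 2500:-2500]
        assert abs(mid.max() - 10.0) / 10.0 < 0.05

    def test_stopband_attenuated(self, tiny_montage):
        # measured gain of the implemented zero-phase filter at 80 Hz
        out = bandpass_filter(sine_epochs(tiny_montage, 80.0), 0.3, 50.0)
        mid = out.data[0, 0, 2500:-2500]
        assert mid.max() < 0.1 * 10.0

    def test_high_cutoff_above_nyquist_rejected(self, tiny_montage):
        es = sine_epochs(tiny_montage, 10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(es, 0.3, 125.0)


class TestBaseline:
    def _epochs(self, tiny_montage, data):
        return make_epochs(data, tiny_montage, time_zero_index=100)

    def test_constant_trace_zeroed(self, tiny_montage):
        es = self._epochs(tiny_montage, np.full((2, 6, 400), 7.0, np.float32))
        out = baseline_correct(es, (-200.0, 0.0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)

    def test_zero_baseline_leaves_signal(self, tiny_montage):
        data = np.zeros((1, 6, 400), np.float32)
        data[:, :, 150:] = 3.0
        es = self._epochs(tiny_montage, data)
        out = baseline_correct(es, (-200.0, 0.0))
        np.testing.assert_allclose(out.data, data, atol=1e-6)

    def test_corrected_baseline_mean_is_zero(self, tiny_montage, rng):
        es = self._epochs(tiny_montage, rng.standard_normal((5, 6, 400)).astype(np.float32))
        out = baseline_correct(es, (-200.0, 0.0))
        i0, i1 = out.time_to_index(-200.0), out.time_to_index(0.0)
        np.testing.assert_allclose(out.data[:, :, i0:i1].mean(axis=-1), 0.0, atol=1e-5)

    def test_window_outside_epoch_rejected(self, tiny_montage):
        es = self._epochs(tiny_montage, np.zeros((1, 6, 400), np.float32))
        with pytest.raises(ValueError):
            baseline_correct(es, (-600.0, -500.0))


class TestCrop:
    @pytest.mark.parametrize("fs,window,tz,expected", [
        (250.0, (0.0, 1000.0), 250, 251),
        (250.0, (0.0, 0.0), 250, 1),
        (100.0, (0.0, 1000.0), 100, 101),
    ])
    def test_inclusive_endpoint_sample_counts(self, tiny_montage, fs, window, tz, expected):
        n = int(3 * fs)
        es = make_epochs(np.zeros((1, 6, n), np.float32), tiny_montage,
                         sampling_rate=fs, time_zero_index=tz)
        out = crop_model_window(es, window)
        assert out.n_samples == expected
        assert out.time_zero_index == 0

    def test_window_exceeding_data_rejected(self, tiny_montage):
        es = make_epochs(np.zeros((1, 6, 100), np.float32), tiny_montage,
                         time_zero_index=50)
        with pytest.raises(ValueError):
            crop_model_window(es, (0.0, 1000.0))


class TestReject:
    def test_below_threshold_kept(self, tiny_montage, rng):
        data = (rng.standard_normal((20, 6, 100)) * 10).clip(-99, 99).astype(np.float32)
        es = make_epochs(data, tiny_montage)
        out, bad = reject_artifacts(es, 100.0)
        assert out.n_trials == 20 and len(bad) == 0

    def test_single_excursion_drops_exactly_that_trial(self, tiny_montage):
        data = np.zeros((5, 6, 100), np.float32)
        data[3, 2, 50] = 101.0
        es = make_epochs(data, tiny_montage)
        out, bad = reject_artifacts(es, 100.0)
        assert list(bad) == [3]
        assert out.n_trials == 4
        assert list(out.metadata["trial_index"]) == [0, 1, 2, 4]

    def test_all_rejected_raises(self, tiny_montage):
        es = make_epochs(np.full((3, 6, 50), 200.0, np.float32), tiny_montage)
        with pytest.raises(ValueError, match="every trial"):
            reject_artifacts(es, 100.0)

    def test_simulated_artifacts_are_rejected(self):
        cfg = SimulationConfig(n_subjects=1, noise_sd=5.0, artifact_rate=0.1,
                               seed=6, epoch_window=(-0.2, 0.6))
        sched = make_trial_schedule(1, seed=6, trials_per_task=500)
        es = simulate_epochs(sched, cfg, "null")
        out, bad = reject_artifacts(es, 100.0)
        # injected 150 µV excursions always trip the 100 µV rule; background
        # pink noise (5 µV SD) never does
        assert abs(len(bad) - 100) < 5 * np.sqrt(1000 * 0.1 * 0.9)
        assert np.abs(out.data).max() <= 100.0


class TestDropChannels:
    def test_mastoid_removal_leaves_61(self):
        m = default_montage()
        es = make_epochs(np.zeros((2, m.n_channels, 10), np.float32), m)
        out = drop_channels(es, {"M1", "M2"})
        assert out.n_channels == 61
        assert "M1" not in out.montage.channel_labels

    def test_empty_and_repeated_drop(self, tiny_montage, rng):
        es = make_epochs(rng.standard_normal((2, 6, 10)).astype(np.float32), tiny_montage)
        same = drop_channels(es, set())
        assert np.array_equal(same.data, es.data)
        once = drop_channels(es, {"Fz"})
        twice = drop_channels(drop_channels(es, {"Fz"}), set())
        assert np.array_equal(once.data, twice.data)

    def test_unknown_label_rejected(self, tiny_montage):
        es = make_epochs(np.zeros((1, 6, 10), np.float32), tiny_montage)
        with pytest.raises(KeyError):
            drop_channels(es, {"XX"})


class TestNormalize:
    def test_fit_on_all_gives_unit_stats(self, tiny_montage, rng):
        data = (rng.standard_normal((40, 6, 50)) * 3 + 2).astype(np.float32)
        es = make_epochs(data, tiny_montage)
        out, _ = normalize_subject(es)
        np.testing.assert_allclose(out.data.mean(axis=(0, 2)), 0.0, atol=1e-4)
        np.testing.assert_allclose(out.data.std(axis=(0, 2)), 1.0, atol=1e-4)

    def test_train_stats_do_not_leak_to_shifted_test(self, tiny_montage, rng):
        train = make_epochs(rng.standard_normal((30, 6, 50)).astype(np.float32),
                            tiny_montage)
        shifted = make_epochs(
            (rng.standard_normal((30, 6, 50)) + 5).astype(np.float32), tiny_montage)
        _, stats = normalize_subject(train)
        out, _ = normalize_subject(shifted, stats=stats)
        assert abs(out.data.mean()) > 1.0  # shift visible: stats were not refit

    def test_subjects_standardized_independently(self, tiny_montage, rng):
        subj = np.repeat([0, 1], 20)
        data = rng.standard_normal((40, 6, 50)).astype(np.float32)
        data[20:] *= 50.0
        es = make_epochs(data, tiny_montage, subjects=subj)
        out, _ = normalize_subject(es)
        for s in (0, 1):
            np.testing.assert_allclose(out.data[subj == s].std(axis=(0, 2)), 1.0,
                                       atol=1e-4)

    def test_zero_variance_channel_warns(self, tiny_montage):
        data = np.zeros((5, 6, 50), np.float32)
        es = make_epochs(data, tiny_montage)
        with pytest.warns(UserWarning, match="zero-variance"):
            normalize_subject(es)


class TestBalance:
    def _labeled(self, tiny_montage, counts):
        labels = np.concatenate([[k] * v for k, v in counts.items()])
        data = np.zeros((len(labels), 6, 10), np.float32)
        return make_epochs(data, tiny_montage, condition=labels)

    def test_undersamples_to_minority(self, tiny_montage):
        es = self._labeled(tiny_montage, {"A": 100, "B": 80, "C": 120})
        out = balance_classes(es, "condition", seed=1)
        counts = out.metadata["condition"].value_counts()
        assert (counts == 80).all()

    def test_already_balanced_is_permutation(self, tiny_montage):
        es = self._labeled(tiny_montage, {"A": 50, "B": 50})
        out = balance_classes(es, "condition", seed=2)
        assert sorted(out.metadata["trial_index"]) == list(range(100))

    def test_seeded_determinism(self, tiny_montage):
        es = self._labeled(tiny_montage, {"A": 30, "B": 20})
        a = balance_classes(es, "condition", seed=3)
        b = balance_classes(es, "condition", seed=3)
        assert list(a.metadata["trial_index"]) == list(b.metadata["trial_index"])

    def test_single_class_rejected(self, tiny_montage):
        es = self._labeled(tiny_montage, {"A": 10})
        with pytest.raises(ValueError):
            balance_classes(es, "condition", seed=0)


class TestPipeline:
    def test_composition_keeps_alignment_and_shapes(self):
        cfg = SimulationConfig(n_subjects=2, noise_sd=5.0, artifact_rate=0.05,
                               seed=8, epoch_window=(-0.3, 1.1))
        sched = make_trial_schedule(2, seed=8, trials_per_task=28)
        es = simulate_epochs(sched, cfg, "null")
        out, report = standard_pipeline(es)
        assert out.n_channels == 61
        assert out.n_samples == 251
        assert out.n_trials == len(out.metadata)
        assert report["n_in"] - report["n_out"] == len(report["rejected_indices"])
        # determinism
        out2, _ = standard_pipeline(es)
        assert np.array_equal(out.data, out2.data)
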