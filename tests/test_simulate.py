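"""Synthetic-EEG generator: closed forms, spectra, locality, reproducibility."""

import dataclasses

import numpy as np
import pytest

from eegdecode.montage import default_montage
from eegdecode.schedule import TASK_SCENE, TASK_SPATIAL, make_trial_schedule
from eegdecode.simulate import (
    ComponentSpec,
    SimulationConfig,
    _pink_noise,
    preset_config,
    remap_condition_patterns,
    simulate_epochs,
)


def _noiseless(components, **over):
    return SimulationConfig(
        n_subjects=1, components=components, noise_sd=0.0, spatial_mixing=0.0,
        epoch_window=over.pop("epoch_window", (-0.2, 1.0)), **over)


def _frozen(comp: ComponentSpec) -> ComponentSpec:
    return dataclasses.replace(comp, subject_gain_sd=0.0, subject_latency_jitter_sd=0.0)


class TestClosedForm:
    def test_noiseless_single_component_is_gaussian_bump(self):
        comp = _frozen(ComponentSpec(("Oz", "O1"), 200.0, 30.0,
                                     {TASK_SCENE: 5.0, TASK_SPATIAL: 5.0}, "task"))
        cfg = _noiseless({"task": [comp]})
        sched = make_trial_schedule(1, seed=0, trials_per_task=14)
        es = simulate_epochs(sched, cfg, "task")
        t_ms = es.times * 1000.0
        expected = 5.0 * np.exp(-0.5 * ((t_ms - 200.0) / 30.0) ** 2)
        oz = es.montage.index("Oz")
        fz = es.montage.index("Fz")
        np.testing.assert_allclose(es.data[0, oz], expected, atol=1e-4)
        np.testing.assert_allclose(es.data[0, fz], 0.0, atol=1e-6)

    def test_null_scenario_class_means_converge(self):
        cfg = SimulationConfig(n_subjects=1, noise_sd=5.0, seed=4,
                               epoch_window=(-0.2, 0.6))
        sched = make_trial_schedule(1, seed=4, trials_per_task=350)
        es = simulate_epochs(sched, cfg, "null")
        tasks = es.labels("task")
        diff = es.data[tasks == TASK_SCENE].mean() - es.data[tasks == TASK_SPATIAL].mean()
        # grand-mean difference of pure noise shrinks with trial count
        assert abs(diff) < 0.5

    def test_task_preset_peak_in_early_window(self):
        # oracle: the noiseless between-task difference restricted to
        # occipitoparietal channels must peak inside 50-250 ms, where the
        # preset plants its class-dependent components
        cfg = preset_config("task", n_subjects=1, epoch_window=(-0.2, 1.0))
        comps = [_frozen(c) for c in cfg.components["task"]]
        cfg = dataclasses.replace(cfg, components={"task": comps},
                                  noise_sd=0.0, spatial_mixing=0.0)
        sched = make_trial_schedule(1, seed=0, trials_per_task=14)
        es = simulate_epochs(sched, cfg, "task")
        tasks = es.labels("task")
        occ = es.montage.group_indices("occipitoparietal")
        diff = np.abs(es.data[tasks == TASK_SPATIAL].mean(0)[occ]
                      - es.data[tasks == TASK_SCENE].mean(0)[occ])
        peak_ms = es.times[np.unravel_index(diff.argmax(), diff.shape)[1]] * 1000
        assert 50.0 <= peak_ms <= 250.0


class TestNoise:
    def test_spectral_slope_matches_exponent(self):
        for beta in (0.5, 1.0):
            x = _pink_noise(np.random.default_rng(0), (4,), 16384, beta)
            f = np.fft.rfftfreq(16384)
            p = np.abs(np.fft.rfft(x, axis=-1)) ** 2
            sel = slice(2, 4000)
            slope = np.polyfit(np.log(f[sel]), np.log(p[:, sel].mean(0)), 1)[0]
            assert abs(slope + beta) < 0.3

    def test_spatial_mixing_raises_channel_correlation(self):
        base = SimulationConfig(n_subjects=1, noise_sd=5.0, seed=9,
                                epoch_window=(-0.2, 0.6))
        sched = make_trial_schedule(1, seed=9, trials_per_task=21)
        flat = simulate_epochs(sched, dataclasses.replace(base, spatial_mixing=0.0), "null")
        mixed = simulate_epochs(sched, dataclasses.replace(base, spatial_mixing=0.6), "null")

        def mean_corr(es):
            x = es.data.reshape(-1, es.n_channels, es.n_samples)[0]
            c = np.corrcoef(x)
            return c[np.triu_indices_from(c, 1)].mean()

        assert mean_corr(mixed) > mean_corr(flat) + 0.2

    def test_artifact_rate_injection(self):
        cfg = SimulationConfig(n_subjects=1, noise_sd=5.0, artifact_rate=0.1,
                               seed=2, epoch_window=(-0.2, 0.6))
        sched = make_trial_schedule(1, seed=2, trials_per_task=500)
        es = simulate_epochs(sched, cfg, "null")
        n_hot = int((np.abs(es.data).max(axis=(1, 2)) > 100.0).sum())
        # Binomial(1000, 0.1): 5 sigma of 100
        assert abs(n_hot - 100) < 5 * np.sqrt(1000 * 0.1 * 0.9)


class TestReproducibilityAndLocality:
    def test_bit_identical_given_seed(self):
        cfg = preset_config("task", n_subjects=2, seed=7, epoch_window=(-0.3, 1.1))
        sched = make_trial_schedule(2, seed=7, trials_per_task=28)
        a = simulate_epochs(sched, cfg, "task")
        b = simulate_epochs(sched, cfg, "task")
        assert np.array_equal(a.data, b.data)
        assert a.metadata.equals(b.metadata)

    def test_effect_locality_noiseless(self):
        comp = _frozen(ComponentSpec(("POz",), 150.0, 25.0,
                                     {TASK_SPATIAL: 4.0}, "task",
                                     weights=(1.0,)))
        cfg = _noiseless({"task": [comp]})
        sched = make_trial_schedule(1, seed=0, trials_per_task=14)
        es = simulate_epochs(sched, cfg, "task")
        tasks = es.labels("task")
        diff = np.abs(es.data[tasks == TASK_SPATIAL].mean(0)
                      - es.data[tasks == TASK_SCENE].mean(0))
        best_channel = diff.max(axis=1).argmax()
        assert es.montage.channel_labels[best_channel] == "POz"

    def test_latency_outside_epoch_rejected(self):
        comp = ComponentSpec(("Oz",), 1500.0, 20.0, {TASK_SCENE: 1.0}, "task")
        cfg = _noiseless({"task": [comp]}, epoch_window=(-0.2, 1.0))
        sched = make_trial_schedule(1, seed=0, trials_per_task=14)
        with pytest.raises(ValueError, match="latency"):
            simulate_epochs(sched, cfg, "task")


class TestRemapping:
    def _cfg(self):
        return preset_config("affordance", n_subjects=1, epoch_window=(-0.2, 0.6))

    def test_identity_permutation_returns_config_unchanged(self):
        cfg = self._cfg()
        out = remap_condition_patterns(cfg, "affordance", permutation=np.arange(7))
        assert out is cfg

    def test_two_class_swap_exchanges_means(self):
        comps = [
            _frozen(ComponentSpec(("Oz",), 150.0, 25.0, {"a": 3.0}, "letter")),
            _frozen(ComponentSpec(("Fz",), 150.0, 25.0, {"b": 3.0}, "letter")),
        ]
        cfg = _noiseless({"letters": comps})
        swapped = remap_condition_patterns(cfg, "letters", permutation=[1, 0])
        sched = make_trial_schedule(1, seed=0, trials_per_task=14)
        sched = sched.assign(letter=np.where(np.arange(len(sched)) % 2 == 0, "a", "b"))
        es = simulate_epochs(sched, swapped, "letters")
        spatial = es.metadata["task"] == TASK_SPATIAL
        is_a = es.metadata["letter"] == "a"
        oz, fz = es.montage.index("Oz"), es.montage.index("Fz")
        # remapped task: class a now expresses class b's Fz pattern
        a_spatial = es.data[(spatial & is_a).to_numpy()]
        assert a_spatial[:, fz].max() > 2.5
        assert np.abs(a_spatial[:, oz]).max() < 1e-5
        # scene task unchanged: class a keeps its Oz pattern
        a_scene = es.data[(~spatial & is_a).to_numpy()]
        assert a_scene[:, oz].max() > 2.5

    def test_marginal_amplitudes_preserved(self):
        cfg = self._cfg()
        out = remap_condition_patterns(cfg, "affordance", seed=5)
        def marginal(c):
            return sorted(a for comp in c.components["affordance"]
                          for a in comp.amplitude_by_class.values()
                          if comp.task_filter != TASK_SCENE)
        spatial_amps = marginal(out)
        orig = sorted(a for comp in cfg.components["affordance"]
                      for a in comp.amplitude_by_class.values())
        assert spatial_amps == orig

    def test_single_class_rejected(self):
        comp = ComponentSpec(("Oz",), 150.0, 25.0, {"only": 1.0}, "letter")
        cfg = _noiseless({"letters": [comp]})
        with pytest.raises(ValueError, match="two classes"):
            remap_condition_patterns(cfg, "letters")
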