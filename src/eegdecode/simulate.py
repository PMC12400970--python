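"""Synthetic evoked-potential generator.

Each epoch is 1/f^beta background noise (optionally spatially correlated)
plus a sum of class-conditional evoked components — Gaussian bumps in time
with a fixed channel topography — plus optional high-amplitude artifact
excursions. Components carry per-class amplitudes keyed to a metadata field
(task, goal direction, door configuration, or wall color), per-subject
lognormal gain and Gaussian latency jitter, so that planted spatiotemporal
effects are recoverable by a decoder and attributable by Grad-CAM.

Scenario presets plant effects in the channel groups and latency windows
where evoked scene responses are observed empirically: occipitoparietal
channels from ~50-250 ms, frontal channels near 180-200 ms, and late
central (motor) activity after 600 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .montage import Montage, default_montage
from .schedule import TASK_SCENE, TASK_SPATIAL, door_configurations, make_trial_schedule
from .utils import substream

SCENARIOS = ("task", "goal", "affordance", "color", "null")


@dataclass(frozen=True)
class ComponentSpec:
    """One planted evoked component.

    Parameters
    ----------
    channels
        Montage labels carrying the component.
    latency_center, latency_width
        Gaussian time course, in milliseconds post-stimulus (width = SD).
    amplitude_by_class
        Peak amplitude in microvolts for each class label of
        ``label_field``; absent labels contribute nothing.
    label_field
        Metadata column whose value selects the amplitude.
    weights
        Optional per-channel weights (default 1 on every listed channel);
        normalized so max |w| = 1.
    task_filter
        Restrict the component to one task, or ``None`` for both.
    subject_gain_sd
        Lognormal SD of the per-subject multiplicative gain.
    subject_latency_jitter_sd
        SD (ms) of the per-subject latency shift.
    """

    channels: tuple[str, ...]
    latency_center: float
    latency_width: float
    amplitude_by_class: dict
    label_field: str
    weights: tuple[float, ...] | None = None
    task_filter: str | None = None
    subject_gain_sd: float = 0.2
    subject_latency_jitter_sd: float = 10.0

    def topography(self, montage: Montage) -> np.ndarray:
        w = np.zeros(montage.n_channels)
        vals = self.weights if self.weights is not None else [1.0] * len(self.channels)
        if len(vals) != len(self.channels):
            raise ValueError("weights length must match channels")
        for lb, v in zip(self.channels, vals):
            w[montage.index(lb)] = v
        peak = np.abs(w).max()
        if peak > 0:
            w = w / peak
        return w


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model, cohort size and planted components for one simulation."""

    n_subjects: int = 5
    montage: Montage = field(default_factory=default_montage)
    components: dict = field(default_factory=dict)  # scenario -> list[ComponentSpec]
    noise_sd: float = 6.0
    noise_exponent: float = 1.0
    spatial_mixing: float = 0.3
    behavioral_accuracy: float = 0.93
    artifact_rate: float = 0.0
    sampling_rate: float = 250.0
    epoch_window: tuple[float, float] = (-1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("behavioral_accuracy", self.behavioral_accuracy),
                          ("artifact_rate", self.artifact_rate)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.spatial_mixing < 1.0:
            raise ValueError("spatial_mixing must be in [0, 1)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch window must be increasing")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.sampling_rate)) + 1

    @property
    def time_zero_index(self) -> int:
        return int(round(-self.epoch_window[0] * self.sampling_rate))


OCC = ("P8", "POz", "O1", "O2", "P6", "PO4", "PO6", "PO7", "PO8", "Oz")
FRONT = ("Fpz", "AF3", "AF4", "F1", "Fz", "F2")
CENT = ("C3", "C1", "Cz", "C2", "C4")


def _preset_components(scenario: str, effect_gain: float, n_colors: int) -> list[ComponentSpec]:
    g = effect_gain
    if scenario == "null":
        return []
    if scenario == "task":
        return [
            # early occipitoparietal window differing between tasks
            ComponentSpec(OCC, 120.0, 30.0,
                          {TASK_SCENE: 2.0 * g, TASK_SPATIAL: 5.0 * g}, "task"),
            # P2-range occipitoparietal difference
            ComponentSpec(OCC, 220.0, 25.0,
                          {TASK_SCENE: 1.0 * g, TASK_SPATIAL: 3.5 * g}, "task"),
            # late motor preparation, spatial task only
            ComponentSpec(CENT, 700.0, 80.0,
                          {TASK_SPATIAL: 2.5 * g}, "task"),
        ]
    if scenario == "goal":
        # distinct topography/latency per retrieved goal direction;
        # frontal ~190 ms and occipitoparietal ~210 ms carry the signal
        return [
            ComponentSpec(FRONT, 190.0, 20.0, {"left": 6.0 * g}, "goal_direction"),
            ComponentSpec(OCC[:5], 210.0, 20.0, {"center": 6.0 * g}, "goal_direction"),
            ComponentSpec(OCC[5:], 210.0, 20.0, {"right": 6.0 * g}, "goal_direction"),
        ]
    if scenario == "affordance":
        # each door configuration activates a distinct three-channel
        # occipitoparietal patch, latencies staggered through the P2 window
        comps = []
        for i, cfg in enumerate(door_configurations()):
            label = "+".join(cfg)
            chans = tuple(OCC[(i + j) % len(OCC)] for j in range(3))
            comps.append(ComponentSpec(
                chans, 170.0 + 12.0 * i, 20.0, {label: 8.0 * g},
                "door_configuration"))
        return comps
    if scenario == "color":
        # task-invariant early chromatic response, one patch per color
        comps = []
        for c in range(n_colors):
            chans = tuple(OCC[(c + j) % len(OCC)] for j in range(3))
            comps.append(ComponentSpec(
                chans, 80.0 + 20.0 * c, 18.0, {c: 8.0 * g}, "wall_color"))
        return comps
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def preset_config(
    scenario: str,
    n_subjects: int = 5,
    seed: int = 0,
    effect_gain: float = 1.0,
    n_colors: int = 7,
    **overrides,
) -> SimulationConfig:
    """A SimulationConfig with the named scenario's planted components."""
    comps = {scenario: _preset_components(scenario, effect_gain, n_colors)}
    return SimulationConfig(
        n_subjects=n_subjects, components=comps, seed=seed, **overrides)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                exponent: float) -> np.ndarray:
    """Gaussian 1/f^beta noise along the last axis, unit variance."""
    n_f = n_samples // 2 + 1
    freqs = np.arange(n_f, dtype=np.float64)
    scale = np.ones(n_f)
    if exponent != 0:
        scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    spec = (rng.standard_normal(shape + (n_f,)) + 1j * rng.standard_normal(shape + (n_f,)))
    spec *= scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x / sd).astype(np.float32)


def simulate_epochs(schedule: pd.DataFrame, config: SimulationConfig,
                    scenario: str) -> EpochSet:
    """Render synthetic epochs for every schedule row of the configured cohort.

    Fully reproducible from ``config.seed``: noise, subject gains/jitters and
    artifact placement each draw from named sub-streams.
    """
    if scenario not in SCENARIOS and scenario not in config.components:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of "
                         f"{SCENARIOS} or a key of config.components")
    comps = list(config.components.get(scenario, ()))
    montage = config.montage
    n_samples = config.n_samples
    fs = config.sampling_rate
    t_ms = (np.arange(n_samples) - config.time_zero_index) / fs * 1000.0

    for k, comp in enumerate(comps):
        if not (config.epoch_window[0] * 1000 <= comp.latency_center
                <= config.epoch_window[1] * 1000):
            raise ValueError(
                f"component {k} latency {comp.latency_center} ms outside epoch window")

    sched = schedule.reset_index(drop=True)
    n_trials = len(sched)
    n_chan = montage.n_channels
    data = np.zeros((n_trials, n_chan, n_samples), dtype=np.float32)

    subjects = np.sort(sched["participant_id"].unique())
    # per-subject, per-component gain and latency jitter
    gains = {}
    jitters = {}
    for s in subjects:
        rng_g = substream(config.seed, "gains", int(s))
        gains[s] = np.array([
            rng_g.lognormal(mean=0.0, sigma=c.subject_gain_sd) for c in comps])
        jitters[s] = np.array([
            rng_g.normal(0.0, c.subject_latency_jitter_sd) for c in comps])

    topos = [c.topography(montage) for c in comps]

    for s in subjects:
        rows = np.flatnonzero(sched["participant_id"].to_numpy() == s)
        meta = sched.iloc[rows]
        rng_n = substream(config.seed, "noise", int(s))

        # background: per-channel pink noise, mixed with a shared trace
        noise = _pink_noise(rng_n, (len(rows), n_chan), n_samples, config.noise_exponent)
        if config.spatial_mixing > 0:
            shared = _pink_noise(rng_n, (len(rows), 1), n_samples, config.noise_exponent)
            rho = config.spatial_mixing
            noise = np.sqrt(1 - rho) * noise + np.sqrt(rho) * shared
        data[rows] = config.noise_sd * noise

        for k, comp in enumerate(comps):
            amp = meta[comp.label_field].map(comp.amplitude_by_class).fillna(0.0).to_numpy()
            if comp.task_filter is not None:
                amp = amp * (meta["task"].to_numpy() == comp.task_filter)
            if not np.any(amp):
                continue
            center = comp.latency_center + jitters[s][k]
            bump = np.exp(-0.5 * ((t_ms - center) / comp.latency_width) ** 2)
            waves = (gains[s][k] * amp)[:, None, None] * topos[k][None, :, None] \
                * bump[None, None, :]
            data[rows] += waves.astype(np.float32)

        if config.artifact_rate > 0:
            rng_a = substream(config.seed, "artifacts", int(s))
            hit = rng_a.random(len(rows)) < config.artifact_rate
            width = max(1, int(round(0.1 * fs)))  # 100 ms excursion
            for local_i in np.flatnonzero(hit):
                chans = rng_a.choice(n_chan, size=2, replace=False)
                start = int(rng_a.integers(0, n_samples - width))
                data[rows[local_i], chans[:, None], start:start + width] += 150.0

    return EpochSet(data, fs, config.time_zero_index, sched, montage,
                    attrs={"scenario": scenario, "seed": config.seed})


def remap_condition_patterns(config: SimulationConfig, scenario: str,
                             seed: int = 0,
                             permutation=None) -> SimulationConfig:
    """Re-assign class->component mapping for spatial-memory trials only.

    Models a task-dependent change of the discriminative neural pattern: the
    same classes exist in both tasks, but in the spatial-memory task each
    class is expressed through another class's topography/latency (a seeded
    derangement by default), with the marginal amplitude distribution
    preserved. A decoder trained on scene-memory trials then faces scrambled
    patterns on spatial-memory trials. An explicit ``permutation`` (class
    indices over the sorted class labels) overrides the seeded draw; the
    identity permutation returns the config unchanged.
    """
    comps = list(config.components.get(scenario, ()))
    classful = [c for c in comps if c.amplitude_by_class]
    if not classful:
        raise ValueError(f"scenario {scenario!r} has no class-dependent components")
    labels = sorted({lb for c in classful for lb in c.amplitude_by_class},
                    key=str)
    if len(labels) < 2:
        raise ValueError("remapping requires at least two classes")

    if permutation is not None:
        perm = np.asarray(permutation)
        if sorted(perm.tolist()) != list(range(len(labels))):
            raise ValueError("permutation must permute the class indices")
        if np.array_equal(perm, np.arange(len(labels))):
            return config
    else:
        rng = substream(seed, "remap")
        perm = np.arange(len(labels))
        while np.any(perm == np.arange(len(labels))):  # derangement
            perm = rng.permutation(len(labels))
    mapping = {labels[i]: labels[perm[i]] for i in range(len(labels))}

    out: list[ComponentSpec] = []
    for comp in comps:
        if not comp.amplitude_by_class:
            out.append(comp)
            continue
        if comp.task_filter is not None:
            raise ValueError("remapping expects task-invariant components")
        out.append(replace(comp, task_filter=TASK_SCENE))
        remapped = {mapping[lb]: a for lb, a in comp.amplitude_by_class.items()}
        out.append(replace(comp, task_filter=TASK_SPATIAL,
                           amplitude_by_class=remapped))
    new_components = dict(config.components)
    new_components[scenario] = out
    return replace(config, components=new_components)


def planted_window_cohort(n_subjects: int = 5, seed: int = 0,
                          trials_per_task: int = 280,
                          epoch_window: tuple[float, float] = (-0.3, 1.1)
                          ) -> EpochSet:
    """A two-task cohort whose *only* class-dependent signal lives on the
    occipitoparietal cluster between 50 and 250 ms.

    The canonical parameter-recovery condition: a decoder must find the
    effect, and its attribution map must concentrate in the planted
    channel x time window (no competing late components are planted).
    """
    comps = [
        ComponentSpec(OCC, 120.0, 30.0,
                      {TASK_SCENE: 2.0, TASK_SPATIAL: 6.0}, "task"),
        ComponentSpec(OCC, 220.0, 25.0,
                      {TASK_SCENE: 1.0, TASK_SPATIAL: 4.0}, "task"),
    ]
    cfg = SimulationConfig(n_subjects=n_subjects, components={"task": comps},
                           seed=seed, epoch_window=epoch_window)
    sched = make_trial_schedule(n_subjects, seed=seed,
                                trials_per_task=trials_per_task)
    return simulate_epochs(sched, cfg, "task")


def simulate_cohort(scenario: str, n_subjects: int = 5, seed: int = 0,
                    trials_per_task: int = 770, n_colors: int = 7,
                    behavioral_accuracy: float = 0.93,
                    remap: bool = False, **config_overrides) -> EpochSet:
    """Convenience wrapper: schedule + preset config + epochs in one call."""
    cfg = preset_config(scenario, n_subjects=n_subjects, seed=seed,
                        n_colors=n_colors,
                        behavioral_accuracy=behavioral_accuracy,
                        **config_overrides)
    if remap:
        cfg = remap_condition_patterns(cfg, scenario, seed=seed)
    sched = make_trial_schedule(
        n_subjects, n_colors=n_colors,
        behavioral_accuracy=behavioral_accuracy, seed=seed,
        trials_per_task=trials_per_task)
    return simulate_epochs(sched, cfg, scenario)
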