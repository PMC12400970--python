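"""The EpochSet container: trials x channels x samples plus trial metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Montage


@dataclass
class EpochSet:
    """Epoched multi-channel EEG with per-trial metadata.

    Attributes
    ----------
    data
        Amplitudes in microvolts, shaped ``(n_trials, n_channels, n_samples)``.
    sampling_rate
        Samples per second.
    time_zero_index
        Sample index of stimulus onset within each epoch.
    metadata
        One row per trial (participant, block, task, stimulus, goal, ...).
    montage
        Channel labels and region groups; must match ``data``'s channel axis.
    """

    data: np.ndarray
    sampling_rate: float
    time_zero_index: int
    metadata: pd.DataFrame
    montage: Montage
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError(
                f"metadata rows ({len(self.metadata)}) != trials ({self.data.shape[0]})"
            )
        if self.montage.n_channels != self.data.shape[1]:
            raise ValueError(
                f"montage has {self.montage.n_channels} channels, data has {self.data.shape[1]}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.time_zero_index < self.data.shape[2]:
            raise ValueError("time_zero_index outside epoch")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, zero at stimulus onset."""
        return (np.arange(self.n_samples) - self.time_zero_index) / self.sampling_rate

    def time_to_index(self, t_ms: float) -> int:
        """Nearest sample index for a latency in milliseconds post-onset."""
        return int(round(self.time_zero_index + t_ms / 1000.0 * self.sampling_rate))

    def select(self, mask_or_indices) -> "EpochSet":
        """Subset of trials; metadata kept in lockstep."""
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EpochSet(
            self.data[idx],
            self.sampling_rate,
            self.time_zero_index,
            self.metadata.iloc[idx],
            self.montage,
            dict(self.attrs),
        )

    def query(self, expr: str) -> "EpochSet":
        """Subset of trials by a pandas query on the metadata."""
        kept = self.metadata.query(expr).index.to_numpy()
        return self.select(kept)

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.sampling_rate,
            self.time_zero_index,
            self.metadata.copy(),
            self.montage,
            dict(self.attrs),
        )

    def labels(self, field_name: str) -> np.ndarray:
        if field_name not in self.metadata.columns:
            raise KeyError(f"no metadata field {field_name!r}")
        return self.metadata[field_name].to_numpy()
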