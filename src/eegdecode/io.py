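"""On-disk formats: epoch containers, model checkpoints, EDF import, reports.

Epochs are stored as a single HDF5 file (the amplitude array) with a JSON
sidecar carrying the schedule rows, montage, sampling rate, seeds and a
schema version tag, so the metadata stays human-inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epochs import EpochSet
from .montage import Montage
from .nn.network import ClassifierModel, CompactCNN, ModelConfig, TrainConfig

SCHEMA_VERSION = "1"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_epochset(es: EpochSet, path) -> tuple[Path, Path]:
    """Write the array container + JSON metadata sidecar; lossless round trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=es.data, compression="gzip", compression_opts=1)
        f.attrs["schema_version"] = SCHEMA_VERSION
    meta = {
        "schema_version": SCHEMA_VERSION,
        "sampling_rate": es.sampling_rate,
        "time_zero_index": int(es.time_zero_index),
        "montage": es.montage.to_dict(),
        "metadata": es.metadata.to_dict(orient="list"),
        "attrs": es.attrs,
    }
    side = _sidecar(path)
    side.write_text(json.dumps(meta))
    return path, side


def read_epochset(path) -> EpochSet:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"epoch container schema {version!r} != supported {SCHEMA_VERSION!r}")
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"array container schema {f.attrs.get('schema_version')!r} "
                f"!= supported {SCHEMA_VERSION!r}")
        data = f["data"][()]
    metadata = pd.DataFrame(meta["metadata"])
    return EpochSet(data, meta["sampling_rate"], meta["time_zero_index"],
                    metadata, Montage.from_dict(meta["montage"]), meta.get("attrs", {}))


def save_checkpoint(model: ClassifierModel, path) -> Path:
    """Weights (HDF5) plus config/label-map/history in the JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.network.state_dict()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for i, arr in enumerate(state):
            f.create_dataset(f"param_{i:04d}", data=arr)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "model_config": model.config.__dict__,
        "train_config": model.train_config.__dict__ if model.train_config else None,
        "label_map": {str(k): v for k, v in model.label_map.items()},
        "label_types": {str(k): type(k).__name__ for k in model.label_map},
        "history": model.history,
    }
    _sidecar(path).write_text(json.dumps(meta, default=float))
    return path


def load_checkpoint(path) -> ClassifierModel:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"checkpoint schema {meta.get('schema_version')!r} unsupported")
    mc = meta["model_config"]
    mc["pool_sizes"] = tuple(mc["pool_sizes"])
    config = ModelConfig(**mc)
    net = CompactCNN(config)
    with h5py.File(path, "r") as f:
        state = [f[k][()] for k in sorted(f.keys())]
    net.load_state_dict(state)
    label_map = {}
    for key, idx in meta["label_map"].items():
        typ = meta.get("label_types", {}).get(key, "str")
        label_map[int(key) if typ in ("int", "int64") else key] = idx
    tc = TrainConfig(**meta["train_config"]) if meta.get("train_config") else None
    return ClassifierModel(config=config, network=net, label_map=label_map,
                           history=meta.get("history", []), train_config=tc)


# ---- EDF import ------------------------------------------------------------

def epochs_from_raw(raw, event_samples, metadata: pd.DataFrame,
                    tmin: float = -1.0, tmax: float = 2.0,
                    target_rate: float = 250.0) -> EpochSet:
    """Cut epochs around event sample indices from an mne Raw object.

    Resamples (with a warning) when the recording rate differs from
    ``target_rate``. Overlapping epochs are allowed; they are flagged in
    ``attrs``. Used by :func:`import_edf` and directly testable on
    synthetic ``mne.io.RawArray`` data.
    """
    import warnings

    fs = raw.info["sfreq"]
    if fs != target_rate:
        warnings.warn(f"resampling from {fs} Hz to {target_rate} Hz")
        raw = raw.copy().resample(target_rate)
        event_samples = [int(round(e * target_rate / fs)) for e in event_samples]
        fs = target_rate
    data = raw.get_data(units="uV") if hasattr(raw, "get_data") else raw[:][0]
    n_before = int(round(-tmin * fs))
    n_after = int(round(tmax * fs))
    n_len = n_before + n_after + 1
    segments = []
    kept_rows = []
    for i, ev in enumerate(event_samples):
        start = ev - n_before
        stop = ev + n_after + 1
        if start < 0 or stop > data.shape[1]:
            warnings.warn(f"event {i} too close to the recording edge; skipped")
            continue
        segments.append(data[:, start:stop])
        kept_rows.append(i)
    if not segments:
        raise ValueError("no events yielded complete epochs")
    overlap = any(event_samples[kept_rows[j + 1]] - event_samples[kept_rows[j]] < n_len
                  for j in range(len(kept_rows) - 1))
    montage = Montage(tuple(raw.ch_names), region_groups={})
    return EpochSet(np.stack(segments), fs, n_before,
                    metadata.iloc[kept_rows], montage,
                    attrs={"overlapping_epochs": bool(overlap)})


def import_edf(path, metadata_path, tmin: float = -1.0, tmax: float = 2.0,
               target_rate: float = 250.0, stim_channel: str | None = None
               ) -> EpochSet:
    """Adapter for real recordings in European Data Format.

    ``metadata_path`` points at a CSV sidecar with one row per event and an
    ``onset_sample`` column (plus any schedule columns). Requires mne.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, stim_channel=stim_channel,
                              verbose="error")
    meta = pd.read_csv(metadata_path)
    if "onset_sample" not in meta.columns:
        raise ValueError("metadata CSV must contain an 'onset_sample' column")
    events = meta["onset_sample"].astype(int).tolist()
    if not events:
        raise ValueError("no events in metadata")
    return epochs_from_raw(raw, events, meta.drop(columns=["onset_sample"]),
                           tmin, tmax, target_rate)


def write_report_json(summary: dict, path) -> Path:
    """Serialize a full-report summary (live report objects stripped)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clean = {k: v for k, v in summary.items() if not k.startswith("_")}
    path.write_text(json.dumps(clean, indent=2, default=float))
    return path


def save_heatmap(amap, montage: Montage, sampling_rate: float, path,
                 title: str = "Grad-CAM importance") -> Path:
    """Render a channels x time heatmap (channels ordered frontal to occipital)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 10))
    t_ms = np.arange(amap.importance.shape[1]) / sampling_rate * 1000.0
    im = ax.imshow(amap.importance, aspect="auto", cmap="jet",
                   extent=[t_ms[0], t_ms[-1], amap.importance.shape[0], 0],
                   vmin=0, vmax=1)
    ax.set_xlabel("time after stimulus (ms)")
    ax.set_ylabel("channel")
    ticks = np.arange(0, amap.importance.shape[0], max(1, amap.importance.shape[0] // 20))
    ax.set_yticks(ticks + 0.5)
    ax.set_yticklabels([montage.channel_labels[i] for i in ticks], fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="relative importance (0-1)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
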