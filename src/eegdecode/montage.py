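"""Electrode montage: channel labels, region groups, reference handling.

The default layout models a 64-electrode 10-10 cap with the reference at
CPz (not carried as a data channel) and mastoid electrodes M1/M2 flagged
as removable, leaving 61 scalp data channels for modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: 63 data channels of the default 64-electrode cap (CPz serves as reference
#: and is therefore not a data channel). M1/M2 are the mastoids.
DEFAULT_64_LABELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "M1", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "M2",
    "TP7", "CP5", "CP3", "CP1", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

MASTOIDS: frozenset[str] = frozenset({"M1", "M2"})
REFERENCE_LABEL = "CPz"

OCCIPITOPARIETAL = ("P8", "POz", "O1", "O2", "P6", "PO4", "PO6", "PO7", "PO8", "Oz")
FRONTAL = ("Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
           "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8")
CENTRAL = ("C5", "C3", "C1", "Cz", "C2", "C4", "C6")


@dataclass(frozen=True)
class Montage:
    """An ordered set of data-channel labels with named regional subsets.

    Parameters
    ----------
    channel_labels
        Ordered, unique 10-10 labels of the data channels (reference
        excluded).
    region_groups
        Named channel subsets, e.g. ``"occipitoparietal"``; every member
        must be a data channel.
    reference
        Label of the (excluded) reference electrode, kept for provenance.
    removable
        Labels conventionally dropped before modelling (mastoids).
    """

    channel_labels: tuple[str, ...] = DEFAULT_64_LABELS
    region_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "occipitoparietal": OCCIPITOPARIETAL,
            "frontal": FRONTAL,
            "central": CENTRAL,
        }
    )
    reference: str = REFERENCE_LABEL
    removable: frozenset[str] = MASTOIDS

    def __post_init__(self) -> None:
        labels = self.channel_labels
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if self.reference in labels:
            raise ValueError("reference electrode must not appear as a data channel")
        for name, group in self.region_groups.items():
            missing = set(group) - set(labels)
            if missing:
                raise ValueError(f"region group {name!r} has unknown channels {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def indices(self, labels) -> list[int]:
        return [self.index(lb) for lb in labels]

    def group_indices(self, name: str) -> list[int]:
        return self.indices(self.region_groups[name])

    def without(self, labels) -> "Montage":
        """Return a montage with `labels` removed (set semantics)."""
        drop = set(labels)
        unknown = drop - set(self.channel_labels)
        if unknown:
            raise KeyError(f"unknown channels {sorted(unknown)}")
        kept = tuple(lb for lb in self.channel_labels if lb not in drop)
        groups = {
            name: tuple(lb for lb in group if lb not in drop)
            for name, group in self.region_groups.items()
        }
        return Montage(kept, groups, self.reference, self.removable - drop)

    def to_dict(self) -> dict:
        return {
            "channel_labels": list(self.channel_labels),
            "region_groups": {k: list(v) for k, v in self.region_groups.items()},
            "reference": self.reference,
            "removable": sorted(self.removable),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            tuple(d["channel_labels"]),
            {k: tuple(v) for k, v in d["region_groups"].items()},
            d.get("reference", REFERENCE_LABEL),
            frozenset(d.get("removable", sorted(MASTOIDS))),
        )


def default_montage() -> Montage:
    """The 64-electrode cap: 63 data channels; dropping M1/M2 leaves 61."""
    return Montage()
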