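"""Trial schedules reproducing the two-task scene/spatial-memory design.

The experiment shows images of a room whose three walls may each contain an
open door (a navigational affordance). The 7 door configurations are the
non-empty subsets of {left, center, right}. Crossing them with wall colors
yields the stimulus catalog (7 x 7 = 49 at the default). Each participant
completes 6 blocks; within every block a one-back *scene memory* task
precedes a *spatial memory* task in which the learned, color-cued goal
direction must be retrieved. At full scale each participant sees 770 images
per task (110 per door configuration), 1,540 in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .utils import substream

DOOR_POSITIONS = ("left", "center", "right")
TASK_SCENE = "scene_memory"
TASK_SPATIAL = "spatial_memory"
TASKS = (TASK_SCENE, TASK_SPATIAL)
GOAL_DIRECTIONS = ("left", "center", "right")
N_CONFIGURATIONS = 7
N_BLOCKS = 6

SCHEDULE_COLUMNS = (
    "participant_id", "block", "task", "door_configuration", "n_doors",
    "wall_color", "goal_direction", "response_correct", "trial_index",
)


@dataclass(frozen=True)
class StimulusSpec:
    """A unique room image: which doors are open, and the wall color index."""

    door_configuration: tuple[str, ...]
    wall_color: int

    def __post_init__(self) -> None:
        if not self.door_configuration:
            raise ValueError("door configuration must be a non-empty subset")
        if any(p not in DOOR_POSITIONS for p in self.door_configuration):
            raise ValueError(f"unknown door position in {self.door_configuration}")

    @property
    def n_doors(self) -> int:
        return len(self.door_configuration)

    @property
    def label(self) -> str:
        return "+".join(self.door_configuration)


def door_configurations() -> list[tuple[str, ...]]:
    """The 7 non-empty subsets of wall positions, ordered by subset bitmask."""
    configs = []
    for mask in range(1, 8):
        configs.append(tuple(p for i, p in enumerate(DOOR_POSITIONS) if mask >> i & 1))
    return configs


def make_stimulus_catalog(n_colors: int) -> list[StimulusSpec]:
    """All door configurations crossed with ``n_colors`` wall colors.

    Ordered by configuration bitmask, then color index; with the study's
    seven colors this yields the 49-image catalog.
    """
    if n_colors < 1:
        raise ValueError("n_colors must be >= 1")
    return [
        StimulusSpec(cfg, color)
        for cfg in door_configurations()
        for color in range(int(n_colors))
    ]


def _split_counts(total: int, parts: int) -> np.ndarray:
    """Split `total` into `parts` near-equal integers (remainder spread, never dropped)."""
    base, rem = divmod(int(total), int(parts))
    out = np.full(parts, base, dtype=int)
    out[:rem] += 1
    return out


def make_trial_schedule(
    n_subjects: int,
    n_colors: int = 7,
    behavioral_accuracy: float = 0.93,
    seed: int = 0,
    trials_per_task: int = 770,
) -> pd.DataFrame:
    """Generate the full pseudorandomized trial sequence for a cohort.

    Per subject and task, ``trials_per_task`` trials are divided equally
    over the 7 door configurations (remainders spread deterministically,
    never dropped) and over 6 blocks; within every block scene-memory
    trials come before spatial-memory trials. Each subject receives a
    private color-to-goal-direction map, drawn once; spatial-memory
    responses are correct with probability ``behavioral_accuracy``
    (scene-memory responses are recorded correct).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 <= behavioral_accuracy <= 1.0:
        raise ValueError("behavioral_accuracy must be a probability")
    if n_colors < 1:
        raise ValueError("n_colors must be >= 1")
    if trials_per_task < N_CONFIGURATIONS:
        raise ValueError("trials_per_task must cover all 7 door configurations")

    configs = door_configurations()
    rows: list[dict] = []
    for s in range(int(n_subjects)):
        rng = substream(seed, "schedule", s)
        # color -> goal direction: fixed per subject, covers all directions
        # as evenly as n_colors allows
        directions = np.tile(GOAL_DIRECTIONS, int(np.ceil(n_colors / 3)))[:n_colors]
        rng.shuffle(directions)
        color_to_goal = {c: directions[c] for c in range(n_colors)}

        for task in TASKS:
            per_config = _split_counts(trials_per_task, N_CONFIGURATIONS)
            stimuli: list[StimulusSpec] = []
            for ci, cfg in enumerate(configs):
                colors = np.tile(np.arange(n_colors), int(np.ceil(per_config[ci] / n_colors)))
                for rep in range(per_config[ci]):
                    stimuli.append(StimulusSpec(cfg, int(colors[rep])))
            order = rng.permutation(len(stimuli))
            per_block = _split_counts(len(stimuli), N_BLOCKS)
            cursor = 0
            for b in range(N_BLOCKS):
                for j in order[cursor:cursor + per_block[b]]:
                    st = stimuli[j]
                    correct = True
                    goal = "none"
                    if task == TASK_SPATIAL:
                        goal = color_to_goal[st.wall_color]
                        correct = bool(rng.random() < behavioral_accuracy)
                    rows.append({
                        "participant_id": s,
                        "block": b + 1,
                        "task": task,
                        "door_configuration": st.label,
                        "n_doors": st.n_doors,
                        "wall_color": st.wall_color,
                        "goal_direction": goal,
                        "response_correct": correct,
                    })
                cursor += per_block[b]

    df = pd.DataFrame(rows)
    # chronological order: block, then scene before spatial within the block
    task_rank = df["task"].map({TASK_SCENE: 0, TASK_SPATIAL: 1})
    df = (
        df.assign(_rank=task_rank)
        .sort_values(["participant_id", "block", "_rank"], kind="stable")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    df["trial_index"] = df.groupby("participant_id").cumcount()
    return df[list(SCHEDULE_COLUMNS)]
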