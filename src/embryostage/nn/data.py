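"""Dataset handling for classifier training.

On disk a dataset is ``videos/<video_id>/<frame_index>.png`` (or
``.jpg``) plus ``annotations.csv`` with columns
``video_id,frame_index,time_minutes,label``.  In memory it is a
:class:`FrameDataset` of aligned arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ..ontology import StageLabel, parse_label
from ..synthetic import render_frame

__all__ = [
    "FrameDataset",
    "exclude_transition_frames",
    "load_dataset",
    "make_blob_dataset",
]


@dataclass
class FrameDataset:
    """Aligned per-frame arrays: grayscale images, minutes, label ordinals, video ids."""

    images: list[np.ndarray]
    minutes: np.ndarray
    labels: np.ndarray  # ordinals into the label list
    video_ids: list[str]
    label_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.minutes) == len(self.labels) == len(self.video_ids) == n):
            raise ValueError("dataset arrays are misaligned")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices: np.ndarray) -> "FrameDataset":
        return FrameDataset(
            [self.images[i] for i in indices],
            self.minutes[indices],
            self.labels[indices],
            [self.video_ids[i] for i in indices],
            self.label_names,
        )


def exclude_transition_frames(
    annotations: pd.DataFrame, margin: int = 2
) -> pd.DataFrame:
    """Drop frames within ``margin`` frames of a label change, per video.

    For a change between positions ``b-1`` and ``b``, positions
    ``b-margin .. b+margin-1`` are removed — ``margin`` frames on each
    side of the boundary.  Intended for training sets only; test sets
    keep every frame.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin == 0:
        return annotations.copy()
    keep_parts = []
    for _, grp in annotations.groupby("video_id", sort=False):
        grp = grp.sort_values("frame_index")
        labels = grp["label"].to_numpy()
        drop = np.zeros(len(grp), dtype=bool)
        for b in np.flatnonzero(labels[1:] != labels[:-1]) + 1:
            drop[max(0, b - margin) : b + margin] = True
        keep_parts.append(grp[~drop])
    return pd.concat(keep_parts, ignore_index=True)


def load_dataset(root: str | Path) -> FrameDataset:
    """Read an on-disk dataset into memory."""
    root = Path(root)
    ann = pd.read_csv(root / "annotations.csv")
    images, minutes, labels, vids = [], [], [], []
    from ..ontology import STAGE_NAMES

    for row in ann.itertuples(index=False):
        vdir = root / "videos" / str(row.video_id)
        path = vdir / f"{row.frame_index}.png"
        if not path.exists():
            path = vdir / f"{row.frame_index}.jpg"
        images.append(np.asarray(Image.open(path).convert("L")))
        minutes.append(float(row.time_minutes))
        labels.append(parse_label(str(row.label)).ordinal)
        vids.append(str(row.video_id))
    return FrameDataset(
        images, np.array(minutes), np.array(labels, dtype=np.int64), vids, STAGE_NAMES
    )


#: Minutes since fertilisation typical of each renderable stage, used to
#: give synthetic classification frames plausible timestamps.
_TYPICAL_MINUTES = {
    "tPB2": 120, "tPNa": 600, "tPNf": 1380, "t2": 1680, "t3": 2220,
    "t4": 2300, "t5": 3060, "t6": 3180, "t7": 3330, "t8": 3500,
    "t9+": 4200, "tM": 5160, "tSB": 5760, "tB": 6240, "tEB": 6720,
    "tHB": 7400, "Empty": 7600,
}


def make_blob_dataset(
    classes: tuple[str, ...] = ("t2", "t3", "t4", "t5", "t6"),
    videos_per_class: int = 20,
    frames_per_video: int = 6,
    size: int = 32,
    seed: int = 0,
) -> FrameDataset:
    """Rendered classification dataset: each synthetic video shows one stage.

    Designed to be easy: class identity is carried by blob count and
    total foreground area, so a tiny model separates it quickly.
    """
    rng = np.random.default_rng(seed)
    images, minutes, labels, vids = [], [], [], []
    stages: list[StageLabel] = [parse_label(c) for c in classes]
    v = 0
    for ci, stage in enumerate(stages):
        for _ in range(videos_per_class):
            vid = f"blob{v:04d}"
            v += 1
            base_t = _TYPICAL_MINUTES[stage.name] + rng.uniform(-120, 120)
            for k in range(frames_per_video):
                images.append(render_frame(stage, size, rng))
                minutes.append(max(0.0, base_t + 20.0 * k))
                labels.append(ci)
                vids.append(vid)
    return FrameDataset(
        images, np.array(minutes), np.array(labels, dtype=np.int64), vids, tuple(classes)
    )
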