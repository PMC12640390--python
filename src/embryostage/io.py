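"""CSV/JSON readers and writers for the interchange formats.

All tables are UTF-8 comma-separated with a header row.  Probabilities
are written at 6 decimal places and hours in summaries at 2; round trips
are stable at those precisions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import ALL_STAGES, LabelError, StageLabel, parse_label
from .postprocess import FramePrediction, PredictionSequence
from .timings import TransitionEvent

__all__ = [
    "AnnotationRecord",
    "read_annotations",
    "annotations_to_frame",
    "read_predictions",
    "write_predictions",
    "write_final_labels",
    "read_events",
    "write_events",
    "write_summary",
    "read_summary",
    "write_metrics",
]

_PROB_COLUMNS = [f"p_{s.name}" for s in ALL_STAGES]


@dataclass(frozen=True)
class AnnotationRecord:
    video_id: str
    frame_index: int
    time_minutes: float
    label: StageLabel


def read_annotations(path: str | Path) -> dict[str, list[AnnotationRecord]]:
    """Validated annotation records grouped by video, sorted by frame index.

    Raises
    ------
    ValueError
        On a missing column, an unparseable label or non-monotone times
        — each naming the offending row.
    """
    df = pd.read_csv(path)
    required = ["video_id", "frame_index", "time_minutes", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records: dict[str, list[AnnotationRecord]] = {}
    for row in df.itertuples():
        try:
            label = parse_label(str(row.label))
        except LabelError as exc:
            raise ValueError(f"{path}: row {row.Index + 2}: {exc}") from None
        records.setdefault(str(row.video_id), []).append(
            AnnotationRecord(
                str(row.video_id), int(row.frame_index), float(row.time_minutes), label
            )
        )
    for vid, recs in records.items():
        recs.sort(key=lambda r: r.frame_index)
        for a, b in zip(recs, recs[1:]):
            if b.frame_index == a.frame_index:
                raise ValueError(
                    f"{path}: duplicate frame_index {b.frame_index} in video {vid!r}"
                )
            if b.time_minutes <= a.time_minutes:
                raise ValueError(
                    f"{path}: non-monotone time at video {vid!r} frame {b.frame_index}"
                )
    return records


def annotations_to_frame(records: dict[str, list[AnnotationRecord]]) -> pd.DataFrame:
    rows = [
        (r.video_id, r.frame_index, r.time_minutes, r.label.name)
        for recs in records.values()
        for r in recs
    ]
    return pd.DataFrame(rows, columns=["video_id", "frame_index", "time_minutes", "label"])


def write_predictions(path: str | Path, sequences: list[PredictionSequence]) -> None:
    rows = []
    for seq in sequences:
        for f in seq.frames:
            rows.append(
                [seq.video_id, f.frame_index, f.time_minutes]
                + [round(float(p), 6) for p in f.probabilities]
            )
    df = pd.DataFrame(rows, columns=["video_id", "frame_index", "time_minutes"] + _PROB_COLUMNS)
    df.to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[PredictionSequence]:
    df = pd.read_csv(path)
    missing = [c for c in ["video_id", "frame_index", "time_minutes"] + _PROB_COLUMNS
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    sequences = []
    for vid, grp in df.groupby("video_id", sort=False):
        grp = grp.sort_values("frame_index")
        probs = grp[_PROB_COLUMNS].to_numpy(dtype=np.float64)
        probs = probs / probs.sum(axis=1, keepdims=True)  # undo rounding drift
        frames = tuple(
            FramePrediction.from_probabilities(
                int(fi), float(tm), p
            )
            for fi, tm, p in zip(grp["frame_index"], grp["time_minutes"], probs)
        )
        sequences.append(PredictionSequence(str(vid), frames))
    return sequences


def write_final_labels(
    path: str | Path,
    seq: PredictionSequence,
    final: list[StageLabel],
    append: bool = False,
) -> None:
    rows = [
        (seq.video_id, f.frame_index, f.time_minutes, f.top_label.name, lab.name)
        for f, lab in zip(seq.frames, final)
    ]
    df = pd.DataFrame(
        rows, columns=["video_id", "frame_index", "time_minutes", "label_raw", "label_final"]
    )
    path = Path(path)
    header = not (append and path.exists())
    df.to_csv(path, index=False, mode="a" if append else "w", header=header)


def write_events(path: str | Path, events: list[TransitionEvent]) -> None:
    df = pd.DataFrame(
        [(e.video_id, e.stage.name, round(e.time_hours, 6)) for e in events],
        columns=["video_id", "stage", "time_hours"],
    )
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> list[TransitionEvent]:
    df = pd.read_csv(path)
    missing = [c for c in ("video_id", "stage", "time_hours") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        TransitionEvent(str(r.video_id), parse_label(str(r.stage)), float(r.time_hours))
        for r in df.itertuples(index=False)
    ]


def write_summary(path: str | Path, summary: pd.DataFrame) -> None:
    """Timing-error summary CSV: stats as rows (count, mean, std, percentiles)."""
    out = summary.copy()
    out.loc[out.index != "count"] = out.loc[out.index != "count"].round(2)
    out.to_csv(path, index_label="statistic")


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="statistic")


def write_metrics(path: str | Path, metrics: dict) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
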