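"""Denoising of per-frame stage predictions.

The smoother works in two stages.  First, frames whose top-class
probability does not exceed a confidence threshold (default 0.8) are
replaced by the most recent confident prediction.  Second, the label
sequence is partitioned into runs by cumulative change counting; for
every class, any run whose id falls strictly inside the span of that
class's run ids but does not belong to the class is an *interruptive
group* and is relabelled to the class.  The procedure iterates to a
fixpoint, so the final sequence has every class occupying a contiguous
block of runs.  Unlike monotonic-regression smoothing, genuine stage
reversions (reverse cleavage) survive: two long runs in reverse order
are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ontology import ALL_STAGES, StageLabel

__all__ = [
    "FramePrediction",
    "PredictionSequence",
    "RunGroup",
    "substitute_low_confidence",
    "compute_changes",
    "assign_groups",
    "run_groups",
    "find_interruptive_groups",
    "remove_interruptions",
    "smooth",
]

DEFAULT_CONFIDENCE_THRESHOLD = 0.8


@dataclass(frozen=True)
class FramePrediction:
    """Per-frame classifier output.

    ``top_label`` is the argmax of ``probabilities`` (ties broken toward
    the lower ordinal, i.e. the earlier stage) and ``confidence`` its
    value.  Both are derived in :meth:`from_probabilities`; when built
    directly they are validated.
    """

    frame_index: int
    time_minutes: float
    probabilities: np.ndarray
    top_label: StageLabel
    confidence: float

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=np.float64)
        object.__setattr__(self, "probabilities", probs)
        if probs.ndim != 1 or len(probs) != len(ALL_STAGES):
            raise ValueError(
                f"probabilities must have length {len(ALL_STAGES)}, got shape {probs.shape}"
            )
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be non-negative and sum to 1 (tol 1e-6)")
        # np.argmax returns the first maximum, i.e. the lowest ordinal on ties
        am = int(np.argmax(probs))
        if self.top_label.ordinal != am:
            raise ValueError(
                f"top_label {self.top_label} is not the argmax of probabilities "
                f"({ALL_STAGES[am]})"
            )
        if abs(self.confidence - probs[am]) > 1e-9:
            raise ValueError("confidence must equal max(probabilities)")

    @classmethod
    def from_probabilities(
        cls, frame_index: int, time_minutes: float, probabilities: np.ndarray
    ) -> "FramePrediction":
        probs = np.asarray(probabilities, dtype=np.float64)
        am = int(np.argmax(probs))
        return cls(frame_index, float(time_minutes), probs, ALL_STAGES[am], float(probs[am]))


@dataclass(frozen=True)
class PredictionSequence:
    """Ordered frame predictions for one video."""

    video_id: str
    frames: tuple[FramePrediction, ...]

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        idx = [f.frame_index for f in frames]
        t = [f.time_minutes for f in frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"frame_index must be strictly increasing in video {self.video_id}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"time_minutes must be strictly increasing in video {self.video_id}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_minutes(self) -> np.ndarray:
        return np.array([f.time_minutes for f in self.frames], dtype=np.float64)

    @property
    def top_labels(self) -> list[StageLabel]:
        return [f.top_label for f in self.frames]


@dataclass(frozen=True)
class RunGroup:
    """A maximal run of identical labels; ``group_id`` is its cumulative-change value."""

    group_id: int
    label: StageLabel
    start: int
    length: int


def substitute_low_confidence(
    seq: PredictionSequence,
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> list[StageLabel]:
    """Replace low-confidence top labels by the latest confident one.

    A frame keeps its own top label when its confidence is strictly
    greater than ``threshold``; otherwise it takes the top label of the
    most recent earlier frame exceeding the threshold.  Leading frames
    with no confident predecessor keep their own labels.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if len(seq) == 0:
        raise ValueError(f"empty prediction sequence for video {seq.video_id}")
    out: list[StageLabel] = []
    last_confident: StageLabel | None = None
    for frame in seq.frames:
        if frame.confidence > threshold:
            last_confident = frame.top_label
            out.append(frame.top_label)
        else:
            out.append(last_confident if last_confident is not None else frame.top_label)
    return out


def compute_changes(labels: list[StageLabel]) -> np.ndarray:
    """Binary change vector: 1 where the label differs from its predecessor.

    The first frame has no predecessor and is assigned 0.
    """
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    delta = np.zeros(len(labels), dtype=np.int64)
    for i in range(1, len(labels)):
        delta[i] = int(labels[i] != labels[i - 1])
    return delta


def assign_groups(changes: np.ndarray) -> np.ndarray:
    """Running sum of the change vector; equal values mark one run."""
    return np.cumsum(np.asarray(changes, dtype=np.int64))


def run_groups(labels: list[StageLabel]) -> list[RunGroup]:
    """Decompose a label sequence into its maximal same-label runs."""
    groups = assign_groups(compute_changes(labels))
    out: list[RunGroup] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or groups[i] != groups[i - 1]:
            out.append(RunGroup(int(groups[start]), labels[start], start, i - start))
            start = i
    return out


def find_interruptive_groups(
    labels: list[StageLabel], groups: np.ndarray
) -> dict[StageLabel, dict[int, int]]:
    """Interruptive group ids (with lengths) per class.

    For class ``c`` with run ids ``Gc``, every id in ``[min(Gc), max(Gc)]``
    that is not in ``Gc`` belongs to a run of a foreign class sitting
    strictly inside ``c``'s span; it is interruptive for ``c``.
    """
    groups = np.asarray(groups)
    if len(labels) != len(groups):
        raise ValueError("labels and group vector must be aligned")
    lengths: dict[int, int] = {}
    ids_by_class: dict[StageLabel, set[int]] = {}
    for lab, g in zip(labels, groups):
        g = int(g)
        lengths[g] = lengths.get(g, 0) + 1
        ids_by_class.setdefault(lab, set()).add(g)
    result: dict[StageLabel, dict[int, int]] = {}
    for lab, gc in ids_by_class.items():
        gmin, gmax = min(gc), max(gc)
        result[lab] = {
            ig: lengths[ig] for ig in range(gmin, gmax + 1) if ig not in gc
        }
    return result


def remove_interruptions(
    labels: list[StageLabel], min_main_run: int = 1
) -> list[StageLabel]:
    """Relabel every interruptive group to its enclosing class, to fixpoint.

    Classes are processed in ascending order of first occurrence (order
    fixed at the start of each pass); passes repeat until no interruptive
    group remains.  Each relabelling merges runs, so the run count
    strictly decreases and the procedure terminates.

    ``min_main_run`` > 1 enables a length-guarded variant: only runs of
    at least that many frames anchor a class's span, so an isolated
    spike of a class cannot capture the frames between itself and the
    class's main run.
    """
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    labels = list(labels)
    while True:
        changed = False
        order: list[StageLabel] = []
        for lab in labels:  # ascending first occurrence
            if lab not in order:
                order.append(lab)
        for cls in order:
            groups = assign_groups(compute_changes(labels))
            run_len: dict[int, int] = {}
            for lab, g in zip(labels, groups):
                if lab == cls:
                    run_len[int(g)] = run_len.get(int(g), 0) + 1
            gc = set(run_len)
            anchors = {g for g, n in run_len.items() if n >= min_main_run}
            if len(anchors) < 2:
                continue
            gmin, gmax = min(anchors), max(anchors)
            interruptive = {g for g in range(gmin, gmax + 1) if g not in gc}
            if not interruptive:
                continue
            for i, g in enumerate(groups):
                if int(g) in interruptive:
                    labels[i] = cls
            changed = True
        if not changed:
            return labels


def smooth(
    seq: PredictionSequence,
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    min_main_run: int = 1,
) -> list[StageLabel]:
    """Full two-stage denoising: confidence substitution, then interruption removal."""
    return remove_interruptions(
        substitute_low_confidence(seq, threshold), min_main_run=min_main_run
    )
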