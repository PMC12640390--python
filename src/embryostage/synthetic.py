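"""Synthetic time-lapse data: timelines, rendered frames, noisy predictions.

The generator emulates the structure of a real annotated embryo
time-lapse corpus: per-video stage timelines over the 17-class ontology,
a fixed frame interval (default 20 min), day-5 removal producing Empty
frames, occasional arrest and reverse-cleavage episodes, and per-frame
classifier noise concentrated around stage transitions with occasional
low-confidence dips — so the smoothing and timing modules can be
exercised end to end without any real data.

Rendered frames are deliberately schematic (stage-coded blob geometry in
a circular well): the point is that class identity is recoverable by a
small model, not photorealism.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import disk as _disk

from .ontology import ALL_STAGES, DEVELOPMENTAL_STAGES, EMPTY, StageLabel, parse_label
from .postprocess import FramePrediction, PredictionSequence
from .timings import TransitionEvent, extract_transitions

__all__ = [
    "DEFAULT_STAGE_HOURS",
    "TimelineConfig",
    "NoiseConfig",
    "SyntheticTimeline",
    "sample_timeline",
    "render_frame",
    "simulate_predictions",
    "split_videos",
    "generate_dataset",
]

#: Mean stage durations in hours.  Loosely anchored to clinical
#: morphokinetics (2-cell around day 1, blastocyst around day 4-5) but
#: these are configuration defaults, not biological claims.
DEFAULT_STAGE_HOURS: dict[str, float] = {
    "tPB2": 5.0,
    "tPNa": 16.0,
    "tPNf": 4.0,
    "t2": 11.0,
    "t3": 1.5,
    "t4": 13.0,
    "t5": 2.0,
    "t6": 2.5,
    "t7": 2.0,
    "t8": 9.0,
    "t9+": 18.0,
    "tM": 10.0,
    "tSB": 8.0,
    "tB": 8.0,
    "tEB": 12.0,
    "tHB": 10.0,
}


@dataclass(frozen=True)
class TimelineConfig:
    frame_interval_minutes: float = 20.0
    stage_duration_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_HOURS)
    )
    duration_log_sigma: float = 0.18
    reversion_probability: float = 0.05
    removal_day: float = 5.0
    removal_jitter_hours: float = 6.0
    arrest_probability: float = 0.25
    tail_hours: float = 8.0

    def __post_init__(self) -> None:
        if self.frame_interval_minutes <= 0:
            raise ValueError("frame_interval_minutes must be positive")
        if any(v <= 0 for v in self.stage_duration_means.values()):
            raise ValueError("stage durations must be positive")
        for name, p in (
            ("reversion_probability", self.reversion_probability),
            ("arrest_probability", self.arrest_probability),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-frame prediction-noise model.

    ``baseline_error_rate``: away from transitions, probability that a
    frame flips to an ordinal-adjacent class with low confidence.
    ``transition_error_rate``: inside the transition window, probability
    a frame is corrupted (confidence dips below the 0.8 substitution
    threshold; half of corrupted frames also swap to the class on the
    other side of the boundary).  ``boundary_flip_rate``: probability
    that one of the two frames straddling a boundary is a *confident*
    flip to its partner class.  Confidences never fall below
    ``confidence_floor``.
    """

    baseline_error_rate: float = 0.05
    transition_window_frames: int = 3
    transition_error_rate: float = 0.12
    boundary_flip_rate: float = 0.10
    confidence_floor: float = 0.35
    low_confidence_ceiling: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "baseline_error_rate",
            "transition_error_rate",
            "boundary_flip_rate",
            "confidence_floor",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.transition_error_rate < self.baseline_error_rate:
            raise ValueError("transition_error_rate must be >= baseline_error_rate")
        if not 0 < self.confidence_floor < self.low_confidence_ceiling <= 1:
            raise ValueError("need 0 < confidence_floor < low_confidence_ceiling <= 1")


@dataclass(frozen=True)
class SyntheticTimeline:
    """Ground truth for one synthetic video.

    ``events`` are frame-quantised: each is the first *frame* bearing a
    new label, matching what transition extraction reports on the true
    label sequence.
    """

    video_id: str
    times_minutes: np.ndarray
    labels: tuple[StageLabel, ...]
    events: tuple[TransitionEvent, ...]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_timeline(
    config: TimelineConfig | None = None,
    seed: int | np.random.Generator | None = None,
    video_id: str = "synthetic",
) -> SyntheticTimeline:
    """Draw one per-frame (time, true stage) timeline.

    Stages traverse the developmental order with log-normal durations;
    with configured probabilities a video arrests at a random cleavage or
    blastocyst stage, or shows one reverse-cleavage episode (a temporary
    return to the previous stage).  Frames after the day-``removal_day``
    removal time are labelled Empty.
    """
    config = config or TimelineConfig()
    rng = _rng(seed)
    sigma = config.duration_log_sigma
    durations: dict[str, float] = {}
    for stage in DEVELOPMENTAL_STAGES:
        mean = config.stage_duration_means[stage.name]
        mu = np.log(mean) - sigma**2 / 2.0  # lognormal with the requested mean
        durations[stage.name] = float(rng.lognormal(mu, sigma))

    arrest_at: int | None = None
    if rng.random() < config.arrest_probability:
        arrest_at = int(rng.integers(3, 15))  # t2 .. tEB

    removal_h = config.removal_day * 24.0 + float(
        rng.uniform(0.0, config.removal_jitter_hours)
    )
    end_h = config.removal_day * 24.0 + config.tail_hours

    events: list[tuple[StageLabel, float]] = []
    t = 0.0
    for stage in DEVELOPMENTAL_STAGES:
        if t >= removal_h:
            break
        events.append((stage, t))
        if arrest_at is not None and stage.ordinal == arrest_at:
            break
        t += durations[stage.name]

    if rng.random() < config.reversion_probability:
        events = _insert_reversion(events, removal_h, rng)

    events.append((EMPTY, removal_h))

    n_frames = int(np.floor(end_h * 60.0 / config.frame_interval_minutes)) + 1
    times = np.arange(n_frames, dtype=np.float64) * config.frame_interval_minutes
    starts = np.array([e[1] * 60.0 for e in events])
    idx = np.searchsorted(starts, times, side="right") - 1
    labels = tuple(events[i][0] for i in idx)
    truth = tuple(extract_transitions(list(labels), times, video_id))
    return SyntheticTimeline(video_id, times, labels, truth)


def _insert_reversion(
    events: list[tuple[StageLabel, float]],
    removal_h: float,
    rng: np.random.Generator,
) -> list[tuple[StageLabel, float]]:
    """One reverse-cleavage episode inside a sufficiently long cleavage stage."""
    candidates = []
    for k in range(1, len(events)):
        stage, start = events[k]
        nxt = events[k + 1][1] if k + 1 < len(events) else removal_h
        if 4 <= stage.ordinal <= 9 and nxt - start >= 2.5:  # t3 .. t8
            candidates.append((k, start, nxt))
    if not candidates:
        return events
    k, start, nxt = candidates[int(rng.integers(len(candidates)))]
    stage = events[k][0]
    prev_stage = ALL_STAGES[stage.ordinal - 1]
    rev_dur = float(rng.uniform(0.5, 1.5))
    rev_start = start + float(rng.uniform(0.3, 0.6)) * (nxt - start - rev_dur)
    out = events[: k + 1]
    out.append((prev_stage, rev_start))
    out.append((stage, rev_start + rev_dur))
    out.extend(events[k + 1 :])
    return out


# ---------------------------------------------------------------------------
# frame rendering


def _place_discs(
    rng: np.random.Generator, n: int, well_r: float, disc_r: float, center: float
) -> list[tuple[float, float]]:
    """Non-overlapping disc centres inside the well, by rejection sampling."""
    margin = 2.0
    positions: list[tuple[float, float]] = []
    spacing = 2 * disc_r + margin
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 400:  # relax spacing rather than loop forever
            spacing *= 0.92
            attempts = 0
        rho = np.sqrt(rng.uniform(0, 1)) * (well_r - disc_r - margin)
        theta = rng.uniform(0, 2 * np.pi)
        x, y = center + rho * np.cos(theta), center + rho * np.sin(theta)
        if all((x - px) ** 2 + (y - py) ** 2 >= spacing**2 for px, py in positions):
            positions.append((x, y))
    return positions


_CLEAVAGE_COUNTS = {"t2": 2, "t3": 3, "t4": 4, "t5": 5, "t6": 6, "t7": 7, "t8": 8, "t9+": 10}

_WELL_VALUE = 90
_BACKGROUND = 30
_BLOB_VALUE = 200


def render_frame(
    stage: StageLabel, size: int = 64, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Render a schematic grayscale frame for ``stage`` (uint8, size x size).

    A circular well contains stage-coded geometry: a single large disc
    with internal marks for the pronuclear stages, N bright discs for the
    cleavage stages, a cluster of tiny discs for the morula, a cavity of
    growing size for the blastocyst stages, and nothing for Empty.
    Bright structures sit at a fixed intensity so a threshold-and-count
    blob detector can recover cleavage counts.  Deterministic per seed.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    rng = _rng(seed)
    img = np.full((size, size), _BACKGROUND, dtype=np.float64)
    c = (size - 1) / 2.0
    well_r = 0.48 * size
    rr, cc = _disk((c, c), well_r, shape=img.shape)
    img[rr, cc] = _WELL_VALUE

    name = stage.name
    if name in ("tPB2", "tPNa", "tPNf"):
        body_r = 0.28 * size
        rr, cc = _disk((c, c), body_r, shape=img.shape)
        img[rr, cc] = 150
        if name == "tPB2":  # polar body at the edge of the zygote
            rr, cc = _disk((c, c + body_r + 0.04 * size), 0.045 * size, shape=img.shape)
            img[rr, cc] = _BLOB_VALUE
        elif name == "tPNa":  # two pronuclei
            off = 0.09 * size
            for dx in (-off, off):
                rr, cc = _disk((c, c + dx), 0.06 * size, shape=img.shape)
                img[rr, cc] = _BLOB_VALUE
    elif name in _CLEAVAGE_COUNTS:
        n = _CLEAVAGE_COUNTS[name]
        disc_r = (0.09 if n <= 6 else 0.08 if n <= 8 else 0.07) * size
        for x, y in _place_discs(rng, n, well_r, disc_r, c):
            rr, cc = _disk((x, y), disc_r, shape=img.shape)
            img[rr, cc] = _BLOB_VALUE
    elif name == "tM":  # compacted cluster of many tiny cells
        disc_r = 0.04 * size
        for x, y in _place_discs(rng, 18, 0.34 * size, disc_r, c):
            rr, cc = _disk((x, y), disc_r, shape=img.shape)
            img[rr, cc] = _BLOB_VALUE
    elif name in ("tSB", "tB", "tEB", "tHB"):
        body_r = {"tSB": 0.30, "tB": 0.30, "tEB": 0.36, "tHB": 0.30}[name] * size
        cavity_r = {"tSB": 0.08, "tB": 0.16, "tEB": 0.24, "tHB": 0.16}[name] * size
        rr, cc = _disk((c, c), body_r, shape=img.shape)
        img[rr, cc] = 180
        rr, cc = _disk((c, c), cavity_r, shape=img.shape)
        img[rr, cc] = 100
        if name == "tHB":  # herniation outside the zona
            rr, cc = _disk((c, c + body_r + 0.07 * size), 0.07 * size, shape=img.shape)
            img[rr, cc] = 180
    elif name == "Empty":
        pass
    else:  # pragma: no cover - ontology is closed
        raise ValueError(f"no renderer for stage {name}")

    img += rng.normal(0.0, 2.0, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# prediction noise


def _probability_vector(label: StageLabel, confidence: float) -> np.ndarray:
    """Vector with ``confidence`` on ``label`` and the remainder on neighbours.

    The leak is split between the two ordinal-adjacent classes; at the
    ontology edges the missing neighbour's share is spread uniformly over
    the remaining classes so the stated label always stays the argmax.
    """
    k = len(ALL_STAGES)
    p = np.zeros(k)
    p[label.ordinal] = confidence
    leak = 1.0 - confidence
    neighbours = [o for o in (label.ordinal - 1, label.ordinal + 1) if 0 <= o < k]
    for o in neighbours:
        p[o] += leak / 2.0
    short = leak - (leak / 2.0) * len(neighbours)
    if short > 0:
        others = [o for o in range(k) if o != label.ordinal and o not in neighbours]
        p[others] += short / len(others)
    return p


def simulate_predictions(
    timeline: SyntheticTimeline,
    noise: NoiseConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> PredictionSequence:
    """Emulate noisy classifier output for a ground-truth timeline.

    Away from transitions, frames are confident and correct except for
    occasional low-confidence flips to an ordinal-adjacent class.  Inside
    the transition window, confidence dips and corrupted frames swap to
    the class on the other side of the boundary; the two frames
    straddling a boundary may additionally carry a *confident* flip,
    which only the run-grouping stage of the smoother can repair.  With
    all rates zero the output is exact and fully confident.
    """
    noise = noise or NoiseConfig()
    rng = _rng(seed)
    labels = timeline.labels
    n = len(labels)
    boundaries = [i for i in range(1, n) if labels[i] != labels[i - 1]]

    frames = []
    for i in range(n):
        true = labels[i]
        nearest = None
        for b in boundaries:
            if b - noise.transition_window_frames <= i <= b + noise.transition_window_frames - 1:
                if nearest is None or abs(i - b) < abs(i - nearest):
                    nearest = b
        label, conf = true, 1.0
        if nearest is not None:
            partner = labels[nearest] if i < nearest else labels[nearest - 1]
            at_boundary = i in (nearest - 1, nearest)
            if at_boundary and rng.random() < noise.boundary_flip_rate:
                label = partner
                conf = 1.0 - float(rng.uniform(0.0, noise.baseline_error_rate))
            elif rng.random() < noise.transition_error_rate:
                conf = float(rng.uniform(noise.confidence_floor, noise.low_confidence_ceiling))
                if rng.random() < 0.5:
                    label = partner
            else:
                conf = 1.0 - float(rng.uniform(0.0, noise.transition_error_rate))
        else:
            if rng.random() < noise.baseline_error_rate:
                step = -1 if rng.random() < 0.5 else 1
                o = min(max(true.ordinal + step, 0), len(ALL_STAGES) - 1)
                if o == true.ordinal:
                    o = true.ordinal - step
                label = ALL_STAGES[o]
                conf = float(rng.uniform(noise.confidence_floor, noise.low_confidence_ceiling))
            else:
                conf = 1.0 - float(rng.uniform(0.0, noise.baseline_error_rate))
        frames.append(
            FramePrediction.from_probabilities(
                i, timeline.times_minutes[i], _probability_vector(label, conf)
            )
        )
    return PredictionSequence(timeline.video_id, tuple(frames))


# ---------------------------------------------------------------------------
# on-disk datasets


def split_videos(
    video_ids: list[str],
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int | np.random.Generator | None = None,
) -> dict[str, str]:
    """Video-level train/val/test assignment by largest-remainder rounding."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = _rng(seed)
    ids = list(video_ids)
    rng.shuffle(ids)
    n = len(ids)
    quotas = [f * n for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    remainders = [q - b for q, b in zip(quotas, base)]
    for _ in range(n - sum(base)):
        j = int(np.argmax(remainders))
        base[j] += 1
        remainders[j] = -1.0
    names = ("train", "val", "test")
    out: dict[str, str] = {}
    pos = 0
    for name, count in zip(names, base):
        for vid in ids[pos : pos + count]:
            out[vid] = name
        pos += count
    return out


def generate_dataset(
    n_videos: int,
    out_dir: str | Path,
    timeline_config: TimelineConfig | None = None,
    size: int = 64,
    seed: int = 0,
    render: bool = True,
) -> dict[str, str]:
    """Write a synthetic dataset in the classifier's on-disk layout.

    Produces ``videos/<video_id>/<frame_index>.png`` (when ``render`` is
    true), ``annotations.csv`` and a 70/10/20 ``split.csv``.  Returns the
    split assignment.
    """
    if n_videos < 10:
        raise ValueError("need at least 10 videos for a meaningful 70/10/20 split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    config = timeline_config or TimelineConfig()
    video_ids = [f"vid{i:04d}" for i in range(n_videos)]

    with open(out_dir / "annotations.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["video_id", "frame_index", "time_minutes", "label"])
        for vid in video_ids:
            timeline = sample_timeline(config, rng, video_id=vid)
            vdir = out_dir / "videos" / vid
            if render:
                vdir.mkdir(parents=True, exist_ok=True)
            for i, (t, lab) in enumerate(zip(timeline.times_minutes, timeline.labels)):
                writer.writerow([vid, i, f"{t:g}", lab.name])
                if render:
                    Image.fromarray(render_frame(lab, size, rng)).save(
                        vdir / f"{i}.png"
                    )

    split = split_videos(video_ids, seed=rng)
    with open(out_dir / "split.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["video_id", "split"])
        for vid in video_ids:
            writer.writerow([vid, split[vid]])
    return split
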