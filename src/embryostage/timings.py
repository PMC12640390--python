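"""Stage-transition extraction and timing-error statistics.

A transition event records only the resulting stage (a change from t2 to
t4 and a change from t3 to t4 are both "transition to t4") and the time,
in hours, of the first frame carrying the new label.  Errors are signed:
predicted time minus ground-truth time.  Per-stage summaries report the
count, mean, sample standard deviation, and the 25/50/75/80/85/90/95/99th
percentiles, all in hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ontology import StageLabel

__all__ = [
    "TransitionEvent",
    "PERCENTILES",
    "extract_transitions",
    "timing_errors",
    "summarize_errors",
]

PERCENTILES: tuple[int, ...] = (25, 50, 75, 80, 85, 90, 95, 99)


@dataclass(frozen=True)
class TransitionEvent:
    """Arrival at a stage: the resulting stage and its first-frame time in hours."""

    video_id: str
    stage: StageLabel
    time_hours: float


def extract_transitions(
    labels: list[StageLabel],
    times_minutes: np.ndarray,
    video_id: str = "",
) -> list[TransitionEvent]:
    """One event per run start, including the first run.

    ``times_minutes`` must be strictly increasing and aligned with
    ``labels``; event times are reported in hours.
    """
    times_minutes = np.asarray(times_minutes, dtype=np.float64)
    if len(labels) != len(times_minutes):
        raise ValueError(
            f"labels ({len(labels)}) and times ({len(times_minutes)}) are misaligned"
        )
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    if np.any(np.diff(times_minutes) <= 0):
        raise ValueError("times must be strictly increasing")
    events = [TransitionEvent(video_id, labels[0], times_minutes[0] / 60.0)]
    for i in range(1, len(labels)):
        if labels[i] != labels[i - 1]:
            events.append(TransitionEvent(video_id, labels[i], times_minutes[i] / 60.0))
    return events


def _first_occurrence(
    events: list[TransitionEvent], policy: str
) -> dict[tuple[str, StageLabel], float]:
    table: dict[tuple[str, StageLabel], float] = {}
    for ev in events:
        key = (ev.video_id, ev.stage)
        if key in table:
            if policy == "error":
                raise ValueError(
                    f"duplicate event for stage {ev.stage} in video {ev.video_id!r}; "
                    "pass duplicate_policy='first' to keep the first occurrence"
                )
            continue  # 'first': keep earliest (events are time ordered per video)
        table[key] = ev.time_hours
    return table


def timing_errors(
    predicted: list[TransitionEvent],
    truth: list[TransitionEvent],
    duplicate_policy: str = "first",
) -> tuple[dict[StageLabel, list[float]], dict[str, list[tuple[str, StageLabel]]]]:
    """Signed per-stage timing errors, predicted minus truth, in hours.

    Events are matched by (video_id, stage).  Stages present on only one
    side are reported in the second return value under
    ``"unmatched_predicted"`` / ``"unmatched_truth"`` and excluded from
    the error lists.

    ``duplicate_policy`` is ``"first"`` (keep the first occurrence of a
    re-entered stage, the standard morphokinetic convention) or
    ``"error"``.
    """
    if duplicate_policy not in ("first", "error"):
        raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    pred = _first_occurrence(predicted, duplicate_policy)
    true = _first_occurrence(truth, duplicate_policy)
    errors: dict[StageLabel, list[float]] = {}
    unmatched: dict[str, list[tuple[str, StageLabel]]] = {
        "unmatched_predicted": sorted(
            (k for k in pred if k not in true), key=lambda k: (k[0], k[1].ordinal)
        ),
        "unmatched_truth": sorted(
            (k for k in true if k not in pred), key=lambda k: (k[0], k[1].ordinal)
        ),
    }
    for key, t_pred in pred.items():
        if key in true:
            errors.setdefault(key[1], []).append(t_pred - true[key])
    return errors, unmatched


def summarize_errors(errors: dict[StageLabel, list[float]]) -> pd.DataFrame:
    """Per-stage quantile summary of timing errors.

    Returns a DataFrame with one column per stage (developmental order)
    and rows ``count, mean, std, 25%, ..., 99%``.  Percentiles use linear
    interpolation between order statistics; statistics that need more
    data than available (std of a single error) are NaN.
    """
    rows = ["count", "mean", "std"] + [f"{p}%" for p in PERCENTILES]
    stages = sorted(errors, key=lambda s: s.ordinal)
    table = {}
    for stage in stages:
        vals = np.asarray(errors[stage], dtype=np.float64)
        col = [float(len(vals))]
        if len(vals) == 0:
            col += [np.nan] * (2 + len(PERCENTILES))
        else:
            col.append(float(np.mean(vals)))
            col.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan)
            col.extend(float(np.percentile(vals, p)) for p in PERCENTILES)
        table[stage.name] = col
    return pd.DataFrame(table, index=rows)
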