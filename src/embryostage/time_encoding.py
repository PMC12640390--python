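"""One-hot encoding of elapsed time since fertilisation.

Time is binned into two-hour windows over a maximum incubation of seven
days, giving 7 * 24 / 2 = 84 windows.  The encoded vector is consumed by
the fused image+time classifier.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["WINDOW_MINUTES", "VECTOR_LENGTH", "MAX_MINUTES", "time_to_index", "encode_time"]

WINDOW_MINUTES = 60 * 2
MAX_DAYS = 7
VECTOR_LENGTH = MAX_DAYS * 24 * 60 // WINDOW_MINUTES  # 84
MAX_MINUTES = MAX_DAYS * 24 * 60  # 10080


def time_to_index(minutes: float) -> int:
    """Map minutes since fertilisation to a two-hour window index.

    ``index = floor(minutes / 120)``, clamped to the last window (83)
    with a warning for times at or beyond seven days.

    Raises
    ------
    ValueError
        If ``minutes`` is negative or not finite.
    """
    minutes = float(minutes)
    if not np.isfinite(minutes) or minutes < 0:
        raise ValueError(f"minutes must be finite and non-negative, got {minutes}")
    index = int(minutes // WINDOW_MINUTES)
    if index >= VECTOR_LENGTH:
        warnings.warn(
            f"time {minutes:.1f} min exceeds the {MAX_DAYS}-day window range; "
            f"clamping to index {VECTOR_LENGTH - 1}",
            stacklevel=2,
        )
        index = VECTOR_LENGTH - 1
    return index


def encode_time(minutes: float) -> np.ndarray:
    """One-hot vector of length 84 with a 1 in the window containing ``minutes``."""
    vec = np.zeros(VECTOR_LENGTH, dtype=np.float64)
    vec[time_to_index(minutes)] = 1.0
    return vec
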