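"""The 17-class morphokinetic stage ontology.

Stages follow the developmental order of human pre-implantation
development: polar-body appearance, pronuclear appearance/fading, the
cleavage stages (2 through 8 cells, then 9-plus), morula, blastulation
onset, blastocyst, expanded blastocyst, hatched blastocyst.  A 17th
class, ``Empty``, marks frames acquired after the embryo was removed
from the well; it is a well-state flag, not a developmental stage, and
is therefore excluded from developmental adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import total_ordering

__all__ = [
    "STAGE_NAMES",
    "StageLabel",
    "LabelError",
    "ALL_STAGES",
    "DEVELOPMENTAL_STAGES",
    "RARE_STAGES",
    "EMPTY",
    "parse_label",
    "is_adjacent",
]

#: Canonical label strings, in developmental order; ``Empty`` is last.
STAGE_NAMES: tuple[str, ...] = (
    "tPB2",
    "tPNa",
    "tPNf",
    "t2",
    "t3",
    "t4",
    "t5",
    "t6",
    "t7",
    "t8",
    "t9+",
    "tM",
    "tSB",
    "tB",
    "tEB",
    "tHB",
    "Empty",
)

#: Accepted alternative spellings (e.g. filesystem-safe forms of ``t9+``).
LABEL_ALIASES: dict[str, str] = {
    "t9plus": "t9+",
    "t9 +": "t9+",
    "t9+ ": "t9+",
}

#: Stages with too few samples to analyse; evaluation excludes them by default.
RARE_STAGES: frozenset[str] = frozenset({"tHB"})


class LabelError(ValueError):
    """Raised when a string is not a recognised morphokinetic label."""


@total_ordering
@dataclass(frozen=True)
class StageLabel:
    """One of the 17 morphokinetic classes.

    Attributes
    ----------
    name : str
        Canonical label string.
    ordinal : int
        Position 0-16 in developmental order; ``Empty`` is 16.
    rare : bool
        True for stages excluded from analysis by default (``tHB``).
    """

    name: str
    ordinal: int
    rare: bool = field(default=False, compare=False)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name

    def __lt__(self, other: "StageLabel") -> bool:
        if not isinstance(other, StageLabel):
            return NotImplemented
        return self.ordinal < other.ordinal


ALL_STAGES: tuple[StageLabel, ...] = tuple(
    StageLabel(name, i, rare=name in RARE_STAGES)
    for i, name in enumerate(STAGE_NAMES)
)

#: The 16 developmental stages (``Empty`` excluded).
DEVELOPMENTAL_STAGES: tuple[StageLabel, ...] = ALL_STAGES[:-1]

EMPTY: StageLabel = ALL_STAGES[-1]

_BY_NAME: dict[str, StageLabel] = {s.name: s for s in ALL_STAGES}


def parse_label(text: str) -> StageLabel:
    """Parse a canonical label string (or documented alias) into a stage.

    Raises
    ------
    LabelError
        If ``text`` is not one of the 17 canonical names or a known alias.
    """
    if not isinstance(text, str):
        raise LabelError(f"label must be a string, got {type(text).__name__}")
    key = LABEL_ALIASES.get(text, text)
    try:
        return _BY_NAME[key]
    except KeyError:
        raise LabelError(
            f"unknown morphokinetic label {text!r}; expected one of "
            f"{', '.join(STAGE_NAMES)}"
        ) from None


def is_adjacent(a: StageLabel, b: StageLabel) -> bool:
    """True iff ``a`` and ``b`` are consecutive developmental stages.

    ``Empty`` is adjacent to nothing: it denotes a well state rather
    than a developmental event.
    """
    if a == EMPTY or b == EMPTY:
        return False
    return abs(a.ordinal - b.ordinal) == 1
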