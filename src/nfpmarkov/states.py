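"""Behavior state space for smoking and betel quid chewing.

Each behavior is observed at every screening round in one of three ordered
intensity categories: ``none`` (never used or ceased), ``low`` (fewer than
20 units per day) and ``high`` (20 or more units per day).
"""

from __future__ import annotations

import enum
import math
from functools import total_ordering

#: Canonical state order; integer codes index transition matrices.
STATES: tuple[str, str, str] = ("none", "low", "high")

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

#: The six directed off-diagonal transitions, in the canonical order
#: N→L, N→H, L→N, L→H, H→N, H→L.
TRANSITIONS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1),
)

TRANSITION_INDEX: dict[tuple[int, int], int] = {
    rs: t for t, rs in enumerate(TRANSITIONS)
}

#: Daily-unit threshold separating low from high dose (units/day at or
#: above it classify as high).
HIGH_DOSE_THRESHOLD = 20.0

BEHAVIORS: tuple[str, str] = ("smoking", "betel")


@total_ordering
class BehaviorState(enum.Enum):
    """Ordered behavior intensity: ``NONE < LOW < HIGH``."""

    NONE = "none"
    LOW = "low"
    HIGH = "high"

    def __lt__(self, other: "BehaviorState") -> bool:
        if not isinstance(other, BehaviorState):
            return NotImplemented
        return STATE_INDEX[self.value] < STATE_INDEX[other.value]

    @property
    def index(self) -> int:
        return STATE_INDEX[self.value]

    @classmethod
    def from_label(cls, label: str) -> "BehaviorState":
        return cls(label)


def classify_dose(units_per_day: float, ever_user: bool = True) -> BehaviorState:
    """Classify a daily consumption into the three-level state space.

    Zero units per day means never used or ceased (``NONE``), regardless of
    ``ever_user``; below 20 units is ``LOW``; 20 or more is ``HIGH``.

    Parameters
    ----------
    units_per_day : float
        Cigarettes or betel quids consumed per day. Must be finite and
        nonnegative.
    ever_user : bool
        Whether the participant ever used; informational only (a current
        value of zero classifies as ``NONE`` — cessation — either way).
    """
    units = float(units_per_day)
    if not math.isfinite(units) or units < 0:
        raise ValueError(
            f"units_per_day must be finite and >= 0, got {units_per_day!r}"
        )
    if units == 0:
        return BehaviorState.NONE
    if units < HIGH_DOSE_THRESHOLD:
        return BehaviorState.LOW
    return BehaviorState.HIGH
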