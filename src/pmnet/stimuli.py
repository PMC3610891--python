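"""The letter-pair stimulus space and trial classification.

Stimuli are pairs of letters from {A, B, C}, one upper-case and one
lower-case, shown left and right of fixation.  The ongoing task is to
report the side of the upper-case letter (Left/Right); the PM task is to
press the PM button instead whenever the same letter appears on both
sides (e.g. "a A").  There are 18 distinct stimuli: 6 targets (3 letters
x 2 case arrangements) and 12 nontargets.

Input-unit ordering is position-major: the six left-position tokens
A, a, B, b, C, c occupy indices 0-5 and the six right-position tokens
indices 6-11, so the stimulus "A c" activates the leftmost (0) and
rightmost (11) input units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache

LETTERS = "ABC"

#: Tokens in within-position order: upper then lower case per letter.
_TOKENS = ["A", "a", "B", "b", "C", "c"]


class Response(enum.Enum):
    """A response emitted by the network (or a timeout non-response)."""

    LEFT = "Left"
    RIGHT = "Right"
    PM = "PM"
    TIMEOUT = "Timeout"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TrialClass(enum.Enum):
    """Exhaustive classification of a (stimulus, response) pair."""

    ONGOING_CORRECT = "ongoing_correct"
    ONGOING_ERROR = "ongoing_error"
    PM_HIT = "pm_hit"
    PM_MISS_CORRECT_ONGOING = "pm_miss_correct_ongoing"
    PM_MISS_WRONG_ONGOING = "pm_miss_wrong_ongoing"
    PM_FALSE_ALARM = "pm_false_alarm"
    TIMEOUT = "timeout"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_pm_miss(self) -> bool:
        return self in (TrialClass.PM_MISS_CORRECT_ONGOING,
                        TrialClass.PM_MISS_WRONG_ONGOING)


def _token_index(token: str, side: str) -> int:
    base = 0 if side == "left" else 6
    return base + _TOKENS.index(token)


@dataclass(frozen=True)
class Stimulus:
    """A letter pair with case assignment, e.g. ``Stimulus("A", "c")``.

    Exactly one of the two tokens must be upper-case.
    """

    left_token: str
    right_token: str

    def __post_init__(self) -> None:
        for token in (self.left_token, self.right_token):
            if token not in _TOKENS:
                raise ValueError(f"invalid token {token!r}")
        if self.left_token.isupper() == self.right_token.isupper():
            raise ValueError(
                f"exactly one token must be upper-case, got "
                f"{self.label!r}")

    @property
    def label(self) -> str:
        """Two-token serialization used in all logs, e.g. ``"A c"``."""
        return f"{self.left_token} {self.right_token}"

    @classmethod
    def from_label(cls, label: str) -> "Stimulus":
        left, right = label.split()
        return cls(left, right)

    @property
    def active_units(self) -> tuple[int, int]:
        """Indices of the two active input units (left, right)."""
        return (_token_index(self.left_token, "left"),
                _token_index(self.right_token, "right"))

    @property
    def is_target(self) -> bool:
        """True iff the same letter appears on both sides."""
        return self.left_token.upper() == self.right_token.upper()

    @property
    def correct_ongoing(self) -> Response:
        """Left if the upper-case letter is on the left, else Right."""
        return Response.LEFT if self.left_token.isupper() else Response.RIGHT

    def __str__(self) -> str:
        return self.label


@lru_cache(maxsize=1)
def _stimulus_tuple() -> tuple[Stimulus, ...]:
    out = []
    for left_letter in LETTERS:
        for right_letter in LETTERS:
            # two case arrangements per letter pair
            out.append(Stimulus(left_letter, right_letter.lower()))
            out.append(Stimulus(left_letter.lower(), right_letter))
    return tuple(out)


def enumerate_stimuli() -> list[Stimulus]:
    """All 18 stimuli in a stable order (6 targets, 12 nontargets)."""
    return list(_stimulus_tuple())


def correct_ongoing(stimulus: Stimulus) -> Response:
    """The correct ongoing response for a stimulus (ignores targetness)."""
    return stimulus.correct_ongoing


def classify_trial(stimulus: Stimulus, result) -> TrialClass:
    """Map a trial outcome onto the exhaustive trial taxonomy.

    ``result`` may be a :class:`~pmnet.network.TrialResult` or a bare
    :class:`Response`.
    """
    response = getattr(result, "response", result)
    if response is Response.TIMEOUT:
        return TrialClass.TIMEOUT
    if stimulus.is_target:
        if response is Response.PM:
            return TrialClass.PM_HIT
        if response is stimulus.correct_ongoing:
            return TrialClass.PM_MISS_CORRECT_ONGOING
        return TrialClass.PM_MISS_WRONG_ONGOING
    if response is Response.PM:
        return TrialClass.PM_FALSE_ALARM
    if response is stimulus.correct_ongoing:
        return TrialClass.ONGOING_CORRECT
    return TrialClass.ONGOING_ERROR
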