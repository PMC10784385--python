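"""State space of the instrument: labels, coding, severity score, dominance.

A *state* is a 6-tuple of levels in {1, 2, 3}, one per attribute in the
fixed order health, social relations, finance & housing, occupation,
security, political & civil rights; it is written as a 6-digit label such
as ``"232332"``.  There are 3**6 = 729 states.  The model coding is
*cumulative* (incremental): per attribute one indicator for level >= 2 and
one for level >= 3, so the level-2 coefficient is the step from level 1 and
the level-3 coefficient is the additional step from level 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterable, Sequence, Union

import numpy as np

#: Attribute names in the fixed instrument order.
ATTRIBUTES = (
    "health",
    "social relations",
    "finance & housing",
    "occupation",
    "security",
    "political & civil rights",
)

N_ATTRIBUTES = len(ATTRIBUTES)
N_LEVELS = 3
#: Number of distinct states (3 ** 6).
N_STATES = N_LEVELS**N_ATTRIBUTES


@dataclass(frozen=True)
class State:
    """An instrument state: one level in {1, 2, 3} per attribute.

    Parameters
    ----------
    levels : tuple of int
        Six levels, attribute order as in :data:`ATTRIBUTES`.
    """

    levels: tuple

    def __post_init__(self) -> None:
        if len(self.levels) != N_ATTRIBUTES:
            raise ValueError(
                f"a state needs {N_ATTRIBUTES} levels, got {len(self.levels)}"
            )
        for attr, lev in zip(ATTRIBUTES, self.levels):
            if not (isinstance(lev, (int, np.integer)) and 1 <= lev <= N_LEVELS):
                raise ValueError(
                    f"invalid level {lev!r} for attribute '{attr}': "
                    f"must be an integer in 1..{N_LEVELS}"
                )
        object.__setattr__(self, "levels", tuple(int(x) for x in self.levels))

    @classmethod
    def from_label(cls, label: str) -> "State":
        """Parse a 6-digit label such as ``"232332"``."""
        label = str(label)
        if len(label) != N_ATTRIBUTES or not label.isdigit():
            raise ValueError(f"state label must be {N_ATTRIBUTES} digits, got {label!r}")
        return cls(tuple(int(c) for c in label))

    @property
    def label(self) -> str:
        return "".join(str(x) for x in self.levels)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


StateLike = Union[State, str, Sequence[int]]


def as_state(state: StateLike) -> State:
    """Coerce a label string, level sequence, or State into a State."""
    if isinstance(state, State):
        return state
    if isinstance(state, str):
        return State.from_label(state)
    return State(tuple(state))


def encode_state(state: StateLike) -> np.ndarray:
    """Cumulative (incremental) main-effects coding of a state.

    Returns a vector of 12 binary indicators, two per attribute in
    instrument order: ``[x2_health, x3_health, x2_social, x3_social, ...]``
    where ``x2 = 1`` iff the level is >= 2 and ``x3 = 1`` iff it is 3.
    The worst state 111111 codes to all zeros and the best state 333333 to
    all ones; ``x3 = 1`` implies ``x2 = 1``.
    """
    s = as_state(state)
    row = np.zeros(2 * N_ATTRIBUTES, dtype=float)
    for i, lev in enumerate(s.levels):
        if lev >= 2:
            row[2 * i] = 1.0
        if lev >= 3:
            row[2 * i + 1] = 1.0
    return row


def design_matrix(states: Iterable[StateLike]) -> np.ndarray:
    """Stack :func:`encode_state` rows for a sequence of states (n x 12)."""
    return np.array([encode_state(s) for s in states], dtype=float)


def lss(state: StateLike) -> int:
    """Level sum score: the sum of the six level digits, in [6, 18].

    A crude severity proxy used for descriptive validity checks.
    """
    return int(sum(as_state(state).levels))


def dominates(s1: StateLike, s2: StateLike) -> bool:
    """True iff ``s1`` dominates ``s2``.

    Dominance holds when every attribute of ``s1`` is at a level at least
    as high as in ``s2`` and at least one is strictly higher, i.e. the
    states form a *dominated pair* with ``s2`` the dominated member.
    """
    a = as_state(s1).levels
    b = as_state(s2).levels
    return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))


@lru_cache(maxsize=1)
def _all_states() -> tuple:
    return tuple(
        State(levels) for levels in product(range(1, N_LEVELS + 1), repeat=N_ATTRIBUTES)
    )


def enumerate_states() -> list:
    """All 729 states in lexicographic label order (111111 first)."""
    return list(_all_states())
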