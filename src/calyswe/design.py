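"""Experimental designs for TTO and DCE elicitation.

Two designs are produced.  For the time trade-off (TTO) tasks, a blocked
D-optimal design for the linear main-effects model (intercept + 12
cumulative indicators) is searched by coordinate exchange; each block is
augmented with the pit state 111111 and a *learning* state that has three
attributes on level 2 and three on level 3, so participants practice on a
state that dominates at least one other state in their block.  For the
discrete choice experiment (DCE), paired choice sets are built from an
orthogonal array for six three-level attributes with a constant
difference-vector generator (Street-style construction), which attains
100% main-effects D-efficiency under the multinomial logit information
matrix.

D-efficiency is reported relative to the continuous (approximate-theory)
D-optimum: for the linear model that optimum is computed by a
Fedorov-Wynn multiplicative algorithm over all 729 candidate states; for
the paired logit design it is the uniform design on pairs differing in
every attribute, certified optimal through the Kiefer-Wolfowitz
equivalence theorem (the maximal directional derivative over all candidate
pairs equals the parameter count).  Determinant ratios are invariant to
nonsingular recoding, so efficiencies do not depend on the coding choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .statespace import (
    N_ATTRIBUTES,
    State,
    as_state,
    design_matrix,
    dominates,
    encode_state,
    enumerate_states,
)

#: The fixed dominated consistency pair shown to every participant:
#: 232332 dominates 222332, so choosing 222332 is an inconsistency.
CONSISTENCY_PAIR = ("222332", "232332")

#: Default learning state: three attributes on level 2, three on level 3.
DEFAULT_LEARNING_STATE = "222333"

PIT_STATE = "111111"

# Classic L18 orthogonal array: 18 runs, up to 7 three-level columns,
# strength 2 (every ordered level pair occurs twice in any two columns).
_L18 = np.array(
    [
        [1, 1, 1, 1, 1, 1, 1],
        [1, 2, 2, 2, 2, 2, 2],
        [1, 3, 3, 3, 3, 3, 3],
        [2, 1, 1, 2, 2, 3, 3],
        [2, 2, 2, 3, 3, 1, 1],
        [2, 3, 3, 1, 1, 2, 2],
        [3, 1, 2, 1, 3, 2, 3],
        [3, 2, 3, 2, 1, 3, 1],
        [3, 3, 1, 3, 2, 1, 2],
        [1, 1, 3, 3, 2, 2, 1],
        [1, 2, 1, 1, 3, 3, 2],
        [1, 3, 2, 2, 1, 1, 3],
        [2, 1, 2, 3, 1, 3, 2],
        [2, 2, 3, 1, 2, 1, 3],
        [2, 3, 1, 2, 3, 2, 1],
        [3, 1, 3, 2, 3, 1, 2],
        [3, 2, 1, 3, 1, 2, 3],
        [3, 3, 2, 1, 2, 3, 1],
    ],
    dtype=int,
)


@dataclass
class TTODesign:
    """A blocked TTO design: per block 3 design states + pit + learning."""

    blocks: List[List[State]]
    d_efficiency: float
    learning_state: State = field(default_factory=lambda: as_state(DEFAULT_LEARNING_STATE))
    pit_state: State = field(default_factory=lambda: as_state(PIT_STATE))
    #: best log-determinant after each exchange sweep (non-decreasing)
    search_trace: List[float] = field(default_factory=list)

    @property
    def design_states(self) -> List[State]:
        """All searched design states (pit and learning excluded)."""
        return [s for block in self.blocks for s in block]

    def block_states(self, block_id: int) -> List[State]:
        """The five TTO states of one block: design states + pit + learning."""
        return list(self.blocks[block_id]) + [self.pit_state, self.learning_state]


@dataclass
class DCEDesign:
    """A paired-comparison DCE design plus the fixed consistency pair."""

    choice_sets: List[Tuple[State, State]]
    d_efficiency: float
    consistency_pair: Tuple[State, State] = field(
        default_factory=lambda: tuple(as_state(s) for s in CONSISTENCY_PAIR)
    )


def _model_matrix(states: Sequence, intercept: bool = True) -> np.ndarray:
    X = design_matrix(states)
    if intercept:
        X = np.column_stack([np.ones(len(X)), X])
    return X


@lru_cache(maxsize=1)
def _linear_continuous_optimum() -> tuple:
    """Continuous D-optimal information matrix for the linear model.

    Fedorov-Wynn multiplicative algorithm over the full 729-state
    candidate set: weights are updated proportionally to the normalized
    prediction variance until the equivalence-theorem bound is met.
    """
    X = _model_matrix(enumerate_states())
    n, p = X.shape
    w = np.full(n, 1.0 / n)
    for _ in range(200_000):
        M = X.T @ (w[:, None] * X)
        var = np.einsum("ij,jk,ik->i", X, np.linalg.inv(M), X)
        if var.max() <= p * (1 + 1e-9):
            break
        w *= var / p
        w /= w.sum()
    M = X.T @ (w[:, None] * X)
    sign, logdet = np.linalg.slogdet(M)
    return M, logdet


def d_efficiency_linear(states: Sequence) -> float:
    """Main-effects D-efficiency (%) of a TTO design.

    The information matrix ``M = X'X / n`` of the intercept +
    12-indicator model is compared with the continuous optimum ``M*``:
    ``100 * (|M| / |M*|) ** (1/p)``.  A singular design scores 0 (with a
    warning).  Invariant to row order and to duplicating the whole design.
    """
    states = list(states)
    X = _model_matrix(states)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} states for the {p}-parameter model, got {n}")
    M = X.T @ X / n
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular information matrix: D-efficiency is 0", stacklevel=2)
        return 0.0
    _, logdet_opt = _linear_continuous_optimum()
    return float(100.0 * np.exp((logdet - logdet_opt) / p))


def _pair_difference(a, b) -> np.ndarray:
    return encode_state(a) - encode_state(b)


def _mnl_information(pairs: Sequence) -> np.ndarray:
    """Null (beta = 0) MNL information matrix of a paired design.

    With two alternatives and equal choice probabilities each set
    contributes ``(1/4) d d'`` with ``d`` the coded difference vector;
    normalized by the number of sets.
    """
    D = np.array([_pair_difference(a, b) for a, b in pairs])
    return D.T @ D / (4.0 * len(pairs))


@lru_cache(maxsize=1)
def _mnl_continuous_optimum() -> tuple:
    """Continuous D-optimum for paired-comparison main effects.

    The uniform design on ordered pairs differing in every attribute.  Its
    information matrix is block diagonal with per-attribute blocks
    ``(1/4) * [[2/3, 1/3], [1/3, 2/3]]`` in cumulative coding.  Optimality
    is certified by :func:`certify_paired_optimum`.
    """
    block = np.array([[2.0, 1.0], [1.0, 2.0]]) / 3.0
    M = np.kron(np.eye(N_ATTRIBUTES), block) / 4.0
    sign, logdet = np.linalg.slogdet(M)
    return M, logdet


def certify_paired_optimum() -> float:
    """Equivalence-theorem certificate for the paired-design optimum.

    Returns the maximum directional derivative ``(1/4) d' M*^{-1} d`` over
    all distinct state pairs; the candidate optimum is D-optimal iff this
    does not exceed the parameter count (12).
    """
    M, _ = _mnl_continuous_optimum()
    Minv = np.linalg.inv(M)
    X = design_matrix(enumerate_states())
    n = len(X)
    best = 0.0
    # max over pairs of quadratic forms of differences; evaluated blockwise
    # to stay within memory at 729 * 728 / 2 candidates.
    for i in range(n - 1):
        D = X[i + 1 :] - X[i]
        vals = np.einsum("ij,jk,ik->i", D, Minv, D) / 4.0
        best = max(best, float(vals.max()))
    return best


def d_efficiency_paired(pairs: Sequence) -> float:
    """Main-effects D-efficiency (%) of a paired DCE design under MNL."""
    M = _mnl_information(pairs)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular information matrix: D-efficiency is 0", stacklevel=2)
        return 0.0
    _, logdet_opt = _mnl_continuous_optimum()
    p = M.shape[0]
    return float(100.0 * np.exp((logdet - logdet_opt) / p))


def _coordinate_exchange(
    n_runs: int,
    rng: np.random.Generator,
    candidates: Sequence[State],
    max_sweeps: int = 50,
) -> tuple:
    """One coordinate-exchange (Fedorov-style) pass from a random start.

    Rows are improved one attribute at a time, keeping the level that
    maximizes the determinant of the normalized information matrix.
    Returns the states and the achieved log-determinant.
    """
    levels_pool = np.array([list(as_state(c).levels) for c in candidates])
    levels = levels_pool[rng.integers(0, len(levels_pool), size=n_runs)].copy()
    excluded = {(1,) * N_ATTRIBUTES, (3,) * N_ATTRIBUTES}

    def logdet_of(lv: np.ndarray) -> float:
        X = _model_matrix([State(tuple(r)) for r in lv])
        sign, ld = np.linalg.slogdet(X.T @ X / len(X))
        return ld if sign > 0 else -np.inf

    best = logdet_of(levels)
    trace = [best]
    for _ in range(max_sweeps):
        improved = False
        for i in range(n_runs):
            for j in range(N_ATTRIBUTES):
                current = levels[i, j]
                for lev in (1, 2, 3):
                    if lev == current:
                        continue
                    trial = levels.copy()
                    trial[i, j] = lev
                    if tuple(trial[i]) in excluded:
                        continue
                    ld = logdet_of(trial)
                    if ld > best + 1e-12:
                        levels, best = trial, ld
                        current = lev
                        improved = True
        trace.append(best)
        if not improved:
            break
    return [State(tuple(r)) for r in levels], best, trace


def generate_tto_design(
    n_blocks: int = 8,
    per_block: int = 3,
    seed: int = 0,
    learning_state=DEFAULT_LEARNING_STATE,
    n_restarts: int = 20,
) -> TTODesign:
    """Search a blocked D-optimal TTO design by coordinate exchange.

    ``n_blocks * per_block`` design states are selected (the pit state
    111111 and the top state 333333 are excluded from the search; the pit
    is appended to every block), then partitioned into blocks and each
    block augmented with the pit and the learning state, so every block
    holds five TTO tasks.  The same seed reproduces the identical design.
    """
    n_runs = n_blocks * per_block
    p = 2 * N_ATTRIBUTES + 1
    if n_runs < p:
        raise ValueError(
            f"{n_blocks} blocks x {per_block} states = {n_runs} runs cannot "
            f"identify the {p}-parameter main-effects model"
        )
    learning = as_state(learning_state)
    if sorted(learning.levels) != [2, 2, 2, 3, 3, 3]:
        raise ValueError(
            "learning state must have exactly three attributes on level 2 "
            f"and three on level 3, got {learning.label}"
        )
    rng = np.random.default_rng(seed)
    candidates = [s for s in enumerate_states() if s.label not in (PIT_STATE, "333333")]
    best_states, best_ld, best_trace = None, -np.inf, []
    for _ in range(n_restarts):
        states, ld, trace = _coordinate_exchange(n_runs, rng, candidates)
        if ld > best_ld:
            best_states, best_ld, best_trace = states, ld, trace
    order = rng.permutation(n_runs)
    blocks = [
        [best_states[order[b * per_block + k]] for k in range(per_block)]
        for b in range(n_blocks)
    ]
    eff = d_efficiency_linear(best_states)
    return TTODesign(blocks=blocks, d_efficiency=eff, learning_state=learning,
                     search_trace=best_trace)


def generate_dce_design(seed: int = 0, generator: Tuple[int, ...] = (1,) * 6) -> DCEDesign:
    """Construct the paired DCE design from an orthogonal array.

    First alternatives are the rows of an L18 orthogonal array restricted
    to six three-level columns; second alternatives add a constant
    difference-vector generator modulo 3 (levels cycling 1 -> 2 -> 3 -> 1),
    so every attribute differs within every choice set.  The fixed
    dominated consistency pair is attached separately.  The construction is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    if len(generator) != N_ATTRIBUTES or any(g % 3 == 0 for g in generator):
        raise ValueError("generator needs 6 components, each nonzero modulo 3")
    first = _L18[:, 1:7]
    second = (first - 1 + np.asarray(generator)) % 3 + 1
    pairs = [
        (State(tuple(a)), State(tuple(b))) for a, b in zip(first, second)
    ]
    eff = d_efficiency_paired(pairs)
    cons = tuple(as_state(s) for s in CONSISTENCY_PAIR)
    assert dominates(cons[1], cons[0])
    return DCEDesign(choice_sets=pairs, d_efficiency=eff, consistency_pair=cons)


def assign_tasks(
    design: TTODesign,
    dce: DCEDesign,
    participant_seed: int,
    block_id: Optional[int] = None,
    n_dce_sampled: int = 5,
) -> dict:
    """Build one participant's task list.

    DCE: ``n_dce_sampled`` choice sets sampled without replacement, shown
    in random order, with the dominated consistency pair inserted at a
    random position (6 DCE tasks by default).  TTO: the participant's block
    with the learning state always first and the remaining four states
    (three design states + pit) shuffled (5 TTO tasks).  Reproducible from
    ``participant_seed``.
    """
    rng = np.random.default_rng(participant_seed)
    n_blocks = len(design.blocks)
    if block_id is None:
        block_id = int(rng.integers(0, n_blocks))
    if not 0 <= block_id < n_blocks:
        raise ValueError(f"block_id {block_id} outside 0..{n_blocks - 1}")

    picked = rng.choice(len(dce.choice_sets), size=n_dce_sampled, replace=False)
    dce_tasks = [
        {"stateA": dce.choice_sets[i][0], "stateB": dce.choice_sets[i][1],
         "is_consistency": False}
        for i in picked
    ]
    pos = int(rng.integers(0, n_dce_sampled + 1))
    dce_tasks.insert(
        pos,
        {"stateA": dce.consistency_pair[0], "stateB": dce.consistency_pair[1],
         "is_consistency": True},
    )

    rest = list(design.blocks[block_id]) + [design.pit_state]
    rng.shuffle(rest)
    tto_tasks = [{"state": design.learning_state, "is_learning": True}] + [
        {"state": s, "is_learning": False} for s in rest
    ]
    return {"block_id": block_id, "dce_tasks": dce_tasks, "tto_tasks": tto_tasks}
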