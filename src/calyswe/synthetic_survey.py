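"""Synthetic survey generation.

The survey data this pipeline analyses are restricted-access, so every
downstream stage is exercised on synthetic surveys that carry the
statistical structure the analysis assumes:

* TTO answers arise from an additive true-weight model with normal noise
  on the latent weight scale, then the iterative year-trading task is
  emulated by rounding the latent weight to the 0.1-step answer grid and
  clamping at the boundaries -- which reproduces the censor clustering at
  0.1 seen in real TTO data (and at 0.2/0.9 for the learning state).
* DCE choices are Bernoulli draws from a logit on the utility difference
  of the two states, scaled by a multiplicative logit scale factor.
* A configurable fraction of participants is *careless*: their TTO answers
  are uniform grid draws and their DCE choices fair coin flips, producing
  dominated-pair inconsistencies that the quality-control stage detects.

Default truth parameters follow the final published hybrid
anchor-scale/censoring model (constant 0.114, the 12 level increments,
linear-model SD 0.302, logit scale factor 5.952), so the generator's
default conditions match the study the pipeline emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DCEDesign, TTODesign, assign_tasks
from .statespace import StateLike, as_state, encode_state

#: Published final-model increments in coding order
#: (health 2, health 3, social 2, social 3, finance 2, finance 3,
#:  occupation 2, occupation 3, security 2, security 3, rights 2, rights 3).
DEFAULT_BETA_TRUE = (
    0.154, 0.078,  # health
    0.108, 0.091,  # social relations
    0.122, 0.040,  # finance & housing
    0.073, 0.021,  # occupation
    0.085, 0.031,  # security
    0.065, 0.021,  # political & civil rights
)

DEFAULT_MU_TRUE = 0.114
DEFAULT_THETA_TRUE = 5.952
DEFAULT_SIGMA_TTO = 0.302


@dataclass
class TrueValueConfig:
    """Generating truth for synthetic surveys.

    ``mu_true`` is the weight of the pit state 111111, ``beta_true`` the
    12 nonnegative level increments in cumulative coding; for an anchored
    truth ``mu_true + sum(beta_true)`` is close to 1.  ``theta_true``
    scales the DCE logit, ``sigma_tto`` is the latent TTO noise SD, and
    ``careless_fraction`` the proportion of disengaged participants.
    """

    mu_true: float = DEFAULT_MU_TRUE
    beta_true: Tuple[float, ...] = DEFAULT_BETA_TRUE
    theta_true: float = DEFAULT_THETA_TRUE
    sigma_tto: float = DEFAULT_SIGMA_TTO
    careless_fraction: float = 0.2
    n_participants: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_true = tuple(float(b) for b in self.beta_true)
        if len(self.beta_true) != 12:
            raise ValueError("beta_true must have 12 increments")
        if any(b < 0 for b in self.beta_true):
            raise ValueError("beta_true increments must be nonnegative")
        if not 0.0 <= self.careless_fraction <= 1.0:
            raise ValueError("careless_fraction must lie in [0, 1]")


def true_weight(state: StateLike, config: TrueValueConfig) -> float:
    """Noiseless additive weight of a state: mu + X . beta."""
    row = encode_state(state)
    return float(config.mu_true + row @ np.asarray(config.beta_true))


def _grid_round(latent: float, lo: float, hi: float) -> float:
    """Round a latent weight half-up to the 0.1 grid and clamp to [lo, hi]."""
    w = math.floor(latent * 10 + 0.5) / 10.0
    return min(max(w, lo), hi)


def iterate_tto_answer(latent: float, lo_years: int = 1, hi_years: int = 10) -> int:
    """Step-by-step emulation of the iterative TTO year trade.

    The participant repeatedly chooses between 10 years in the imperfect
    state (value ``latent``) and ``x`` years at full capability (value
    ``x/10``); a bisection over integer years narrows to the switch point
    and the indifference answer is the closer of the bracketing years
    (ties go up).  Agrees with grid rounding for every latent value; kept
    as an alternative answer engine.
    """
    if latent <= lo_years / 10.0:
        return lo_years
    if latent >= hi_years / 10.0:
        return hi_years
    lo, hi = lo_years, hi_years
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mid / 10.0 <= latent:
            lo = mid
        else:
            hi = mid
    # nearer bracketing year wins, midpoints go up; phrased via the
    # grid criterion so floating-point ties resolve identically
    return lo if latent * 10 + 0.5 < hi else hi


def simulate_tto_answer(
    state: StateLike,
    config: TrueValueConfig,
    is_learning: bool,
    rng: np.random.Generator,
    engine: str = "round",
) -> dict:
    """One TTO answer: latent truth + noise, mapped to the answer grid.

    Non-learning states answer on {0.1, ..., 1.0}; the learning state is
    restricted to {0.2, ..., 0.9}.  Values outside the grid clamp to the
    boundary, producing the censor clustering the Tobit models expect.
    """
    s = as_state(state)
    latent = true_weight(s, config) + rng.normal(0.0, config.sigma_tto)
    lo_years, hi_years = (2, 9) if is_learning else (1, 10)
    if engine == "round":
        w = _grid_round(latent, lo_years / 10.0, hi_years / 10.0)
        x = int(round(w * 10))
    elif engine == "iterate":
        x = iterate_tto_answer(latent, lo_years, hi_years)
        w = x / 10.0
    else:
        raise ValueError(f"unknown answer engine {engine!r}")
    return {
        "state": s.label,
        "x_years": x,
        "w": w,
        "is_learning": bool(is_learning),
    }


def simulate_dce_choice(
    stateA: StateLike,
    stateB: StateLike,
    config: TrueValueConfig,
    rng: np.random.Generator,
) -> dict:
    """One DCE choice: Bernoulli(logistic(theta * (X_A - X_B) . beta))."""
    a, b = as_state(stateA), as_state(stateB)
    if a.levels == b.levels:
        raise ValueError("a choice set needs two distinct states")
    beta = np.asarray(config.beta_true)
    z = config.theta_true * float((encode_state(a) - encode_state(b)) @ beta)
    p = float(expit(z))
    return {
        "stateA": a.label,
        "stateB": b.label,
        "chose_A": bool(rng.random() < p),
    }


def make_careless(
    tto_rows: pd.DataFrame,
    dce_rows: pd.DataFrame,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Replace one participant's answers by disengaged noise.

    TTO answers become uniform draws on the state's answer grid
    ({1..10} years, {2..9} for the learning state); DCE choices become
    fair coin flips.  Other columns are preserved.
    """
    tto = tto_rows.copy()
    dce = dce_rows.copy()
    for idx, row in tto.iterrows():
        lo, hi = (2, 9) if row["is_learning"] else (1, 10)
        x = int(rng.integers(lo, hi + 1))
        tto.loc[idx, "x_years"] = x
        tto.loc[idx, "w"] = x / 10.0
    if len(dce):
        dce["chose_A"] = rng.random(len(dce)) < 0.5
    return tto, dce


def simulate_survey(
    config: TrueValueConfig,
    tto_design: TTODesign,
    dce_design: DCEDesign,
    engine: str = "round",
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a complete synthetic survey.

    Participants are assigned TTO blocks round-robin (balancing the ~equal
    valuations-per-state property of the fielded survey) and receive their
    tasks through :func:`calyswe.design.assign_tasks`: 6 DCE tasks (five
    sampled choice sets plus the dominated consistency pair) and 5 TTO
    tasks (learning state first).  Each participant draws from an RNG
    stream derived from ``(config.seed, participant_id)``, so the tables
    are bit-identical across runs with the same configuration.

    Returns ``(participants, tto, dce)`` data frames.
    """
    if config.n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    n_blocks = len(tto_design.blocks)
    part_rows, tto_rows, dce_rows = [], [], []
    for pid in range(1, config.n_participants + 1):
        rng = np.random.default_rng([config.seed, pid])
        careless = bool(rng.random() < config.careless_fraction)
        block_id = (pid - 1) % n_blocks
        tasks = assign_tasks(
            tto_design, dce_design, participant_seed=int(rng.integers(2**31)),
            block_id=block_id,
        )
        p_tto = []
        for task in tasks["tto_tasks"]:
            row = simulate_tto_answer(
                task["state"], config, task["is_learning"], rng, engine=engine
            )
            row["participant_id"] = pid
            p_tto.append(row)
        p_dce = []
        for task in tasks["dce_tasks"]:
            row = simulate_dce_choice(task["stateA"], task["stateB"], config, rng)
            row["participant_id"] = pid
            row["is_consistency"] = task["is_consistency"]
            p_dce.append(row)
        p_tto = pd.DataFrame(p_tto)
        p_dce = pd.DataFrame(p_dce)
        if careless:
            p_tto, p_dce = make_careless(p_tto, p_dce, rng)
        part_rows.append(
            {"participant_id": pid, "block_id": block_id, "careless": careless}
        )
        tto_rows.append(p_tto)
        dce_rows.append(p_dce)
    participants = pd.DataFrame(part_rows)
    tto = pd.concat(tto_rows, ignore_index=True)[
        ["participant_id", "state", "x_years", "w", "is_learning"]
    ]
    dce = pd.concat(dce_rows, ignore_index=True)[
        ["participant_id", "stateA", "stateB", "chose_A", "is_consistency"]
    ]
    return participants, tto, dce
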