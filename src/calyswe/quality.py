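"""Data-quality control based on dominated-pair inconsistencies.

Within a participant's answered TTO states, a *dominated pair* is an
ordered pair (s1, s2) where s1 is at least as good on every attribute and
strictly better on at least one.  If the corresponding TTO weights
satisfy ``w1 <= w2`` the answer pair is a *weak* inconsistency, and a
*strict* one if ``w1 < w2`` (strict implies weak).  The per-participant
*combined inconsistency severity* (CIS) score summarizes how badly the
dominance orderings are violated; participants with the highest CIS are
excluded (TTO data only -- DCE answers are never excluded).  The DCE side
has its own consistency check: a fixed dominated choice set where picking
the dominated state counts as a failure.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .design import CONSISTENCY_PAIR
from .statespace import as_state, dominates, lss


def find_dominated_pairs(states: Iterable) -> List[Tuple[str, str]]:
    """All ordered dominated pairs among one participant's answered states.

    Returns ``(dominating, dominated)`` label pairs; pit and learning
    states participate like any other state.
    """
    labels = [as_state(s).label for s in states]
    if len(labels) < 2:
        raise ValueError("need at least two answered states")
    return [
        (a, b)
        for a in labels
        for b in labels
        if a != b and dominates(a, b)
    ]


def classify(w1: float, w2: float) -> str:
    """Classify a dominated pair's answers: 'none', 'weak' or 'strict'.

    ``w1`` belongs to the dominating state, ``w2`` to the dominated one.
    Weak: ``w1 <= w2``; strict: ``w1 < w2`` (every strict inconsistency is
    also weak; the returned label is the strongest that applies).
    """
    if not (0.0 <= w1 <= 1.0 and 0.0 <= w2 <= 1.0):
        raise ValueError("weights must lie in [0, 1]")
    if w1 < w2:
        return "strict"
    if w1 == w2:
        return "weak"
    return "none"


def inconsistency_records(tto_answers: pd.DataFrame) -> pd.DataFrame:
    """Classified dominated-pair records for one participant.

    ``tto_answers`` needs columns ``state`` and ``w`` (one row per
    answered state).  Output columns: dominating_state, dominated_state,
    w_dominating, w_dominated, kind.
    """
    w_by_state = dict(zip(tto_answers["state"].astype(str), tto_answers["w"]))
    rows = []
    for s1, s2 in find_dominated_pairs(w_by_state.keys()):
        w1, w2 = float(w_by_state[s1]), float(w_by_state[s2])
        rows.append(
            {
                "dominating_state": s1,
                "dominated_state": s2,
                "w_dominating": w1,
                "w_dominated": w2,
                "kind": classify(w1, w2),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dominating_state",
            "dominated_state",
            "w_dominating",
            "w_dominated",
            "kind",
        ],
    )


def cis_score(records: pd.DataFrame, tie_penalty: float = 0.05,
              kernel: Optional[Callable[[float, float], float]] = None) -> float:
    """Combined inconsistency severity of one participant.

    Sum over weak records of the violation size ``w_dominated -
    w_dominating`` plus ``tie_penalty`` for each exact tie; zero iff there
    is no weak inconsistency, and monotone in both the number and the
    severity of violations.  An alternative severity ``kernel(w1, w2)``
    may replace the default for weak records.
    """
    if len(records) == 0:
        return 0.0
    weak = records[records["kind"].isin(["weak", "strict"])]
    if kernel is not None:
        return float(sum(kernel(r.w_dominating, r.w_dominated) for r in weak.itertuples()))
    severity = (weak["w_dominated"] - weak["w_dominating"]).sum()
    ties = int((records["kind"] == "weak").sum())
    return float(severity + tie_penalty * ties)


def cis_report(tto: pd.DataFrame, tie_penalty: float = 0.05) -> pd.DataFrame:
    """Per-participant CIS table: cis, n_weak, n_strict."""
    rows = []
    for pid, grp in tto.groupby("participant_id"):
        rec = inconsistency_records(grp)
        rows.append(
            {
                "participant_id": pid,
                "cis": cis_score(rec, tie_penalty=tie_penalty),
                "n_weak": int(rec["kind"].isin(["weak", "strict"]).sum()),
                "n_strict": int((rec["kind"] == "strict").sum()),
            }
        )
    return pd.DataFrame(rows)


def exclude_by_cis(cis_reports: pd.DataFrame, fraction: float = 0.2) -> pd.DataFrame:
    """Flag the top-CIS fraction of participants for TTO exclusion.

    Removes the ``ceil(fraction * n)`` participants with the highest CIS;
    ties are broken by participant id (higher ids removed first), so the
    rule is fully deterministic.  Returns the table with an ``excluded``
    flag added.  DCE data are never excluded.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = cis_reports.copy()
    n_excl = math.ceil(fraction * len(out))
    order = out.sort_values(
        ["cis", "participant_id"], ascending=[False, False], kind="mergesort"
    )
    excluded_ids = set(order["participant_id"].head(n_excl))
    out["excluded"] = out["participant_id"].isin(excluded_ids)
    return out


def apply_exclusion(tto: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Drop the TTO rows of participants flagged ``excluded``."""
    keep = set(report.loc[~report["excluded"], "participant_id"])
    return tto[tto["participant_id"].isin(keep)].reset_index(drop=True)


def dce_consistency_failures(dce: pd.DataFrame) -> Tuple[pd.DataFrame, float]:
    """Per-participant DCE consistency flags and the failure proportion.

    A participant fails by choosing the dominated member of the fixed
    consistency pair.  Participants without a consistency-pair answer are
    flagged missing (NaN) and not counted as failures; the returned
    proportion is over participants with an answer.
    """
    cons = dce[dce["is_consistency"].astype(bool)]
    flags = []
    for pid in dce["participant_id"].unique():
        mine = cons[cons["participant_id"] == pid]
        if len(mine) == 0:
            flags.append({"participant_id": pid, "failed": np.nan})
            continue
        row = mine.iloc[0]
        a, b = str(row["stateA"]), str(row["stateB"])
        dominated = a if dominates(b, a) else b
        chosen = a if bool(row["chose_A"]) else b
        flags.append({"participant_id": pid, "failed": chosen == dominated})
    table = pd.DataFrame(flags)
    answered = table["failed"].dropna()
    proportion = float(answered.mean()) if len(answered) else float("nan")
    return table, proportion


def validity_summaries(tto: pd.DataFrame, dce: pd.DataFrame) -> dict:
    """Descriptive validity tables.

    ``tto_by_state``: per state the mean and SD of answered weights with
    the level sum score (LSS) -- engaged data show a positive relation.
    ``dce_by_pair``: per choice set the proportion choosing the first
    state and the LSS difference (first minus second).
    """
    tto_by_state = (
        tto.groupby("state")["w"]
        .agg(mean_w="mean", sd_w="std", n="size")
        .reset_index()
    )
    tto_by_state["lss"] = tto_by_state["state"].map(lss)

    dce_by_pair = (
        dce.groupby(["stateA", "stateB"])["chose_A"]
        .agg(prop_A="mean", n="size")
        .reset_index()
    )
    dce_by_pair["lss_diff"] = dce_by_pair["stateA"].map(lss) - dce_by_pair[
        "stateB"
    ].map(lss)
    return {"tto_by_state": tto_by_state, "dce_by_pair": dce_by_pair}


def quality_report(
    tto: pd.DataFrame,
    dce: pd.DataFrame,
    exclude_fraction: float = 0.2,
    tie_penalty: float = 0.05,
) -> dict:
    """Full quality pass: CIS report with exclusions, DCE check, summaries."""
    report = exclude_by_cis(cis_report(tto, tie_penalty), exclude_fraction)
    flags, failure_proportion = dce_consistency_failures(dce)
    return {
        "cis_report": report,
        "dce_flags": flags,
        "dce_failure_proportion": failure_proportion,
        "summaries": validity_summaries(tto, dce),
        "tto_included": apply_exclusion(tto, report),
    }
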