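"""Model comparison: fidelity, cross-validation, ranking, sensitivity.

Candidate models are compared on five metrics: k-fold DCE accuracy,
k-fold MAE of predicted TTO answers, the distance of the predicted weight
of 333333 from 1, *logit fidelity* (agreement of a model's normalized
increment shares with a reference DCE-only logit's shares, in percentage
points), and the mean 95% credible-interval width of the 729 weights
relative to the range they cover.  Per metric a percentile score with the
appropriate orientation is computed and models are ordered by their mean
rank.  A Breusch-Pagan test screens the TTO residuals for
heteroskedasticity, and a sensitivity analysis refits the selected model
at increasing CIS-based inclusion fractions of the TTO data.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.diagnostic import het_breuschpagan

from .quality import apply_exclusion, cis_report
from .statespace import design_matrix
from .valuation_models import CapabilityValuationModel, ModelSpec, fit

#: Metric orientations: +1 if larger is better, -1 if smaller is better.
METRIC_ORIENTATION = {
    "kfold_dce_accuracy": +1,
    "kfold_mae": -1,
    "dist_333333_to_1": -1,
    "logit_fidelity": -1,
    "mean_ci_width_relative_to_range": -1,
}


def logit_fidelity(
    comparator_coeffs: Sequence[float], reference_logit_coeffs: Sequence[float]
) -> float:
    """Sum of absolute differences of normalized increment shares (in %).

    Both 12-vectors of level increments (no constants) are normalized so
    that their sum corresponds to 100%, then the absolute share
    differences are summed.  Zero iff the shares coincide; invariant to
    rescaling either vector.
    """
    bc = np.asarray(comparator_coeffs, dtype=float)
    br = np.asarray(reference_logit_coeffs, dtype=float)
    if bc.shape != br.shape:
        raise ValueError("coefficient vectors must have equal length")
    if bc.sum() <= 0 or br.sum() <= 0:
        raise ValueError("coefficient sums must be positive to normalize")
    return float(np.abs(100 * bc / bc.sum() - 100 * br / br.sum()).sum())


def _participant_folds(pids: np.ndarray, k: int, seed: int) -> List[np.ndarray]:
    unique = np.unique(pids)
    rng = np.random.default_rng(seed)
    rng.shuffle(unique)
    return [f for f in np.array_split(unique, k)]


def kfold_cv(
    tto_data: pd.DataFrame,
    dce_data: Optional[pd.DataFrame],
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    method: str = "map",
    **fit_kwargs,
) -> dict:
    """Participant-level k-fold cross-validation.

    Participants are partitioned into ``k`` folds; each fold is held out
    once while the model refits on the rest.  Reported: DCE accuracy (a
    held-out choice counts correct when the predicted probability sides
    with the observed choice; a predicted probability of exactly 0.5
    counts half), and ME/MAE/MSE of predicted vs. observed held-out TTO
    answers on the answer scale.  Folds default to the MAP fast path.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    pids = tto_data["participant_id"].to_numpy()
    if len(np.unique(pids)) < k:
        raise ValueError("need at least k participants")
    folds = _participant_folds(pids, k, seed)
    acc, me, mae, mse = [], [], [], []
    for fold in folds:
        test_ids = set(fold)
        tto_tr = tto_data[~tto_data["participant_id"].isin(test_ids)]
        tto_te = tto_data[tto_data["participant_id"].isin(test_ids)]
        dce_tr = dce_te = None
        if spec.use_dce:
            dce_tr = dce_data[~dce_data["participant_id"].isin(test_ids)]
            dce_te = dce_data[dce_data["participant_id"].isin(test_ids)]
        model = fit(spec, tto_tr, dce_tr, method=method, seed=seed, **fit_kwargs)
        pred_w = model.predict_tto_mean(tto_te["state"].astype(str))
        err = pred_w - tto_te["w"].to_numpy(dtype=float)
        me.append(float(err.mean()))
        mae.append(float(np.abs(err).mean()))
        mse.append(float((err**2).mean()))
        if spec.use_dce and len(dce_te):
            p = model.predict_dce_prob(
                dce_te["stateA"].astype(str), dce_te["stateB"].astype(str)
            )
            chose = dce_te["chose_A"].to_numpy(dtype=bool)
            correct = np.where(
                p == 0.5, 0.5, (p > 0.5) == chose
            ).astype(float)
            acc.append(float(correct.mean()))
    out = {
        "kfold_me": float(np.mean(me)),
        "kfold_mae": float(np.mean(mae)),
        "kfold_mse": float(np.mean(mse)),
        "folds": folds,
    }
    if acc:
        out["kfold_dce_accuracy"] = float(100.0 * np.mean(acc))
    return out


def breusch_pagan(residuals: Sequence[float], design_rows: np.ndarray) -> tuple:
    """Breusch-Pagan LM test of the residuals against the design rows.

    The statistic is ``n R^2`` of the auxiliary regression of squared
    residuals on the 12 indicators, chi-squared with 12 df under
    homoskedasticity.  Returns ``(lm_statistic, p_value)``.
    """
    X = np.atleast_2d(np.asarray(design_rows, dtype=float))
    resid = np.asarray(residuals, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design: indicator columns are collinear")
    exog = np.column_stack([np.ones(len(X)), X])
    lm, p, _, _ = het_breuschpagan(resid, exog)
    return float(lm), float(p)


def model_metrics(
    model: CapabilityValuationModel,
    tto_data: pd.DataFrame,
    dce_data: Optional[pd.DataFrame],
    reference_logit_coeffs: Sequence[float],
    k: int = 10,
    seed: int = 0,
    cv_method: str = "map",
) -> dict:
    """All five comparison metrics for one fitted model."""
    spec = model.spec_
    cv = kfold_cv(tto_data, dce_data, spec, k=k, seed=seed, method=cv_method)
    tariff = model.predict_weights()
    w333333 = float(tariff.loc[tariff["state"] == "333333", "weight"].iloc[0])
    widths = tariff["ci_high"] - tariff["ci_low"]
    w_range = tariff["weight"].max() - tariff["weight"].min()
    return {
        "kfold_dce_accuracy": cv.get("kfold_dce_accuracy", 0.0),
        "kfold_me": cv["kfold_me"],
        "kfold_mae": cv["kfold_mae"],
        "kfold_mse": cv["kfold_mse"],
        "dist_333333_to_1": abs(w333333 - 1.0),
        "logit_fidelity": logit_fidelity(model.params_.beta, reference_logit_coeffs),
        "mean_ci_width_relative_to_range": float(widths.mean() / w_range),
    }


def rank_models(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Percentile scores and mean ranks over the five comparison metrics.

    Expects one row per model (index or column ``model``) with all five
    metric columns present.  Per metric a percentile score in [0, 100] is
    assigned (100 = best under the metric's orientation, ties averaged)
    and a rank (1 = best); models are sorted by mean rank.
    """
    if len(metric_table) < 2:
        raise ValueError("need at least two models to rank")
    missing = [m for m in METRIC_ORIENTATION if m not in metric_table.columns]
    if missing:
        raise ValueError(f"missing metric column(s): {', '.join(missing)}")
    out = metric_table.copy()
    n = len(out)
    ranks = []
    for metric, orientation in METRIC_ORIENTATION.items():
        vals = orientation * out[metric].to_numpy(dtype=float)
        r = rankdata(-vals, method="average")  # 1 = best
        ranks.append(r)
        out[f"percentile_{metric}"] = 100.0 * (n - r) / (n - 1)
    out["mean_rank"] = np.mean(ranks, axis=0)
    return out.sort_values("mean_rank", kind="mergesort")


def sensitivity_inclusion(
    tto_data: pd.DataFrame,
    dce_data: Optional[pd.DataFrame],
    spec: ModelSpec,
    fractions: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    seed: int = 0,
    method: str = "map",
    k: Optional[int] = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit at increasing CIS-based TTO inclusion fractions.

    For each fraction the best-consistency participants (ascending CIS)
    are retained and the spec refitted; reported per fraction: the
    coefficient posterior means, the mean credible-interval width of the
    weights relative to their range, and (if ``k`` is given) the k-fold
    MAE relative to the range.  Fraction 1.0 reproduces the unfiltered
    fit.  DCE data are never filtered.
    """
    report = cis_report(tto_data)
    order = report.sort_values(["cis", "participant_id"], kind="mergesort")
    n = len(order)
    rows = []
    for frac in fractions:
        n_keep = int(np.ceil(frac * n))
        keep = set(order["participant_id"].head(n_keep))
        sub = tto_data[tto_data["participant_id"].isin(keep)]
        model = fit(spec, sub, dce_data, method=method, seed=seed, **fit_kwargs)
        tariff = model.predict_weights()
        w_range = tariff["weight"].max() - tariff["weight"].min()
        row = {
            "fraction": frac,
            "n_participants": n_keep,
            "mu": model.params_.mu,
            "mean_ci_width_relative_to_range": float(
                (tariff["ci_high"] - tariff["ci_low"]).mean() / w_range
            ),
        }
        for i, b in enumerate(model.params_.beta):
            row[f"beta[{i}]"] = float(b)
        if k is not None:
            cv = kfold_cv(sub, dce_data, spec, k=k, seed=seed, method=method)
            row["kfold_mae_relative_to_range"] = cv["kfold_mae"] / w_range
        rows.append(row)
    return pd.DataFrame(rows)
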