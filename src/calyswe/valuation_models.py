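"""The TTO/DCE valuation model family.

The core model is additive in the cumulative level coding: the latent TTO
weight of state ``i`` is ``y_i ~ mu + X_i beta + eps_i`` with ``mu, beta >=
0``, so dominance monotonicity of predicted weights is structural.  Model
*features* extend this base:

* **hybrid** -- a conditional-logit DCE component sharing ``beta``:
  ``P(choose A) = logistic(theta (X_A - X_B) beta)`` with a multiplicative
  logit scale factor ``theta``.
* **censoring** -- answers sit on a bounded 0.1-step grid, so boundary
  answers are treated as Tobit-censored: left at 0.1 and right at 1.0
  (0.2 and 0.9 for the learning state).
* **heteroskedasticity** -- the residual SD's logarithm gets the same
  parametrization as the mean: ``log sd_i = mu_H + X_i beta_H``,
  ``beta_H >= 0``.
* **varying intercept** -- a per-participant normal offset with SD
  ``omega`` (non-centered parametrization).
* **anchoring** -- either the *discapability* coding ``1 - y_i ~ X' beta``
  without constant (forcing the best state 333333 to weight 1), or an
  *anchor scale* ``y_i ~ mu + X beta s + eps`` combined with a tight
  pseudo-observation ``1 ~ mu + x_333333 beta`` (SD 0.01) that pins the
  anchored coefficients while ``s`` absorbs the TTO scale compression; the
  scale applies only to the TTO side, never to the DCE logit.

Fitting is Bayesian: weakly informative positivity-respecting priors
(half-normal(1) on ``beta``, ``beta_H``, ``sigma``, ``omega`` and ``s``,
half-normal(10) on ``theta``, standard normal truncated at 0 on ``mu``)
and affine-invariant ensemble MCMC on log-transformed positive
parameters, with split-chain R-hat and effective-sample-size gates.  A
maximum-a-posteriori path with a Laplace approximation serves as a fast
alternative; the full posterior is the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, log_expit
from sklearn.base import BaseEstimator

from .statespace import design_matrix, enumerate_states

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# specification and parameters


@dataclass(frozen=True)
class ModelSpec:
    """Feature flags selecting a member of the model family."""

    use_dce: bool = True
    coding: str = "attainment"
    censoring: bool = True
    heteroskedastic: bool = False
    varying_intercept: bool = False
    anchor_scale: bool = True
    anchor_prior_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.coding not in ("attainment", "discapability"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.coding == "discapability" and self.anchor_scale:
            raise ValueError(
                "discapability coding already anchors 333333 to 1; "
                "it cannot be combined with the anchor scale"
            )
        if self.anchor_prior_sd <= 0:
            raise ValueError("anchor_prior_sd must be positive")

    @property
    def has_constant(self) -> bool:
        return self.coding == "attainment"


@dataclass
class ModelParams:
    """A point in parameter space for a given :class:`ModelSpec`."""

    beta: np.ndarray
    mu: float = 0.0
    sigma: float = 1.0
    theta: float = 1.0
    s: float = 1.0
    mu_H: float = 0.0
    beta_H: Optional[np.ndarray] = None
    omega: float = 0.0
    b: Optional[np.ndarray] = None  # raw (unit-scale) participant offsets

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (12,):
            raise ValueError("beta must hold 12 increments")
        if self.beta_H is not None:
            self.beta_H = np.asarray(self.beta_H, dtype=float)

    def validate(self, spec: ModelSpec) -> None:
        if np.any(self.beta < 0) or self.mu < 0:
            raise ValueError("mu and beta must be nonnegative")
        if self.sigma <= 0 and not spec.heteroskedastic:
            raise ValueError("sigma must be positive")
        if spec.heteroskedastic:
            if self.beta_H is None or self.beta_H.shape != (12,):
                raise ValueError("heteroskedastic spec needs 12 beta_H increments")
            if np.any(self.beta_H < 0):
                raise ValueError("beta_H must be nonnegative")
        if spec.use_dce and self.theta <= 0:
            raise ValueError("theta must be positive")
        if spec.anchor_scale and self.s <= 0:
            raise ValueError("anchor scale s must be positive")
        if spec.varying_intercept and self.omega <= 0:
            raise ValueError("omega must be positive")


def _discapability_matrix(X: np.ndarray) -> np.ndarray:
    """Attainment coding -> cumulative decrement (discapability) coding.

    Per attribute the pair (x2, x3) maps to (1 - x3, 1 - x2): one
    indicator for not reaching level 3 and one for sitting at level 1, so
    333333 codes to the zero row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty_like(X)
    out[:, 0::2] = 1.0 - X[:, 1::2]
    out[:, 1::2] = 1.0 - X[:, 0::2]
    return out


def _weight_terms(spec: ModelSpec, X: np.ndarray) -> tuple:
    """(const, Xw) with predicted weight = const + Xw @ beta (unscaled)."""
    if spec.coding == "attainment":
        return None, np.atleast_2d(X)  # const = mu
    return 1.0, -_discapability_matrix(X)


def tto_mean(params: ModelParams, row: np.ndarray, spec: ModelSpec) -> float:
    """Latent mean TTO weight of one design row under the spec.

    Attainment: ``mu + X beta`` (times ``s`` on the level part for anchor
    models, matching the answer scale); discapability: ``1 - X' beta``
    with the decrement coding, no constant.
    """
    params.validate(spec)
    row = np.asarray(row, dtype=float).reshape(1, -1)
    const, Xw = _weight_terms(spec, row)
    scale = params.s if spec.anchor_scale else 1.0
    base = params.mu if const is None else const
    return float(base + scale * (Xw @ params.beta)[0])


def _tto_arrays(tto_data: pd.DataFrame) -> dict:
    X = design_matrix(tto_data["state"].astype(str))
    learning = tto_data["is_learning"].to_numpy(dtype=bool)
    lo = np.where(learning, 0.2, 0.1)
    hi = np.where(learning, 0.9, 1.0)
    w = tto_data["w"].to_numpy(dtype=float)
    pid = tto_data["participant_id"].to_numpy()
    _, pidx = np.unique(pid, return_inverse=True)
    # censoring status is a data property; precompute the masks once
    at_lo = np.isclose(w, lo)
    at_hi = np.isclose(w, hi)
    return {
        "X": X, "w": w, "lo": lo, "hi": hi, "pidx": pidx,
        "at_lo": at_lo, "at_hi": at_hi, "interior": ~(at_lo | at_hi),
    }


def _tto_loglik_batch(P: dict, arr: dict, spec: ModelSpec) -> np.ndarray:
    """Vectorized TTO log-likelihood for a batch of parameter points.

    ``P`` holds parameter arrays with a leading batch axis (``beta`` is
    (m, 12), scalars are (m,)); returns one log-likelihood per point.
    """
    X, w = arr["X"], arr["w"]
    const, Xw = _weight_terms(spec, X)
    scale = P["s"][:, None] if spec.anchor_scale else 1.0
    base = P["mu"][:, None] if const is None else const
    mean = base + scale * (P["beta"] @ Xw.T)  # (m, n)
    if spec.varying_intercept:
        mean = mean + P["omega"][:, None] * P["b"][:, arr["pidx"]]
    if spec.heteroskedastic:
        sd = np.exp(P["mu_H"][:, None] + P["beta_H"] @ X.T)
    else:
        sd = np.broadcast_to(P["sigma"][:, None], mean.shape)
    if np.any(sd <= 0):
        raise ValueError("residual sd must be positive")
    z = (w[None, :] - mean) / sd
    if not spec.censoring:
        return np.sum(-0.5 * z**2 - np.log(sd) - _LOG_SQRT_2PI, axis=1)
    at_lo, at_hi, interior = arr["at_lo"], arr["at_hi"], arr["interior"]
    ll = np.sum(
        -0.5 * z[:, interior] ** 2 - np.log(sd[:, interior]) - _LOG_SQRT_2PI, axis=1
    )
    ll = ll + np.sum(
        log_ndtr((arr["lo"][at_lo][None, :] - mean[:, at_lo]) / sd[:, at_lo]), axis=1
    )
    ll = ll + np.sum(
        log_ndtr(-(arr["hi"][at_hi][None, :] - mean[:, at_hi]) / sd[:, at_hi]), axis=1
    )
    return ll


def _params_to_batch(params: ModelParams) -> dict:
    return {
        "mu": np.array([params.mu]),
        "beta": params.beta[None, :],
        "sigma": np.array([params.sigma]),
        "theta": np.array([params.theta]),
        "s": np.array([params.s]),
        "mu_H": np.array([params.mu_H]),
        "beta_H": None if params.beta_H is None else params.beta_H[None, :],
        "omega": np.array([params.omega]),
        "b": None if params.b is None else params.b[None, :],
    }


def _tto_loglik_arrays(params: ModelParams, arr: dict, spec: ModelSpec) -> float:
    return float(_tto_loglik_batch(_params_to_batch(params), arr, spec)[0])


def tto_loglik(params: ModelParams, tto_data: pd.DataFrame, spec: ModelSpec) -> float:
    """Censored-normal (Tobit) TTO log-likelihood.

    Interior grid answers contribute the normal density; with censoring
    on, answers at the grid boundary contribute the corresponding tail
    mass, with bounds (0.1, 1) or (0.2, 0.9) for the learning state
    (boundary answers are detected by equality with the bound).
    """
    params.validate(spec)
    return _tto_loglik_arrays(params, _tto_arrays(tto_data), spec)


def _dce_arrays(dce_data: pd.DataFrame, spec: ModelSpec) -> dict:
    XA = design_matrix(dce_data["stateA"].astype(str))
    XB = design_matrix(dce_data["stateB"].astype(str))
    _, TA = _weight_terms(spec, XA)
    _, TB = _weight_terms(spec, XB)
    sign = np.where(dce_data["chose_A"].to_numpy(dtype=bool), 1.0, -1.0)
    return {"D": TA - TB, "sign": sign}


def _dce_loglik_batch(P: dict, arr: dict) -> np.ndarray:
    z = P["theta"][:, None] * (P["beta"] @ arr["D"].T)
    return np.sum(log_expit(arr["sign"][None, :] * z), axis=1)


def _dce_loglik_arrays(params: ModelParams, arr: dict) -> float:
    return float(_dce_loglik_batch(_params_to_batch(params), arr)[0])


def dce_loglik(
    params: ModelParams,
    dce_data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
) -> float:
    """Bernoulli log-likelihood of the DCE choices.

    ``P(choose A) = logistic(theta * (value_A - value_B))`` where the
    values use the shared increments ``beta`` without constant; the anchor
    scale ``s`` never enters the DCE side.
    """
    params.validate(spec)
    return _dce_loglik_arrays(params, _dce_arrays(dce_data, spec))


def anchor_term(params: ModelParams, anchor_prior_sd: float = 0.01) -> float:
    """Log-density of the anchoring pseudo-observation.

    A normal observation of 1 at mean ``mu + sum(beta)`` (the unscaled
    predicted weight of 333333) with a very tight SD, pinning the anchored
    coefficients to the [0, 1] scale.
    """
    m = params.mu + float(np.sum(params.beta))
    z = (1.0 - m) / anchor_prior_sd
    return float(-0.5 * z**2 - np.log(anchor_prior_sd) - _LOG_SQRT_2PI)


# ---------------------------------------------------------------------------
# parameter vector <-> transform machinery


class _ParamLayout:
    """Maps the unconstrained sampling vector to :class:`ModelParams`.

    Positive parameters are sampled on the log scale (with the Jacobian
    added to the posterior); ``mu_H`` and the raw participant offsets stay
    linear.
    """

    def __init__(self, spec: ModelSpec, n_participants: int = 0):
        self.spec = spec
        self.n_participants = n_participants
        names: list = []
        logs: list = []
        if spec.has_constant:
            names.append("mu"); logs.append(True)
        names += [f"beta[{i}]" for i in range(12)]; logs += [True] * 12
        if not spec.heteroskedastic:
            names.append("sigma"); logs.append(True)
        if spec.use_dce:
            names.append("theta"); logs.append(True)
        if spec.anchor_scale:
            names.append("s"); logs.append(True)
        if spec.heteroskedastic:
            names.append("mu_H"); logs.append(False)
            names += [f"beta_H[{i}]" for i in range(12)]; logs += [True] * 12
        if spec.varying_intercept:
            names.append("omega"); logs.append(True)
            names += [f"b[{i}]" for i in range(n_participants)]
            logs += [False] * n_participants
        self.names = names
        self.is_log = np.array(logs)
        self.ndim = len(names)
        self._idx = {n: i for i, n in enumerate(names)}

    def constrain(self, z: np.ndarray) -> np.ndarray:
        x = np.array(z, dtype=float)
        x[self.is_log] = np.exp(x[self.is_log])
        return x

    def to_batch(self, Z: np.ndarray) -> dict:
        """Parameter arrays (leading batch axis) from unconstrained points."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        X = Z.copy()
        X[:, self.is_log] = np.exp(X[:, self.is_log])
        m = len(Z)
        idx = self._idx
        col = lambda n: X[:, idx[n]]
        i0 = idx["beta[0]"]
        P = {
            "beta": X[:, i0 : i0 + 12],
            "mu": col("mu") if "mu" in idx else np.zeros(m),
            "sigma": col("sigma") if "sigma" in idx else np.ones(m),
            "theta": col("theta") if "theta" in idx else np.ones(m),
            "s": col("s") if "s" in idx else np.ones(m),
            "mu_H": col("mu_H") if "mu_H" in idx else np.zeros(m),
            "beta_H": None,
            "omega": None,
            "b": None,
        }
        if self.spec.heteroskedastic:
            j0 = idx["beta_H[0]"]
            P["beta_H"] = X[:, j0 : j0 + 12]
        if self.spec.varying_intercept:
            P["omega"] = col("omega")
            k0 = idx["b[0]"]
            P["b"] = X[:, k0 : k0 + self.n_participants]
        return P

    def to_params(self, z: np.ndarray) -> ModelParams:
        x = self.constrain(z)
        g = lambda n: x[self._idx[n]]
        beta = x[self._idx["beta[0]"] : self._idx["beta[0]"] + 12]
        kw = {"beta": beta}
        if self.spec.has_constant:
            kw["mu"] = g("mu")
        if not self.spec.heteroskedastic:
            kw["sigma"] = g("sigma")
        if self.spec.use_dce:
            kw["theta"] = g("theta")
        if self.spec.anchor_scale:
            kw["s"] = g("s")
        if self.spec.heteroskedastic:
            kw["mu_H"] = g("mu_H")
            i0 = self._idx["beta_H[0]"]
            kw["beta_H"] = x[i0 : i0 + 12]
        if self.spec.varying_intercept:
            kw["omega"] = g("omega")
            i0 = self._idx["b[0]"]
            kw["b"] = x[i0 : i0 + self.n_participants]
        return ModelParams(**kw)

    def initial_z(self) -> np.ndarray:
        """Heuristic starting point in the unconstrained space."""
        z = np.zeros(self.ndim)
        for i, name in enumerate(self.names):
            if name.startswith("beta_H"):
                z[i] = np.log(0.05)
            elif name.startswith("beta"):
                z[i] = np.log(0.07)
            elif name == "mu":
                z[i] = np.log(0.2)
            elif name == "sigma":
                z[i] = np.log(0.3)
            elif name == "theta":
                z[i] = np.log(5.0)
            elif name in ("s", "omega"):
                z[i] = np.log(0.5) if name == "s" else np.log(0.1)
            elif name == "mu_H":
                z[i] = np.log(0.3)
            else:  # b[i]
                z[i] = 0.0
        return z


# ---------------------------------------------------------------------------
# the estimator


class CapabilityValuationModel(BaseEstimator):
    """Bayesian TTO/DCE valuation model (scikit-learn style estimator).

    Parameters mirror :class:`ModelSpec`; ``method`` selects full MCMC
    (``"mcmc"``, the reference) or a MAP + Laplace fast path (``"map"``).
    After :meth:`fit`, fitted attributes carry the posterior summary
    (``summary_``), posterior-mean parameters (``params_``), convergence
    flag (``converged_``) and draws (``samples_``).

    Examples
    --------
    >>> model = CapabilityValuationModel(method="map").fit(tto, dce)
    >>> tariff = model.predict_weights()            # doctest: +SKIP
    """

    def __init__(
        self,
        use_dce: bool = True,
        coding: str = "attainment",
        censoring: bool = True,
        heteroskedastic: bool = False,
        varying_intercept: bool = False,
        anchor_scale: bool = True,
        anchor_prior_sd: float = 0.01,
        method: str = "mcmc",
        n_walkers: Optional[int] = None,
        n_burn: int = 12000,
        n_steps: int = 10000,
        n_laplace_draws: int = 4000,
        rhat_max: float = 1.01,
        ess_min: float = 400.0,
        random_state: int = 0,
    ):
        self.use_dce = use_dce
        self.coding = coding
        self.censoring = censoring
        self.heteroskedastic = heteroskedastic
        self.varying_intercept = varying_intercept
        self.anchor_scale = anchor_scale
        self.anchor_prior_sd = anchor_prior_sd
        self.method = method
        self.n_walkers = n_walkers
        self.n_burn = n_burn
        self.n_steps = n_steps
        self.n_laplace_draws = n_laplace_draws
        self.rhat_max = rhat_max
        self.ess_min = ess_min
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            use_dce=self.use_dce,
            coding=self.coding,
            censoring=self.censoring,
            heteroskedastic=self.heteroskedastic,
            varying_intercept=self.varying_intercept,
            anchor_scale=self.anchor_scale,
            anchor_prior_sd=self.anchor_prior_sd,
        )

    def _log_posterior_batch(self, Z: np.ndarray) -> np.ndarray:
        layout = self._layout_
        spec = layout.spec
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        ok = np.all(np.abs(Z) <= 50, axis=1)
        out = np.full(len(Z), -np.inf)
        if not ok.any():
            return out
        Zok = Z[ok]
        P = layout.to_batch(Zok)
        # weakly informative positivity-respecting priors
        lp = -0.5 * np.sum(P["beta"] ** 2, axis=1)
        if spec.has_constant:
            lp += -0.5 * P["mu"] ** 2
        if not spec.heteroskedastic:
            lp += -0.5 * P["sigma"] ** 2
        if spec.use_dce:
            lp += -0.5 * (P["theta"] / 10.0) ** 2
        if spec.anchor_scale:
            lp += -0.5 * P["s"] ** 2
        if spec.heteroskedastic:
            lp += -0.5 * P["mu_H"] ** 2 - 0.5 * np.sum(P["beta_H"] ** 2, axis=1)
        if spec.varying_intercept:
            lp += -0.5 * P["omega"] ** 2 - 0.5 * np.sum(P["b"] ** 2, axis=1)
        lp += np.sum(Zok[:, layout.is_log], axis=1)  # log-Jacobian
        lp += _tto_loglik_batch(P, self._tto_arr_, spec)
        if spec.use_dce:
            lp += _dce_loglik_batch(P, self._dce_arr_)
        if spec.anchor_scale:
            m = P["mu"] + np.sum(P["beta"], axis=1)
            zs = (1.0 - m) / spec.anchor_prior_sd
            lp += -0.5 * zs**2 - np.log(spec.anchor_prior_sd) - _LOG_SQRT_2PI
        lp[~np.isfinite(lp)] = -np.inf
        out[ok] = lp
        return out

    def _log_posterior(self, z: np.ndarray) -> float:
        return float(self._log_posterior_batch(z[None, :])[0])

    def _map_estimate(self) -> optimize.OptimizeResult:
        neg = lambda z: -self._log_posterior(z)
        layout = self._layout_
        z0 = layout.initial_z()
        # bounds keep line searches away from degenerate plateaus
        bounds = [(-14.0, 4.0) if lg else (-20.0, 20.0) for lg in layout.is_log]
        res = optimize.minimize(neg, z0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 4000, "maxfun": 200_000})
        return res

    def _fd_hessian(self, z: np.ndarray, h: float = 5e-3) -> np.ndarray:
        f = self._log_posterior
        n = len(z)
        H = np.zeros((n, n))
        f0 = f(z)
        for i in range(n):
            zp = z.copy(); zp[i] += h
            zm = z.copy(); zm[i] -= h
            H[i, i] = (f(zp) - 2 * f0 + f(zm)) / (h * h)
            for j in range(i + 1, n):
                zpp = z.copy(); zpp[i] += h; zpp[j] += h
                zpm = z.copy(); zpm[i] += h; zpm[j] -= h
                zmp = z.copy(); zmp[i] -= h; zmp[j] += h
                zmm = z.copy(); zmm[i] -= h; zmm[j] -= h
                H[i, j] = H[j, i] = (f(zpp) - f(zpm) - f(zmp) + f(zmm)) / (4 * h * h)
        return H

    # -- API ---------------------------------------------------------------

    def fit(self, tto: pd.DataFrame, dce: Optional[pd.DataFrame] = None):
        """Fit the model to TTO (and, for hybrid specs, DCE) answer tables.

        ``tto`` needs columns participant_id, state, w, is_learning;
        ``dce`` needs participant_id, stateA, stateB, chose_A.
        """
        spec = self._spec()
        if tto is None or len(tto) == 0:
            raise ValueError("TTO data must be non-empty")
        if spec.use_dce and (dce is None or len(dce) == 0):
            raise ValueError("hybrid specs require DCE data")
        if not spec.use_dce:
            dce = None

        self._tto_arr_ = _tto_arrays(tto)
        n_participants = int(self._tto_arr_["pidx"].max()) + 1
        self._dce_arr_ = _dce_arrays(dce, spec) if spec.use_dce else None
        self._layout_ = _ParamLayout(spec, n_participants)
        self.spec_ = spec
        self.n_obs_tto_ = len(tto)
        self.n_obs_dce_ = 0 if dce is None else len(dce)

        res = self._map_estimate()
        self.map_z_ = res.x
        self.map_params_ = self._layout_.to_params(res.x)
        self.map_logpost_ = -res.fun

        if self.method == "map":
            self._fit_laplace(res)
        elif self.method == "mcmc":
            self._fit_mcmc(res)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        self._finalize_summary()
        return self

    def _fit_laplace(self, res) -> None:
        layout = self._layout_
        rng = np.random.default_rng(self.random_state)
        if layout.ndim <= 40:
            H = self._fd_hessian(res.x)
            cov = np.linalg.pinv(-H)
        else:  # limited-memory approximation for large offset vectors
            cov = res.hess_inv.todense() if hasattr(res.hess_inv, "todense") else np.eye(layout.ndim) * 1e-4
        # symmetrize and guard against negative curvature directions
        cov = (cov + cov.T) / 2
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 1e-10, None)
        cov = vecs @ np.diag(vals) @ vecs.T
        zdraws = rng.multivariate_normal(res.x, cov, size=self.n_laplace_draws,
                                         method="cholesky")
        draws = np.array([layout.constrain(z) for z in zdraws])
        self.samples_ = pd.DataFrame(draws, columns=layout.names)
        self.diagnostics_ = pd.DataFrame(
            {"parameter": layout.names, "rhat": np.nan, "ess": np.nan}
        )
        self.converged_ = bool(res.success)
        if not self.converged_:
            warnings.warn("MAP optimization did not report convergence", stacklevel=2)

    def _fit_mcmc(self, res) -> None:
        import arviz as az
        import emcee

        layout = self._layout_
        ndim = layout.ndim
        nwalkers = self.n_walkers or max(2 * ndim + 2, 64)
        nwalkers += nwalkers % 2
        rng = np.random.default_rng(self.random_state)
        p0 = res.x + 0.01 * rng.standard_normal((nwalkers, ndim))
        # differential-evolution moves traverse the anchor-induced
        # parameter correlations far better than the stretch move
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, self._log_posterior_batch, moves=moves, vectorize=True,
        )
        sampler.random_state = np.random.RandomState(self.random_state).get_state()
        state = sampler.run_mcmc(p0, self.n_burn, progress=False,
                                 skip_initial_state_check=True)
        sampler.reset()
        sampler.run_mcmc(state, self.n_steps, progress=False,
                         skip_initial_state_check=True)
        chain = sampler.get_chain()  # (steps, walkers, ndim)
        zdraws = np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)
        con = np.array([[layout.constrain(z) for z in walker] for walker in zdraws])
        post = {name: con[:, :, i] for i, name in enumerate(layout.names)}
        idata = az.from_dict(posterior=post)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        rhats = np.array([float(rhat[n].values) for n in layout.names])
        esss = np.array([float(ess[n].values) for n in layout.names])
        self.diagnostics_ = pd.DataFrame(
            {"parameter": layout.names, "rhat": rhats, "ess": esss}
        )
        self.converged_ = bool(
            np.all(rhats <= self.rhat_max) and np.all(esss >= self.ess_min)
        )
        if not self.converged_:
            warnings.warn(
                "MCMC convergence gate failed "
                f"(max rhat {np.nanmax(rhats):.4f}, min ess {np.nanmin(esss):.0f})",
                stacklevel=2,
            )
        flat = con.reshape(-1, ndim)
        self.samples_ = pd.DataFrame(flat, columns=layout.names)
        self.acceptance_fraction_ = float(np.mean(sampler.acceptance_fraction))

    def _finalize_summary(self) -> None:
        q = self.samples_.quantile([0.025, 0.975])
        self.summary_ = pd.DataFrame(
            {
                "parameter": self.samples_.columns,
                "mean": self.samples_.mean().to_numpy(),
                "ci_low": q.loc[0.025].to_numpy(),
                "ci_high": q.loc[0.975].to_numpy(),
            }
        ).merge(self.diagnostics_, on="parameter", how="left")
        means = self.samples_.mean()
        layout = self._layout_
        x = np.array([means[n] for n in layout.names])
        zs = x.copy()
        zs[layout.is_log] = np.log(np.clip(zs[layout.is_log], 1e-300, None))
        self.params_ = layout.to_params(zs)

    def _beta_draws(self, max_draws: int = 2000) -> pd.DataFrame:
        n = len(self.samples_)
        step = max(1, n // max_draws)
        return self.samples_.iloc[::step]

    def predict_weights(self, ci: float = 0.95) -> pd.DataFrame:
        """Tariff: posterior weight of all 729 states with credible bands.

        For anchor-scale models the anchored coefficients are used (the
        scale ``s`` is not applied), so the tariff lives on the [0, 1]
        anchored scale; the discapability tariff is ``1 - X' beta``.
        """
        self._check_fitted()
        states = enumerate_states()
        X = design_matrix(states)
        const, Xw = _weight_terms(self.spec_, X)
        # the weight is linear in (mu, beta), so the posterior-mean weight
        # is exact from the full-sample means; bands come from thinned draws
        means = self.samples_.mean()
        beta_mean = means[[f"beta[{i}]" for i in range(12)]].to_numpy()
        base_mean = means["mu"] if const is None else const
        weight = base_mean + Xw @ beta_mean
        sub = self._beta_draws()
        B = sub[[f"beta[{i}]" for i in range(12)]].to_numpy()
        base = sub["mu"].to_numpy() if const is None else const
        W = (Xw @ B.T) + base  # (729, ndraw)
        alpha = (1.0 - ci) / 2
        return pd.DataFrame(
            {
                "state": [s.label for s in states],
                "weight": weight,
                "ci_low": np.quantile(W, alpha, axis=1),
                "ci_high": np.quantile(W, 1 - alpha, axis=1),
            }
        )

    def predict_tto_mean(self, states: Sequence) -> np.ndarray:
        """Predicted TTO answers (answer scale: anchor scale applied)."""
        self._check_fitted()
        X = design_matrix(states)
        p = self.params_
        const, Xw = _weight_terms(self.spec_, X)
        scale = p.s if self.spec_.anchor_scale else 1.0
        base = p.mu if const is None else const
        return base + scale * (Xw @ p.beta)

    def predict_dce_prob(self, stateA: Sequence, stateB: Sequence) -> np.ndarray:
        """P(choose A) for pairs of states under the fitted logit."""
        self._check_fitted()
        if not self.spec_.use_dce:
            raise ValueError("DCE predictions need a hybrid spec")
        from scipy.special import expit

        XA, XB = design_matrix(stateA), design_matrix(stateB)
        _, TA = _weight_terms(self.spec_, XA)
        _, TB = _weight_terms(self.spec_, XB)
        p = self.params_
        return expit(p.theta * ((TA - TB) @ p.beta))

    def _check_fitted(self) -> None:
        if not hasattr(self, "summary_"):
            raise RuntimeError("model is not fitted yet; call fit() first")


def fit(
    spec: ModelSpec,
    tto_data: pd.DataFrame,
    dce_data: Optional[pd.DataFrame] = None,
    method: str = "mcmc",
    seed: int = 0,
    **sampler_config,
) -> CapabilityValuationModel:
    """Fit a model family member; thin wrapper over the estimator class."""
    model = CapabilityValuationModel(
        use_dce=spec.use_dce,
        coding=spec.coding,
        censoring=spec.censoring,
        heteroskedastic=spec.heteroskedastic,
        varying_intercept=spec.varying_intercept,
        anchor_scale=spec.anchor_scale,
        anchor_prior_sd=spec.anchor_prior_sd,
        method=method,
        random_state=seed,
        **sampler_config,
    )
    return model.fit(tto_data, dce_data)


def predict_weights(fitted: CapabilityValuationModel, ci: float = 0.95) -> pd.DataFrame:
    """Tariff of a fitted model (wrapper over ``predict_weights``)."""
    return fitted.predict_weights(ci=ci)
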