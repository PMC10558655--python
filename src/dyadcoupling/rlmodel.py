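"""Reinforcement-learning models of trial-wise skin conductance.

Value update (per conditioned stimulus s):

    V_{t+1}(s_t) = V_t(s_t) + alpha * delta_t,    delta_t = U_t - V_t(s_t)

with U_t = 1 on shocked trials and 0 otherwise. The observation model is
Gaussian: SCR_t ~ Normal(beta0 + beta1 * V_t(s_t), sigma). The Pearce-Hall
variant replaces the constant learning rate by a per-stimulus associability
alpha_{t+1} = eta * |delta_t| + (1 - eta) * alpha_t.

Fitting is per-subject constrained maximum likelihood. For any fixed value
trajectory the Gaussian observation parameters (beta0, beta1, sigma) have a
closed-form ML solution (ordinary least squares of SCR on V), so the search
is concentrated onto the 1-3 trajectory parameters (alpha[, eta][, V0]) and
run from multiple seeded starts. Model comparison uses AIC (default) or BIC.
V0 is fixed at 0.5 for the observational-learning session and free in [0, 1]
for direct-test fits ("freeV0" variants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._utils import as_rng

__all__ = [
    "RWParams", "ValueTrajectory", "RWFitResult", "MODEL_IDS",
    "rw_trajectory", "ph_trajectory", "scr_loglik", "fit_rw",
    "compare_models", "shrink_alphas",
]

MODEL_IDS = ("RW-freeV0", "RW-fixedV0", "PH-freeV0", "PH-fixedV0")
ALPHA_BOUNDS = (0.001, 0.999)
SIGMA_FLOOR = 1e-4


@dataclass
class RWParams:
    """Rescorla-Wagner parameters with the Gaussian SCR observation model."""
    V0: float = 0.5
    alpha: float = 0.3
    beta0: float = 0.0
    beta1: float = 1.0
    sigma: float = 0.3
    eta: float | None = None  # Pearce-Hall associability update rate

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ValueTrajectory:
    """Per-trial values and prediction errors aligned to a schedule."""
    V: np.ndarray            # value of the presented CS, before the update
    delta: np.ndarray        # U_t - V_t(s_t)
    cs_types: list
    us: np.ndarray
    streams: dict = field(default_factory=dict)  # per-CS value sequences

    def __len__(self):
        return len(self.V)


def _check_schedule(schedule):
    if schedule.n_trials == 0:
        raise ValueError("schedule has no trials")


def rw_trajectory(schedule, V0: float, alpha: float) -> ValueTrajectory:
    """Rescorla-Wagner value trajectory; each CS stream updates on its own trials."""
    _check_schedule(schedule)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1] for trajectory computation")
    values = {}
    V, delta = [], []
    us = schedule.us_flags.astype(float)
    cs_types = schedule.cs_types
    streams = {}
    for cs, u in zip(cs_types, us):
        v = values.get(cs, V0)
        d = u - v
        V.append(v)
        delta.append(d)
        values[cs] = v + alpha * d
        streams.setdefault(cs, []).append(v)
    return ValueTrajectory(V=np.array(V), delta=np.array(delta),
                           cs_types=list(cs_types), us=us,
                           streams={k: np.array(v) for k, v in streams.items()})


def ph_trajectory(schedule, V0: float, alpha0: float, eta: float
                  ) -> ValueTrajectory:
    """Pearce-Hall hybrid trajectory with per-stimulus associability.

    ``alpha_{t+1} = eta * |delta_t| + (1 - eta) * alpha_t`` per CS stream;
    ``eta = 0`` reduces exactly to the Rescorla-Wagner model at ``alpha0``.
    """
    _check_schedule(schedule)
    if not 0.0 < alpha0 < 1.0:
        raise ValueError("alpha0 must lie in (0, 1)")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    values, alphas = {}, {}
    V, delta = [], []
    us = schedule.us_flags.astype(float)
    streams = {}
    for cs, u in zip(schedule.cs_types, us):
        v = values.get(cs, V0)
        a = alphas.get(cs, alpha0)
        d = u - v
        V.append(v)
        delta.append(d)
        values[cs] = v + a * d
        alphas[cs] = eta * abs(d) + (1.0 - eta) * a
        streams.setdefault(cs, []).append(v)
    return ValueTrajectory(V=np.array(V), delta=np.array(delta),
                           cs_types=list(schedule.cs_types), us=us,
                           streams={k: np.array(v) for k, v in streams.items()})


def scr_loglik(scr, traj: ValueTrajectory, beta0: float, beta1: float,
               sigma: float) -> float:
    """Total Gaussian log-likelihood of per-trial SCR under the value model."""
    scr = np.asarray(scr, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if len(scr) != len(traj):
        raise ValueError("scr and trajectory lengths differ")
    resid = scr - (beta0 + beta1 * traj.V)
    n = len(scr)
    return float(-0.5 * n * np.log(2.0 * np.pi) - n * np.log(sigma)
                 - 0.5 * np.sum(resid**2) / sigma**2)


@dataclass
class RWFitResult:
    params: RWParams
    loglik: float
    n_trials: int
    model_id: str
    n_params: int
    ic_scores: dict
    degenerate: bool = False
    scr: np.ndarray | None = None
    schedule: object | None = None

    @property
    def aic(self) -> float:
        return self.ic_scores["aic"]

    @property
    def bic(self) -> float:
        return self.ic_scores["bic"]


def _trajectory_for(model_id, schedule, theta, fixed_v0):
    """theta layout: [alpha, (eta,), (V0,)] depending on model."""
    is_ph = model_id.startswith("PH")
    free_v0 = model_id.endswith("freeV0")
    alpha = theta[0]
    i = 1
    eta = None
    if is_ph:
        eta = theta[i]
        i += 1
    v0 = theta[i] if free_v0 else fixed_v0
    if is_ph:
        traj = ph_trajectory(schedule, V0=v0, alpha0=alpha, eta=eta)
    else:
        traj = rw_trajectory(schedule, V0=v0, alpha=alpha)
    return traj, v0, eta


def _profiled_obs_params(scr, V):
    """Closed-form ML (beta0, beta1, sigma) given the value trajectory."""
    X = np.column_stack([np.ones_like(V), V])
    beta, *_ = np.linalg.lstsq(X, scr, rcond=None)
    resid = scr - X @ beta
    sigma = max(float(np.sqrt(np.mean(resid**2))), SIGMA_FLOOR)
    return float(beta[0]), float(beta[1]), sigma


def fit_rw(scr, schedule, model_id: str = "RW-fixedV0", n_starts: int = 20,
           seed=0, fixed_v0: float = 0.5) -> RWFitResult:
    """Constrained maximum-likelihood fit of one subject's per-trial SCR.

    Multi-start L-BFGS-B over the trajectory parameters with the Gaussian
    observation parameters profiled out in closed form. Bounds: alpha in
    (0.001, 0.999), eta in [0, 1], V0 in [0, 1] when free; sigma is floored
    at 1e-4. Returns the best start; a near-flat likelihood (uninformative
    SCR, |beta1| ~ 0) sets ``degenerate=True`` with a warning.
    """
    scr = np.asarray(scr, dtype=float)
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    if len(scr) < 8 or schedule.n_trials < 8:
        raise ValueError("need at least 8 trials to fit")
    if len(scr) != schedule.n_trials:
        raise ValueError("scr length must match the schedule")
    rng = as_rng(seed)

    is_ph = model_id.startswith("PH")
    free_v0 = model_id.endswith("freeV0")
    bounds = [ALPHA_BOUNDS]
    if is_ph:
        bounds.append((0.0, 1.0))
    if free_v0:
        bounds.append((0.0, 1.0))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def nll(theta):
        traj, _, _ = _trajectory_for(model_id, schedule, theta, fixed_v0)
        b0, b1, s = _profiled_obs_params(scr, traj.V)
        return -scr_loglik(scr, traj, b0, b1, s)

    best = None
    n_fail = 0
    for k in range(n_starts):
        x0 = lo + (hi - lo) * rng.uniform(0.05, 0.95, size=len(bounds))
        try:
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        except Exception:
            n_fail += 1
            continue
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"fit failed: all {n_starts} starts diverged "
                           f"({n_fail} exceptions) for model {model_id}")

    traj, v0, eta = _trajectory_for(model_id, schedule, best.x, fixed_v0)
    b0, b1, s = _profiled_obs_params(scr, traj.V)
    loglik = scr_loglik(scr, traj, b0, b1, s)
    # observation parameters (3) + trajectory parameters
    n_params = 3 + len(bounds)
    n = len(scr)
    ic = {"aic": 2 * n_params - 2 * loglik,
          "bic": n_params * np.log(n) - 2 * loglik}
    degenerate = False
    v_sd = float(np.std(traj.V))
    scr_sd = float(np.std(scr))
    if scr_sd < 1e-10 or v_sd < 1e-10 or abs(b1) * v_sd < 1e-6 * max(scr_sd, 1e-10):
        degenerate = True
        warnings.warn(f"{model_id}: flat likelihood in alpha (uninformative "
                      "SCR); estimates are not identified")
    params = RWParams(V0=v0, alpha=float(best.x[0]), beta0=b0, beta1=b1,
                      sigma=s, eta=None if eta is None else float(eta))
    return RWFitResult(params=params, loglik=loglik, n_trials=n,
                       model_id=model_id, n_params=n_params, ic_scores=ic,
                       degenerate=degenerate, scr=scr, schedule=schedule)


def compare_models(fits, criterion: str = "aic") -> pd.DataFrame:
    """Rank fits of the same data by information criterion.

    Returns a DataFrame sorted by the criterion with Delta scores relative to
    the best model; exact ties are flagged in a ``tied`` column and share the
    winner flag.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    n_set = {f.n_trials for f in fits}
    if len(n_set) > 1:
        raise ValueError("fits cover different numbers of trials")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    rows = [{"model_id": f.model_id, "loglik": f.loglik,
             "n_params": f.n_params, "aic": f.aic, "bic": f.bic}
            for f in fits]
    df = pd.DataFrame(rows).sort_values(criterion, kind="mergesort")
    df["delta"] = df[criterion] - df[criterion].min()
    df["winner"] = df["delta"] == 0.0
    df["tied"] = df["winner"] & (df["winner"].sum() > 1)
    return df.reset_index(drop=True)


def _concentrated_nll_alpha(fit: RWFitResult, alpha: float) -> float:
    """Concentrated negative log-likelihood as a function of alpha alone."""
    p = fit.params
    if fit.model_id.startswith("PH"):
        traj = ph_trajectory(fit.schedule, V0=p.V0, alpha0=alpha, eta=p.eta)
    else:
        traj = rw_trajectory(fit.schedule, V0=p.V0, alpha=alpha)
    b0, b1, s = _profiled_obs_params(fit.scr, traj.V)
    return -scr_loglik(fit.scr, traj, b0, b1, s)


def shrink_alphas(fits, h: float = 1e-3) -> np.ndarray:
    """Optional empirical-Bayes pass: shrink per-subject learning rates toward
    the group mean, weighted by inverse likelihood curvature.

    The curvature of each subject's concentrated negative log-likelihood at
    the fitted alpha (central finite difference) approximates the Fisher
    information; subjects with flatter likelihoods shrink harder. The prior
    precision is method-of-moments from the spread of the raw estimates.
    Returns the shrunken alpha per fit, in input order.
    """
    fits = list(fits)
    alphas = np.array([f.params.alpha for f in fits])
    if len(fits) < 3:
        return alphas
    info = np.empty(len(fits))
    for i, f in enumerate(fits):
        if f.scr is None or f.schedule is None:
            info[i] = 0.0
            continue
        a = np.clip(f.params.alpha, ALPHA_BOUNDS[0] + h, ALPHA_BOUNDS[1] - h)
        curv = (_concentrated_nll_alpha(f, a + h)
                - 2.0 * _concentrated_nll_alpha(f, a)
                + _concentrated_nll_alpha(f, a - h)) / h**2
        info[i] = max(curv, 0.0)
    tau2 = max(float(np.var(alphas, ddof=1)), 1e-6)
    prior_prec = 1.0 / tau2
    group = float(alphas.mean())
    return (info * alphas + prior_prec * group) / (info + prior_prec)
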