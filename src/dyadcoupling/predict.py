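"""Time-varying prediction of learning outcome from cumulative coupling.

The per-dyad coupling time course (0.1 s steps over (0, 5.5] s post CS onset)
is converted to cumulative coupling, cum[k] = sum of the first k steps. At
each of the 55 grid points an epsilon-SVR with RBF kernel is trained on all
dyads but one and predicts the held-out dyad's learning outcome
(leave-one-dyad-out); sweep performance is the Pearson correlation (and MAE)
between predicted and actual outcomes, with p-values from the t-transform of
r and BH-FDR across the 55 time points. With informative coupling arriving
late in the CS-US interval the r(t) curve rises toward the expected US.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .btbc import bh_fdr

__all__ = ["TIME_GRID", "cumulative_btbc", "svr_loo_timecourse",
           "summarize_onset", "OnsetSummary"]

#: Prediction time grid: 0.1-5.5 s post CS onset in 0.1 s increments.
TIME_GRID = np.round(np.arange(1, 56) * 0.1, 10)


def cumulative_btbc(series) -> np.ndarray:
    """Cumulative coupling: out[k] = sum of per-step values 1..k (prefix sum)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D over the time grid")
    if not np.all(np.isfinite(series)):
        raise ValueError("per-step coupling contains non-finite values")
    return np.cumsum(series)


def _pearson_p(r: float, n: int) -> float:
    if n < 3 or not np.isfinite(r):
        return np.nan
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class PredictionTrace:
    """LOO prediction performance per time point plus the raw predictions."""
    table: pd.DataFrame        # time_s, r, mae, p, q
    predictions: np.ndarray    # (n_times, n_dyads)
    outcomes: np.ndarray
    kernel_params: dict


def svr_loo_timecourse(traces, outcomes, kernel_params: dict | None = None,
                       seed=0, fdr_q: float = 0.05) -> PredictionTrace:
    """Leave-one-dyad-out epsilon-SVR (RBF) at every cumulative time point.

    Parameters
    ----------
    traces : array (n_dyads, n_times) or DataFrame
        Cumulative coupling per dyad on the time grid.
    outcomes : array (n_dyads,)
        Differential learning outcome per dyad (e.g. differential pupil
        response at direct test).
    kernel_params : dict, optional
        ``C`` (default 1.0), ``epsilon`` (default 0.1) and ``gamma``
        (default "auto", i.e. 1/n_features on fold-standardized inputs).
    fdr_q : BH-FDR level across time points.

    The feature at time k is the scalar cumulative value; inputs are
    standardized within each training fold and the same transform is applied
    to the held-out dyad.
    """
    if isinstance(traces, pd.DataFrame):
        traces = traces.to_numpy(dtype=float)
    traces = np.asarray(traces, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if traces.ndim == 2 and traces.shape[0] == len(outcomes):
        pass
    else:
        raise ValueError("traces must be (n_dyads, n_times) aligned with "
                         "outcomes")
    n_dyads, n_times = traces.shape
    if n_dyads < 8:
        raise ValueError("need at least 8 dyads for leave-one-dyad-out "
                         "correlation")
    if not np.all(np.isfinite(outcomes)) or np.std(outcomes) == 0:
        raise ValueError("outcomes must be finite with nonzero variance")
    kp = {"C": 1.0, "epsilon": 0.1, "gamma": "auto", "tol": 1e-3}
    kp.update(kernel_params or {})

    times = TIME_GRID if n_times == len(TIME_GRID) else \
        np.round(np.arange(1, n_times + 1) * 0.1, 10)
    preds = np.empty((n_times, n_dyads))
    rows = []
    for k in range(n_times):
        X = traces[:, k:k + 1]
        for held in range(n_dyads):
            train = np.ones(n_dyads, dtype=bool)
            train[held] = False
            scaler = StandardScaler().fit(X[train])
            model = SVR(kernel="rbf", C=kp["C"], epsilon=kp["epsilon"],
                        gamma=kp["gamma"], tol=kp["tol"])
            model.fit(scaler.transform(X[train]), outcomes[train])
            preds[k, held] = model.predict(scaler.transform(X[held:held + 1]))[0]
        if np.std(preds[k]) < 1e-12:
            r = np.nan
        else:
            r = float(stats.pearsonr(preds[k], outcomes)[0])
        mae = float(np.mean(np.abs(preds[k] - outcomes)))
        rows.append({"time_s": times[k], "r": r, "mae": mae,
                     "p": _pearson_p(r, n_dyads)})
    table = pd.DataFrame(rows)
    p_for_fdr = table["p"].fillna(1.0).to_numpy()
    _, q_adj = bh_fdr(p_for_fdr, q=fdr_q)
    table["q"] = q_adj
    return PredictionTrace(table=table, predictions=preds, outcomes=outcomes,
                           kernel_params=kp)


@dataclass
class OnsetSummary:
    onset_s: float | None
    window: tuple | None  # maximal contiguous significant run containing onset


def summarize_onset(trace: PredictionTrace, q: float = 0.05) -> OnsetSummary:
    """Earliest FDR-significant time point and its contiguous significant run.

    One-sided on positive prediction performance: a time point counts only if
    q < level and r > 0. Returns (None, None) when nothing is significant.
    """
    tab = trace.table
    sig = (tab["q"].to_numpy() < q) & (tab["r"].to_numpy() > 0)
    if not sig.any():
        return OnsetSummary(onset_s=None, window=None)
    times = tab["time_s"].to_numpy()
    first = int(np.argmax(sig))
    last = first
    while last + 1 < len(sig) and sig[last + 1]:
        last += 1
    return OnsetSummary(onset_s=float(times[first]),
                        window=(float(times[first]), float(times[last])))
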