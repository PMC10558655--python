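"""Brain-to-brain coupling (BtBC) via the circular correlation coefficient.

The coupling statistic between two phase series x, y is

    CCorr(x, y) = sum sin(x - x_bar) sin(y - y_bar)
                  / sqrt( sum sin^2(x - x_bar) * sum sin^2(y - y_bar) )

with x_bar, y_bar the circular means. Values are Fisher-z transformed and
folded to absolute value (``z_abs``) before statistics. Two-step inference:
(1) keep only channel pairs whose task coupling exceeds a stimulus-free
baseline (one-sided paired t across dyads, BH-FDR); (2) on the retained pairs,
a linear mixed model tests CS type, social status and their interaction with
observers nested in demonstrators. A pseudo-demonstrator surrogate (each time
point drawn from a random real demonstrator) provides the coupling null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import Band, band_phase

if TYPE_CHECKING:
    from .synth import DyadRecording

__all__ = [
    "DegenerateInputError", "ccorr", "ccorr_matrix", "normalize",
    "epoch_coupling", "baseline_filter", "condition_contrast", "bh_fdr",
    "pseudo_comparison", "PairSelection", "PseudoComparison",
]

CCORR_CLIP = 1.0 - 1e-6
TASK_WINDOW = (0.0, 5.5)


class DegenerateInputError(ValueError):
    """Raised when the circular correlation denominator vanishes."""


def _circular_mean(x: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * x))))


def ccorr(x, y) -> float:
    """Circular correlation coefficient of two phase series (radians).

    Symmetric, invariant to adding a constant phase to either argument, and
    equal to 1 for identical (perfectly coupled) series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    sx = np.sin(x - _circular_mean(x))
    sy = np.sin(y - _circular_mean(y))
    denom = np.sqrt(np.sum(sx**2) * np.sum(sy**2))
    if denom < 1e-12:
        raise DegenerateInputError("degenerate phase series (zero sine deviation)")
    return float(np.sum(sx * sy) / denom)


def ccorr_matrix(phases_a: np.ndarray, phases_b: np.ndarray) -> np.ndarray:
    """All-pairs circular correlation between two channel sets.

    ``phases_a`` (n_a, n_t) x ``phases_b`` (n_b, n_t) -> (n_a, n_b). Degenerate
    channels yield NaN entries rather than an exception.
    """
    def deviations(p):
        mean = np.angle(np.mean(np.exp(1j * p), axis=-1, keepdims=True))
        return np.sin(p - mean)

    sa = deviations(np.asarray(phases_a, dtype=float))
    sb = deviations(np.asarray(phases_b, dtype=float))
    num = sa @ sb.T
    pa = np.sum(sa**2, axis=-1)
    pb = np.sum(sb**2, axis=-1)
    denom = np.sqrt(np.outer(pa, pb))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom < 1e-12, np.nan, num / denom)
    return out


def normalize(ccorr_raw) -> float:
    """Fisher-z then absolute value: ``|atanh(r)|`` with r clipped to +-(1-1e-6)."""
    r = np.asarray(ccorr_raw, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("|ccorr| > 1 is not a correlation coefficient")
    z = np.abs(np.arctanh(np.clip(r, -CCORR_CLIP, CCORR_CLIP)))
    return float(z) if z.ndim == 0 else z


def epoch_coupling(dyad: "DyadRecording", band: Band,
                   window: tuple[float, float] = TASK_WINDOW,
                   include_baseline: bool = True, dyad_id=0,
                   dem_override: np.ndarray | None = None) -> pd.DataFrame:
    """Per-trial, per-channel-pair coupling table for one dyad.

    Demonstrator and observer phases come from their own session timelines but
    share the trial clock, so the 0-5.5 s post-onset window aligns the two
    roles. When ``include_baseline`` is set, the stimulus-free head segment of
    the recording is chopped into 5.5 s pseudo-trials scored the same way
    (epoch kind ``baseline``). ``dem_override`` substitutes a surrogate
    demonstrator signal array (same shape) for pseudo-dyad analyses.

    Returns a long DataFrame with columns dyad_id, dem_channel, obs_channel,
    band, epoch, trial, cs_type, ccorr_raw, z_abs.
    """
    fs = dyad.fs
    dem = dyad.demonstrator_signals if dem_override is None else dem_override
    ph_dem = band_phase(dem, fs, band).phase
    ph_obs = band_phase(dyad.observer_signals, fs, band).phase
    n = ph_dem.shape[-1]
    span = window[1] - window[0]

    windows = []  # (epoch_kind, trial_idx, cs_type, i0, i1)
    for i, tr in enumerate(dyad.schedule.trials):
        i0 = int(round((tr.onset_s + window[0]) * fs))
        i1 = int(round((tr.onset_s + window[1]) * fs))
        if i0 < 0 or i1 > n:
            warnings.warn(f"trial {i} extends past recording; dropped")
            continue
        windows.append(("task", i, tr.cs_type, i0, i1))
    if include_baseline:
        first = min(tr.onset_s for tr in dyad.schedule.trials)
        guard = 1.0  # filter edge guard, seconds
        t = guard
        k = 0
        while t + span <= first - guard:
            i0 = int(round(t * fs))
            i1 = int(round((t + span) * fs))
            windows.append(("baseline", k, "baseline", i0, i1))
            k += 1
            t += span
        if k == 0:
            raise ValueError("recording has no stimulus-free head segment for "
                             "baseline epochs")

    dem_names = list(dyad.channel_names["demonstrator"])
    obs_names = list(dyad.channel_names["observer"])
    frames = []
    for kind, idx, cs, i0, i1 in windows:
        r = ccorr_matrix(ph_dem[:, i0:i1], ph_obs[:, i0:i1])
        d_idx, o_idx = np.meshgrid(np.arange(len(dem_names)),
                                   np.arange(len(obs_names)), indexing="ij")
        frames.append(pd.DataFrame({
            "dyad_id": dyad_id,
            "dem_channel": np.asarray(dem_names)[d_idx.ravel()],
            "obs_channel": np.asarray(obs_names)[o_idx.ravel()],
            "band": band.name,
            "epoch": kind,
            "trial": idx,
            "cs_type": cs,
            "ccorr_raw": r.ravel(),
        }))
    table = pd.concat(frames, ignore_index=True)
    dropped = table["ccorr_raw"].isna()
    if dropped.any():
        warnings.warn(f"{int(dropped.sum())} degenerate-phase windows dropped")
        table = table[~dropped].reset_index(drop=True)
    table["z_abs"] = normalize(table["ccorr_raw"].to_numpy())
    table["pair"] = table["dem_channel"] + "_" + table["obs_channel"]
    return table


def bh_fdr(p, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR: (rejection mask, adjusted q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, q_adj


@dataclass
class PairSelection:
    """Step-1 result: per-pair task-vs-baseline statistics and retention."""
    stats: pd.DataFrame  # pair, t, p, q, retained
    q_level: float

    @property
    def retained(self) -> list:
        return self.stats.loc[self.stats["retained"], "pair"].tolist()


def baseline_filter(table: pd.DataFrame, q: float = 0.05,
                    method: str = "ttest", n_perm: int = 2000,
                    seed=0) -> PairSelection:
    """Step 1 of the two-step selection: task > baseline per channel pair.

    For every pair, dyad-mean ``z_abs`` is compared between task and baseline
    epochs with a one-sided paired t-test across dyads (or a one-sided
    sign-flip permutation test of the paired differences when
    ``method='permutation'``); BH-FDR across pairs. Retained pairs are those
    with q < ``q`` and a positive task-baseline sign.
    """
    if method not in ("ttest", "permutation"):
        raise ValueError("method must be 'ttest' or 'permutation'")
    rng = np.random.default_rng(seed) if method == "permutation" else None
    if "baseline" not in set(table["epoch"]):
        raise ValueError("coupling table has no baseline epochs")
    means = (table.groupby(["pair", "dyad_id", "epoch"], observed=True)["z_abs"]
             .mean().unstack("epoch"))
    if means[["task", "baseline"]].isna().any().any():
        raise ValueError("every (pair, dyad) needs both task and baseline epochs")
    n_dyads = means.index.get_level_values("dyad_id").nunique()
    if n_dyads < 6:
        raise ValueError("need at least 6 dyads for the baseline filter")
    rows = []
    for pair, sub in means.groupby(level="pair"):
        diff = (sub["task"] - sub["baseline"]).to_numpy()
        if np.allclose(diff, 0):
            t_val, p_val = 0.0, 1.0
        elif method == "ttest":
            t_val, p_val = stats.ttest_rel(sub["task"], sub["baseline"],
                                           alternative="greater")
        else:
            obs = diff.mean()
            signs = rng.choice([-1.0, 1.0], size=(n_perm, len(diff)))
            null = (signs * diff).mean(axis=1)
            p_val = (np.sum(null >= obs) + 1.0) / (n_perm + 1.0)
            t_val = obs / (diff.std(ddof=1) / np.sqrt(len(diff)))
        rows.append({"pair": pair, "mean_task": sub["task"].mean(),
                     "mean_baseline": sub["baseline"].mean(),
                     "t": float(t_val), "p": float(p_val)})
    out = pd.DataFrame(rows)
    reject, q_adj = bh_fdr(out["p"].to_numpy(), q=q)
    out["q"] = q_adj
    out["retained"] = reject & (out["t"] > 0)
    return PairSelection(stats=out, q_level=q)


def condition_contrast(table: pd.DataFrame, status: dict, demonstrator: dict,
                       q: float = 0.05, trial_level: bool = True) -> pd.DataFrame:
    """Step 2: per-pair mixed model ``z_abs ~ cs_type * status`` with random
    intercepts for observer nested within demonstrator.

    ``status`` maps dyad_id -> {"HS", "LS"}; ``demonstrator`` maps dyad_id to a
    demonstrator identity. Task epochs only. ``trial_level=False`` collapses to
    condition means per dyad before fitting. Wald p-values; BH-FDR per effect
    across pairs.

    Returns one row per (pair, effect) with estimate, se, t, p, q.
    """
    import statsmodels.formula.api as smf

    data = table[table["epoch"] == "task"].copy()
    data["status"] = data["dyad_id"].map(status)
    data["demonstrator"] = data["dyad_id"].map(demonstrator)
    data["observer"] = data["dyad_id"].astype(str)
    if data["status"].isna().any() or data["demonstrator"].isna().any():
        raise ValueError("every dyad needs a status group and a demonstrator")
    if data["demonstrator"].nunique() < 2 or data["observer"].nunique() < 3:
        raise ValueError("insufficient grouping levels for a mixed model")
    if not trial_level:
        data = (data.groupby(["pair", "dyad_id", "cs_type", "status",
                              "demonstrator", "observer"], observed=True)
                ["z_abs"].mean().reset_index())

    effects = {
        "C(cs_type, Treatment('CS-'))[T.CS+]": "cs_type",
        "C(status, Treatment('HS'))[T.LS]": "status",
        "C(cs_type, Treatment('CS-'))[T.CS+]:C(status, Treatment('HS'))[T.LS]":
            "interaction",
    }
    formula = "z_abs ~ C(cs_type, Treatment('CS-')) * C(status, Treatment('HS'))"
    rows = []
    for pair, sub in data.groupby("pair", observed=True):
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm(formula, sub, groups=sub["demonstrator"],
                                 re_formula="1",
                                 vc_formula={"observer": "0 + C(observer)"})
                fit = md.fit(reml=True, method="lbfgs")
            except Exception:
                fit = None
            if fit is None or not np.all(np.isfinite(fit.bse.iloc[:4])):
                # singular nested fit: fall back to observer-level intercepts
                warnings.warn(f"pair {pair}: nested fit singular; observer-only "
                              "random intercept used")
                md = smf.mixedlm(formula, sub, groups=sub["observer"],
                                 re_formula="1")
                fit = md.fit(reml=True, method="lbfgs")
        for term, name in effects.items():
            rows.append({"pair": pair, "effect": name,
                         "estimate": float(fit.params[term]),
                         "se": float(fit.bse[term]),
                         "t": float(fit.tvalues[term]),
                         "p": float(fit.pvalues[term])})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for name in set(effects.values()):
        mask = out["effect"] == name
        _, q_adj = bh_fdr(out.loc[mask, "p"].to_numpy(), q=q)
        out.loc[mask, "q"] = q_adj
    out["significant"] = out["q"] < q
    return out


@dataclass
class PseudoComparison:
    """Genuine-vs-pseudo dyad summary (paired t on dyad-mean z_abs)."""
    mean_genuine: float
    sd_genuine: float
    mean_pseudo: float
    sd_pseudo: float
    t: float
    p: float
    n_dyads: int


def pseudo_comparison(genuine: pd.DataFrame, pseudo: pd.DataFrame
                      ) -> PseudoComparison:
    """Compare coupling from genuine vs pseudo-demonstrator tables.

    All-channel mean ``z_abs`` over task epochs is computed per dyad in both
    tables and contrasted with a paired t-test. Identical tables give t = 0,
    p = 1 by convention.
    """
    def dyad_means(tab):
        return (tab[tab["epoch"] == "task"]
                .groupby("dyad_id", observed=True)["z_abs"].mean())

    g = dyad_means(genuine)
    s = dyad_means(pseudo)
    if not g.index.equals(s.index):
        raise ValueError("genuine and pseudo tables cover different dyads")
    diff = g.to_numpy() - s.to_numpy()
    if np.allclose(diff, 0):
        t_val, p_val = 0.0, 1.0
    else:
        t_val, p_val = stats.ttest_rel(g, s)
    return PseudoComparison(
        mean_genuine=float(g.mean()), sd_genuine=float(g.std(ddof=1)),
        mean_pseudo=float(s.mean()), sd_pseudo=float(s.std(ddof=1)),
        t=float(t_val), p=float(p_val), n_dyads=len(g))
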