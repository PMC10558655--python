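"""Consensus clustering of coupling networks by nonnegative matrix factorization.

The subjects-by-channel-pair matrix of nonnegative coupling values (z_abs) is
factorized as M ~ W H with KL-divergence multiplicative updates (the "Brunet"
flavour of NMF). Channel pairs (columns, labelled "DEMchan_OBSchan") are the
clustered dimension: over many random restarts, the fraction of runs in which
two pairs share an argmax component builds a consensus matrix, whose
average-linkage dendrogram yields both the cophenetic coefficient used for
rank selection (first rank at which it starts decreasing) and the final
cluster assignment. Per-subject cluster loadings are the columns of the
best-divergence factorization's W, matched to consensus clusters, and are
correlated with per-subject learning outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from ._utils import as_rng

__all__ = ["NMFResult", "ConsensusResult", "nmf_factorize",
           "consensus_cluster", "loading_learning_correlation"]

_EPS = 1e-12


class NMFResult(NamedTuple):
    W: np.ndarray
    H: np.ndarray
    divergence: float
    n_iter: int
    history: np.ndarray


def _kl_divergence(V, WH):
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum()
                 + WH.sum())


def nmf_factorize(M: np.ndarray, rank: int, seed=0, max_iter: int = 2000,
                  tol: float = 1e-6) -> NMFResult:
    """KL-divergence multiplicative-update NMF (Brunet updates).

    Iterates H <- H * (W^T (V / WH)) / (W^T 1) and the symmetric W update
    until the relative divergence change falls below ``tol`` or ``max_iter``
    is reached. The divergence is monitored every iteration and is
    non-increasing by construction. All-zero columns are dropped (logged) and
    restored as zero columns of H.
    """
    V = np.asarray(M, dtype=float)
    if np.any(V < 0):
        raise ValueError("NMF input must be nonnegative")
    if V.ndim != 2:
        raise ValueError("M must be 2-D (subjects x pairs)")
    zero_cols = np.where(V.sum(axis=0) == 0)[0]
    keep = np.where(V.sum(axis=0) > 0)[0]
    if len(zero_cols):
        warnings.warn(f"{len(zero_cols)} all-zero columns dropped from NMF")
        V = V[:, keep]
    n, m = V.shape
    if not 0 < rank < min(n, m):
        raise ValueError(f"rank must lie in (0, {min(n, m)})")
    rng = as_rng(seed)
    avg = np.sqrt(V.mean() / rank)
    W = avg * rng.uniform(0.1, 1.0, size=(n, rank))
    H = avg * rng.uniform(0.1, 1.0, size=(rank, m))

    history = []
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        div = _kl_divergence(V, W @ H + _EPS)
        history.append(div)
        denom = max(abs(prev), 1e-30)
        if np.isfinite(prev) and (prev - div) / denom < tol:
            prev = div
            break
        prev = div

    if len(zero_cols):
        H_full = np.zeros((rank, len(keep) + len(zero_cols)))
        H_full[:, keep] = H
        H = H_full
    return NMFResult(W=W, H=H, divergence=float(prev), n_iter=it,
                     history=np.array(history))


@dataclass
class ConsensusResult:
    """Selected rank, consensus structure, and cluster loadings."""
    rank: int
    consensus: np.ndarray            # pairs x pairs, selected rank
    assignments: np.ndarray          # cluster index (0-based) per pair
    loadings: np.ndarray             # subjects x rank
    cophenetic: dict                 # rank -> cophenetic coefficient
    pair_labels: list
    consensus_by_rank: dict | None = None


def _consensus_for_rank(V, rank, n_runs, rng, max_iter, tol):
    m = V.shape[1]
    counts = np.zeros((m, m))
    best = None
    for _ in range(n_runs):
        res = nmf_factorize(V, rank, seed=rng, max_iter=max_iter, tol=tol)
        labels = np.argmax(res.H, axis=0)  # ties -> lower component index
        same = labels[:, None] == labels[None, :]
        counts += same
        if best is None or res.divergence < best.divergence:
            best = res
    return counts / n_runs, best


def consensus_cluster(M, candidate_ranks=(2, 3, 4, 5, 6), n_runs: int = 1000,
                      seed=0, max_iter: int = 500, tol: float = 1e-5,
                      pair_labels=None, keep_all_consensus: bool = False
                      ) -> ConsensusResult:
    """Consensus NMF clustering of channel pairs with cophenetic rank selection.

    For each candidate rank, ``n_runs`` random-restart factorizations build a
    pairs-by-pairs consensus matrix (co-assignment frequency). The cophenetic
    coefficient of its average-linkage dendrogram measures consensus
    stability; the selected rank is the first candidate at which the
    coefficient starts decreasing (if it never decreases, the largest
    candidate is selected with a warning). Final assignment cuts the selected
    consensus dendrogram at the selected rank.
    """
    if isinstance(M, pd.DataFrame):
        pair_labels = list(M.columns) if pair_labels is None else pair_labels
        V = M.to_numpy(dtype=float)
    else:
        V = np.asarray(M, dtype=float)
    m = V.shape[1]
    pair_labels = pair_labels or [f"pair{i}" for i in range(m)]
    candidate_ranks = sorted(candidate_ranks)
    if not candidate_ranks:
        raise ValueError("candidate_ranks must be non-empty")
    if max(candidate_ranks) > m // 2:
        raise ValueError("largest candidate rank exceeds half the pair count")
    if n_runs < 50:
        raise ValueError("n_runs must be >= 50 for a stable cophenetic "
                         "coefficient")
    rng = as_rng(seed)

    consensus_by_rank, best_by_rank, coph = {}, {}, {}
    for rank in candidate_ranks:
        C, best = _consensus_for_rank(V, rank, n_runs, rng, max_iter, tol)
        consensus_by_rank[rank] = C
        best_by_rank[rank] = best
        dist = squareform(1.0 - C, checks=False)
        Z = linkage(dist, method="average")
        coph[rank] = float(cophenet(Z, dist)[0]) if dist.std() > 0 else 1.0

    selected = None
    for a, b in zip(candidate_ranks, candidate_ranks[1:]):
        if coph[b] < coph[a]:
            selected = a
            break
    if selected is None:
        selected = candidate_ranks[-1]
        warnings.warn("cophenetic coefficient never decreased over the "
                      "candidate ranks; largest candidate selected")

    C = consensus_by_rank[selected]
    Z = linkage(squareform(1.0 - C, checks=False), method="average")
    assignments = fcluster(Z, t=selected, criterion="maxclust") - 1

    # match the best factorization's components to the consensus clusters so
    # that loading column c corresponds to cluster c
    best = best_by_rank[selected]
    comp_labels = np.argmax(best.H, axis=0)
    overlap = np.zeros((selected, selected))
    for comp in range(selected):
        for clus in range(selected):
            overlap[comp, clus] = np.sum((comp_labels == comp)
                                         & (assignments == clus))
    row, col = linear_sum_assignment(-overlap)
    order = np.empty(selected, dtype=int)
    order[col] = row
    loadings = best.W[:, order]

    return ConsensusResult(
        rank=selected, consensus=C, assignments=assignments,
        loadings=loadings, cophenetic=coph, pair_labels=list(pair_labels),
        consensus_by_rank=consensus_by_rank if keep_all_consensus else None)


def loading_learning_correlation(result: ConsensusResult, outcomes
                                 ) -> pd.DataFrame:
    """Pearson correlation of per-subject cluster loadings with learning.

    ``outcomes`` is one differential learning value per subject, aligned with
    the rows of the factorized matrix. Clusters with zero-variance loadings
    yield NaN with a warning (correlation undefined).
    """
    outcomes = np.asarray(outcomes, dtype=float)
    if len(outcomes) != result.loadings.shape[0]:
        raise ValueError("outcomes must align with subjects")
    if len(outcomes) < 6:
        raise ValueError("need at least 6 subjects")
    rows = []
    for c in range(result.rank):
        load = result.loadings[:, c]
        if np.std(load) < 1e-12 or np.std(outcomes) < 1e-12:
            warnings.warn(f"cluster {c}: zero-variance loading; correlation "
                          "undefined")
            r_val, p_val = np.nan, np.nan
        else:
            r_val, p_val = stats.pearsonr(load, outcomes)
        rows.append({"cluster": c, "r": float(r_val), "p": float(p_val),
                     "n": len(outcomes)})
    return pd.DataFrame(rows)
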