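"""Cohort-level summaries, poor-synchronizer profiling and clustering.

Covers the produced-level distribution table with its column medians,
success-proportion profiles over the four conditions (bounce/clap x
music/metronome), two-stage profile clustering (Ward agglomerative to
choose k, then MacQueen k-means for the centroids), rank-sum group
comparisons, and response-count-weighted regularity summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm, rankdata
from sklearn.metrics import silhouette_score

from .classify import TrialClass

__all__ = [
    "median_half_up",
    "level_distribution_table",
    "success_profiles",
    "ClusterResult",
    "cluster_profiles",
    "rank_sum_test",
    "condition_summary",
    "PROFILE_CONDITIONS",
]

#: success-profile condition order
PROFILE_CONDITIONS = (
    "bounce_music",
    "clap_music",
    "bounce_metronome",
    "clap_metronome",
)


def median_half_up(values) -> int:
    """Median of integer counts with half-integer medians rounded up.

    The even-count median of participant counts is the mean of the two
    middle values; a .5 is rounded upward (81.5 -> 82, 53.5 -> 54).
    """
    med = float(np.median(np.asarray(values, dtype=float)))
    return int(math.floor(med + 0.5))


def level_distribution_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Participant counts at each produced level, per stimulus x movement.

    Expects tidy columns ``stimulus_name``, ``movement_type`` and
    ``level`` (beat / two_beat; other levels are not tabulated). Returns
    one row per stimulus with four count columns plus a final ``median``
    row (halves rounded up).
    """
    kept = trials[trials["level"].isin(["beat", "two_beat"])]
    table = (
        kept.pivot_table(
            index="stimulus_name",
            columns=["movement_type", "level"],
            aggfunc="size",
            fill_value=0,
        )
        .reindex(
            columns=pd.MultiIndex.from_product(
                [["bounce", "clap"], ["beat", "two_beat"]]
            ),
            fill_value=0,
        )
    )
    # preserve stimulus presentation order
    order = trials["stimulus_name"].drop_duplicates().tolist()
    table = table.reindex([s for s in order if s in table.index])
    medians = {col: median_half_up(table[col].to_numpy()) for col in table.columns}
    table.loc["median"] = pd.Series(medians)
    return table


def success_profiles(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant proportion of synchronization successes by condition.

    A success is a trial in which every segment had a significant
    Rayleigh test (class 'normal'). Bimodal and four-beat-level trials
    are removed from the denominator; failed trials (poor, off-tempo,
    unstable, unusable) stay in it. Conditions with no classifiable
    trials are missing (NaN), not zero.
    """
    df = trials.copy()
    df["condition"] = df["movement_type"] + "_" + np.where(
        df["is_metronome"], "metronome", "music"
    )
    classifiable = df[~df["trial_class"].isin([TrialClass.BIMODAL, TrialClass.FOUR_BEAT])]
    out = {}
    for (pid, cond), grp in classifiable.groupby(["participant_id", "condition"]):
        out.setdefault(pid, {})[cond] = float(
            (grp["trial_class"] == TrialClass.NORMAL).mean()
        )
    result = pd.DataFrame.from_dict(out, orient="index").reindex(
        columns=list(PROFILE_CONDITIONS)
    )
    result.index.name = "participant_id"
    return result.sort_index()


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    silhouette: float


def _macqueen_kmeans(
    X: np.ndarray, centroids: np.ndarray, seed: int = 0, max_passes: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """MacQueen's sequential k-means from the given initial centroids.

    Points are visited one at a time in a seeded random order; each
    reassignment immediately updates the running means of the donor and
    recipient clusters. Converges to a fixed point where every centroid
    equals the mean of its members.
    """
    rng = np.random.default_rng(seed)
    k = centroids.shape[0]
    centroids = centroids.copy()
    labels = np.argmin(
        ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros_like(centroids)
    for j in range(k):
        sums[j] = X[labels == j].sum(axis=0)
    with np.errstate(invalid="ignore"):
        centroids = np.where(counts[:, None] > 0, sums / counts[:, None], centroids)

    order = np.arange(X.shape[0])
    for _ in range(max_passes):
        rng.shuffle(order)
        moved = 0
        for i in order:
            d = ((centroids - X[i]) ** 2).sum(axis=1)
            j_new = int(np.argmin(d))
            j_old = int(labels[i])
            if j_new == j_old:
                continue
            if counts[j_old] <= 1:
                continue  # never empty a cluster
            counts[j_old] -= 1
            sums[j_old] -= X[i]
            centroids[j_old] = sums[j_old] / counts[j_old]
            counts[j_new] += 1
            sums[j_new] += X[i]
            centroids[j_new] = sums[j_new] / counts[j_new]
            labels[i] = j_new
            moved += 1
        if moved == 0:
            break
    return labels, centroids


def cluster_profiles(
    profiles: pd.DataFrame | np.ndarray,
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
) -> ClusterResult:
    """Two-stage profile clustering.

    Stage 1: agglomerative hierarchical clustering (Ward linkage,
    Euclidean) cut at each k in `k_range`; the k with the highest mean
    silhouette wins. Stage 2: MacQueen sequential k-means initialized at
    the hierarchical clusters' means refines the centroids. Profiles
    with missing proportions are not allowed. With fewer than two
    distinct profiles, everything lands in a single cluster (k = 1).
    """
    X = profiles.to_numpy(dtype=float) if isinstance(profiles, pd.DataFrame) else np.asarray(profiles, dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("profiles contain missing proportions; complete cases only")
    n = X.shape[0]
    k_lo, k_hi = k_range
    if k_lo < 1:
        raise ValueError("k_range must start at 1 or above")
    if n < k_lo + 1:
        raise ValueError(f"{n} profiles cannot support k >= {k_lo}")

    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < 2 or k_hi == 1:
        return ClusterResult(
            k=1,
            labels=np.zeros(n, dtype=int),
            centroids=X.mean(axis=0, keepdims=True),
            silhouette=float("nan"),
        )

    Z = linkage(X, method="ward")
    best: Optional[tuple[float, int, np.ndarray]] = None
    for k in range(max(k_lo, 2), min(k_hi, n - 1, n_distinct) + 1):
        labels_k = fcluster(Z, t=k, criterion="maxclust") - 1
        if np.unique(labels_k).size < 2:
            continue
        score = float(silhouette_score(X, labels_k))
        if best is None or score > best[0]:
            best = (score, k, labels_k)
    if best is None:
        return ClusterResult(
            k=1,
            labels=np.zeros(n, dtype=int),
            centroids=X.mean(axis=0, keepdims=True),
            silhouette=float("nan"),
        )
    score, k, hier_labels = best
    init = np.vstack([X[hier_labels == j].mean(axis=0) for j in range(k)])
    labels, centroids = _macqueen_kmeans(X, init, seed=seed)
    return ClusterResult(k=k, labels=labels, centroids=centroids, silhouette=score)


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney rank-sum test (normal approximation, tie-corrected).

    Returns (U, p) with U = the number of (a, b) pairs with a < b plus
    half a count per tie. Two-sided p from the normal approximation with
    the tie-corrected variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r1 = float(ranks[:n1].sum())
    # U counting pairs a > b (+ half-ties), then flip to the a < b convention
    u_greater = r1 - n1 * (n1 + 1) / 2.0
    U = n1 * n2 - u_greater
    mean_u = n1 * n2 / 2.0
    N = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_u <= 0:
        return U, 1.0  # all values tied: no evidence either way
    z = (U - mean_u) / math.sqrt(var_u)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return U, p


def condition_summary(sr_table: pd.DataFrame) -> dict:
    """Response-count-weighted SR summaries per condition.

    Expects tidy columns ``participant_id``, ``movement_type``,
    ``stimulus_name``, ``sr`` and ``n_responses``. A beat-level trial
    holds twice the responses of a two-beat trial, so trial SR values are
    weighted by response count. Returns per-condition weighted means and
    the per-participant clap - bounce SR contrast (descriptive only).
    """
    df = sr_table.dropna(subset=["sr"]).copy()

    def wmean(grp: pd.DataFrame) -> float:
        w = grp["n_responses"].to_numpy(dtype=float)
        return float(np.average(grp["sr"].to_numpy(dtype=float), weights=w))

    by_condition = (
        df.groupby(["movement_type", "stimulus_name"])
        .apply(wmean, include_groups=False)
        .rename("weighted_mean_sr")
    )
    by_movement = (
        df.groupby("movement_type").apply(wmean, include_groups=False).rename("weighted_mean_sr")
    )
    per_participant = df.groupby(["participant_id", "movement_type"]).apply(
        wmean, include_groups=False
    )
    wide = per_participant.unstack("movement_type")
    contrast = (
        (wide["clap"] - wide["bounce"]).dropna()
        if {"bounce", "clap"} <= set(wide.columns)
        else pd.Series(dtype=float)
    )
    return {
        "by_condition": by_condition,
        "by_movement": by_movement,
        "clap_minus_bounce": contrast,
    }
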