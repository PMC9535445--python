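"""Meal clustering: Gower dissimilarity + partitioning around medoids (PAM).

Each meal is represented by a mixed feature vector — its NRF9.3 score plus
15 binary food-group presence indicators — and meals are clustered per
occasion category with PAM on the Gower dissimilarity, the cluster number
chosen by the same index-battery vote used for food grouping (candidate
range 4-15 by default).

Gower here averages 16 per-feature dissimilarities: the numeric score
contributes |Delta score| / (within-category score range), clamped to 1;
each binary contributes 0 on agreement and 1 on mismatch (symmetric coding —
joint absence of a food group is informative agreement between meals).

PAM is the classic two-phase algorithm: a greedy BUILD of the initial medoid
set, then SWAP steps that replace a medoid with a non-medoid whenever that
lowers the total dissimilarity to the nearest medoid, until no improving swap
exists.  Swaps take the best improvement, ties broken by the smallest
(medoid, candidate) index pair, so the result is deterministic for a given
matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grouping import KSelectionResult, choose_k, DEFAULT_INDICES
from .meals import Meal


class MealClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class MealFeatures:
    nrf93: float
    indicators: tuple[int, ...]  # one per food group, in catalog order


def meal_feature_vector(meal: Meal, group_ids: Sequence[str]) -> MealFeatures:
    """Score + binary presence indicator per food group (1 iff in signature)."""
    if meal.nrf93 is None:
        raise MealClusteringError("meal has no NRF9.3 score; run scoring first")
    return MealFeatures(
        nrf93=meal.nrf93,
        indicators=tuple(int(g in meal.group_signature) for g in group_ids),
    )


def gower(a: MealFeatures, b: MealFeatures, nrf_range: float) -> float:
    """Pairwise Gower dissimilarity in [0, 1]."""
    if len(a.indicators) != len(b.indicators):
        raise MealClusteringError("feature vectors of different lengths")
    delta = abs(a.nrf93 - b.nrf93)
    if nrf_range <= 0:
        if delta > 0:
            raise MealClusteringError("nrf_range <= 0 with unequal scores")
        num = 0.0
    else:
        num = min(1.0, delta / nrf_range)
    mismatches = sum(x != y for x, y in zip(a.indicators, b.indicators))
    return (num + mismatches) / (1 + len(a.indicators))


def gower_matrix(features: Sequence[MealFeatures], nrf_range: float | None = None) -> np.ndarray:
    """Square symmetric Gower matrix; the score range defaults to the
    observed within-set min-max (clamped per-pair to 1)."""
    scores = np.array([f.nrf93 for f in features], dtype=float)
    B = np.array([f.indicators for f in features], dtype=float)
    if nrf_range is None:
        nrf_range = float(scores.max() - scores.min()) if len(scores) else 0.0
    if nrf_range > 0:
        num = np.minimum(1.0, np.abs(scores[:, None] - scores[None, :]) / nrf_range)
    else:
        if len(scores) and np.ptp(scores) > 0:
            raise MealClusteringError("nrf_range <= 0 with unequal scores")
        num = np.zeros((len(scores), len(scores)))
    mism = (B[:, None, :] != B[None, :, :]).sum(axis=2)
    p = 1 + B.shape[1]
    return (num + mism) / p


@dataclass
class PAMResult:
    medoids: np.ndarray  # indices into the clustered set
    labels: np.ndarray  # meal index -> cluster index (into medoids)
    cost: float
    n_swaps: int


def _check_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise MealClusteringError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise MealClusteringError("dissimilarity matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise MealClusteringError("dissimilarity matrix must have zero diagonal")
    return D


def _build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD: the most central point first, then repeatedly the point
    that most reduces the total distance to the nearest medoid."""
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        nearest = np.minimum(nearest, D[nxt])
    return np.array(sorted(medoids))


def _swap(D: np.ndarray, med: np.ndarray) -> tuple[np.ndarray, float, int]:
    """SWAP phase: apply the best cost-reducing (medoid, candidate) swap until
    none exists; ties break toward the smaller index pair."""
    n, k = D.shape[0], len(med)
    n_swaps = 0
    while True:
        dist_to_med = D[:, med]  # (n, k)
        order = np.argsort(dist_to_med, axis=1)
        nearest_j = order[:, 0]
        d1 = dist_to_med[np.arange(n), nearest_j]
        d2 = dist_to_med[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        cost = d1.sum()

        best_delta, best_swap = -1e-12, None
        non_med = np.setdiff1d(np.arange(n), med)
        if len(non_med) == 0:  # k == n: nothing to swap
            break
        for j in range(k):
            # cost of serving each point if medoid j were removed
            base = np.where(nearest_j == j, d2, d1)
            # new cost for each candidate h: min(base, D[:, h])
            new_costs = np.minimum(base[:, None], D[:, non_med]).sum(axis=0)
            deltas = new_costs - cost
            h_best = int(np.argmin(deltas))
            if deltas[h_best] < best_delta:
                best_delta = float(deltas[h_best])
                best_swap = (j, int(non_med[h_best]))
        if best_swap is None:
            break
        med = med.copy()
        med[best_swap[0]] = best_swap[1]
        med = np.sort(med)
        n_swaps += 1
    return med, float(D[:, med].min(axis=1).sum()), n_swaps


def pam(D: np.ndarray, k: int, seed: int | None = None, n_restarts: int = 16) -> PAMResult:
    """BUILD + SWAP k-medoids with seeded random restarts.

    The deterministic BUILD start is always refined by SWAP; ``n_restarts``
    additional SWAP descents from random medoid sets (drawn from
    ``default_rng(seed)``) guard against the local optima single-start PAM is
    known to settle in on small unstructured matrices.  The best solution by
    cost wins (ties toward the BUILD solution, then the lexicographically
    smaller medoid set), so the result is deterministic given matrix and
    seed.
    """
    D = _check_matrix(D)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise MealClusteringError(f"k={k} out of range for n={n}")

    best_med, best_cost, total_swaps = None, np.inf, 0
    starts: list[np.ndarray] = [_build(D, k)]
    rng = np.random.default_rng(0 if seed is None else seed)
    for _ in range(n_restarts):
        starts.append(np.sort(rng.choice(n, size=k, replace=False)))
    for start in starts:
        med, cost, n_swaps = _swap(D, start)
        total_swaps += n_swaps
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12
            and best_med is not None
            and tuple(med) < tuple(best_med)
        ):
            best_med, best_cost = med, cost
    med = best_med
    dist_to_med = D[:, med]
    labels = np.argmin(dist_to_med, axis=1)
    cost = float(dist_to_med[np.arange(n), labels].sum())
    return PAMResult(medoids=med, labels=labels, cost=cost, n_swaps=total_swaps)


def brute_force_pam(D: np.ndarray, k: int) -> tuple[tuple[int, ...], float]:
    """Exhaustive optimum over all C(n, k) medoid sets — the oracle PAM is
    checked against on small instances."""
    D = _check_matrix(D)
    n = D.shape[0]
    best_set, best_cost = None, np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = D[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_set = cost, medoids
    return best_set, float(best_cost)


def cluster_category(
    meals: Sequence[Meal],
    group_ids: Sequence[str],
    k_min: int = 4,
    k_max: int = 15,
    min_cluster_size: int = 1,
    indices: Sequence[str] = DEFAULT_INDICES,
) -> tuple[PAMResult, KSelectionResult]:
    """Cluster the meals of one occasion category into generic-meal groups.

    Builds the mixed feature vectors, the Gower matrix, selects k by the
    index-battery vote (PAM as the clusterer) and returns the final PAM fit
    plus the selection diagnostics.
    """
    if len(meals) < k_min:
        raise MealClusteringError(
            f"category has {len(meals)} meals, fewer than k_min={k_min}"
        )
    feats = [meal_feature_vector(m, group_ids) for m in meals]
    D = gower_matrix(feats)
    if D.max() == 0:
        warnings.warn("degenerate category: all meals identical; using k_min")
    if len(meals) - 1 < k_min:
        # too few meals for any index to discriminate; fit k_min directly
        warnings.warn(
            f"category has only {len(meals)} meals; clustering at k={k_min} "
            "without an index vote"
        )
        fit = pam(D, min(k_min, len(meals)))
        sel = KSelectionResult(
            k_min=k_min,
            k_max=k_max,
            per_index_k={},
            votes={k_min: 0},
            chosen_k=min(k_min, len(meals)),
            fallback_applied=False,
            warnings=["category too small for index vote"],
        )
        return fit, sel
    sel = choose_k(
        D,
        k_min,
        min(k_max, len(meals)),
        lambda M, k: pam(M, k).labels,
        min_cluster_size=min_cluster_size,
        metric="precomputed",
        indices=indices,
    )
    fit = pam(D, sel.chosen_k)
    return fit, sel
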