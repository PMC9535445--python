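"""Data-driven food groups.

Foods are first placed on the shelves of the Irish food pyramid; within each
shelf (except fats/spreads/oils, left whole, and the residual ``other``
shelf, split manually into alcoholic beverages, non-alcoholic beverages and
miscellaneous foods) k-means is run on the 12 NRF9.3 nutrients expressed per
100 kcal and z-standardized within the shelf.

The number of clusters is not fixed a priori: a battery of internal validity
indices each proposes a k in a candidate range (default 2-10) and the modal
proposal wins, ties going to the smaller k.  If the winning solution leaves a
cluster smaller than ``min_cluster_size`` foods, the next-most-voted k is
used instead (the fallback the small-shelf data demand).

The same ``choose_k`` machinery is reused by :mod:`genericmeals.mealclust`
with PAM as the clusterer and a Gower matrix as input, so every index here is
defined purely from a dissimilarity matrix and a label vector.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .diary import FoodDB, FoodRecord
from .nutrients import NRF_NUTRIENTS

CLUSTERED_SHELVES = (
    "veg_salad_fruit",
    "cereal_bread_potato",
    "milk_yogurt_cheese",
    "meat_fish_eggs_beans_nuts",
    "high_fat_sugar_salt",
)
FATS_SHELF = "fats_spreads_oils"
OTHER_SHELF = "other"
OTHER_GROUPS = ("alcoholic_bev", "nonalcoholic_bev", "misc")


class GroupingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

@dataclass
class FoodFeatureMatrix:
    """Standardized per-100 kcal nutrient features for the foods of one shelf."""

    food_ids: list[str]
    nutrient_ids: tuple[str, ...]
    X: np.ndarray  # standardized
    means: np.ndarray
    sds: np.ndarray
    constant_columns: list[str] = field(default_factory=list)


def nutrient_features(
    foods: Iterable[FoodRecord], nutrient_ids: Sequence[str] = NRF_NUTRIENTS
) -> FoodFeatureMatrix:
    """Per-100 kcal amounts of ``nutrient_ids``, z-standardized per column.

    feature = amount_per_100g * 100 / energy_kcal_per_100g.  Constant columns
    (SD 0) are set to all zeros with a warning: they carry no contrast and
    would otherwise divide by zero.
    """
    foods = list(foods)
    ids = [f.food_id for f in foods]
    raw = np.empty((len(foods), len(nutrient_ids)))
    for i, f in enumerate(foods):
        energy = f.energy_kcal_per100g
        if not energy > 0:
            raise GroupingError(
                f"food {f.food_id!r} has no energy; exclude energy-free foods upstream"
            )
        for j, nid in enumerate(nutrient_ids):
            raw[i, j] = f.per100g.get(nid) * 100.0 / energy
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    X = np.zeros_like(raw)
    constant = []
    tol = 1e-12 * np.maximum(1.0, np.abs(means))  # guards float round-trip jitter
    for j, nid in enumerate(nutrient_ids):
        if sds[j] > tol[j]:
            X[:, j] = (raw[:, j] - means[j]) / sds[j]
        else:
            constant.append(nid)
    if constant:
        warnings.warn(f"constant feature columns set to zero: {constant}")
    return FoodFeatureMatrix(
        food_ids=ids,
        nutrient_ids=tuple(nutrient_ids),
        X=X,
        means=means,
        sds=sds,
        constant_columns=constant,
    )


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

@dataclass
class KMeansFit:
    labels: np.ndarray
    centers: np.ndarray
    wcss: float


def kmeans(matrix: np.ndarray, k: int, seed: int = 0, n_restarts: int = 25) -> KMeansFit:
    """Lloyd k-means, best of ``n_restarts`` seeded restarts by total
    within-cluster sum of squares; initial centers drawn uniformly from the
    data points."""
    X = np.asarray(matrix, dtype=float)
    if k < 1:
        raise GroupingError("k must be >= 1")
    if k > X.shape[0]:
        raise GroupingError(f"k={k} exceeds n_rows={X.shape[0]}")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    return KMeansFit(labels=km.labels_.copy(), centers=km.cluster_centers_.copy(), wcss=float(km.inertia_))


# ---------------------------------------------------------------------------
# Cluster-number index battery
# ---------------------------------------------------------------------------

def _cluster_stats(D: np.ndarray, labels: np.ndarray) -> dict:
    """Shared per-partition quantities, all from the dissimilarity matrix.

    For Euclidean distances the pairwise identity
    WCSS_c = (1/n_c) * sum_{i<j in c} d_ij^2 makes ``W`` the pooled
    within-cluster sum of squares.
    """
    n = len(labels)
    ks = np.unique(labels)
    iu = np.triu_indices(n, k=1)
    d_all = D[iu]
    same = labels[iu[0]] == labels[iu[1]]
    d_within = d_all[same]
    d_between = d_all[~same]

    W = 0.0
    sizes, medoids, mean_to_medoid, diameters = [], [], [], []
    for c in ks:
        idx = np.where(labels == c)[0]
        sub = D[np.ix_(idx, idx)]
        nc = len(idx)
        sizes.append(nc)
        W += (sub**2).sum() / (2 * nc)
        m_local = int(np.argmin(sub.sum(axis=1)))
        medoids.append(int(idx[m_local]))
        mean_to_medoid.append(sub[m_local].sum() / nc)
        diameters.append(sub.max() if nc > 1 else 0.0)
    T = float((d_all**2).sum()) / n
    return {
        "n": n,
        "k": len(ks),
        "sizes": np.array(sizes),
        "W": W,
        "T": T,
        "B": T - W,
        "d_within": d_within,
        "d_between": d_between,
        "medoids": np.array(medoids),
        "mean_to_medoid": np.array(mean_to_medoid),
        "diameters": np.array(diameters),
    }


def _safe(x: float) -> float:
    return float(x) if np.isfinite(x) else np.nan


def _idx_silhouette(D, labels, st):
    if st["k"] < 2 or st["k"] >= st["n"]:
        return np.nan
    return _safe(silhouette_score(D, labels, metric="precomputed"))


def _idx_calinski_harabasz(D, labels, st):
    n, k, W, B = st["n"], st["k"], st["W"], st["B"]
    if k < 2 or n == k or W <= 0:
        return np.nan
    return _safe((B / (k - 1)) / (W / (n - k)))


def _idx_davies_bouldin(D, labels, st):
    k = st["k"]
    if k < 2:
        return np.nan
    S = st["mean_to_medoid"]
    M = D[np.ix_(st["medoids"], st["medoids"])]
    R = np.full((k, k), -np.inf)
    for i in range(k):
        for j in range(k):
            if i != j:
                R[i, j] = (S[i] + S[j]) / M[i, j] if M[i, j] > 0 else np.inf
    return _safe(np.mean(np.max(R, axis=1)))


def _idx_dunn(D, labels, st):
    if st["k"] < 2:
        return np.nan
    dmax = st["diameters"].max()
    if len(st["d_between"]) == 0:
        return np.nan
    dmin = st["d_between"].min()
    if dmax == 0:
        return np.nan
    return _safe(dmin / dmax)


def _idx_c_index(D, labels, st):
    dw, da = st["d_within"], np.sort(np.concatenate([st["d_within"], st["d_between"]]))
    nw = len(dw)
    if nw == 0:
        return np.nan
    s_min = da[:nw].sum()
    s_max = da[-nw:].sum()
    if s_max == s_min:
        return np.nan
    return _safe((dw.sum() - s_min) / (s_max - s_min))


def _idx_mcclain_rao(D, labels, st):
    dw, db = st["d_within"], st["d_between"]
    if len(dw) == 0 or len(db) == 0 or db.mean() == 0:
        return np.nan
    return _safe(dw.mean() / db.mean())


def _idx_point_biserial(D, labels, st):
    dw, db = st["d_within"], st["d_between"]
    d_all = np.concatenate([dw, db])
    sd = d_all.std()
    if sd == 0 or len(dw) == 0 or len(db) == 0:
        return np.nan
    nt = len(d_all)
    return _safe((db.mean() - dw.mean()) * np.sqrt(len(dw) * len(db) / nt**2) / sd)


def _idx_xie_beni(D, labels, st):
    if st["k"] < 2:
        return np.nan
    M = D[np.ix_(st["medoids"], st["medoids"])]
    sep = M[np.triu_indices(st["k"], k=1)].min()
    if sep == 0:
        return np.nan
    W2 = 0.0
    for c, m in zip(np.unique(labels), st["medoids"]):
        idx = np.where(labels == c)[0]
        W2 += (D[idx, m] ** 2).sum()
    return _safe(W2 / (st["n"] * sep**2))


def _idx_wb_ratio(D, labels, st):
    if st["B"] <= 0:
        return np.nan
    return _safe(st["k"] * st["W"] / st["B"])


#: value-per-k indices, with the direction of the vote.
_VALUE_INDICES: dict[str, tuple[Callable, str]] = {
    "silhouette": (_idx_silhouette, "max"),
    "calinski_harabasz": (_idx_calinski_harabasz, "max"),
    "davies_bouldin": (_idx_davies_bouldin, "min"),
    "dunn": (_idx_dunn, "max"),
    "c_index": (_idx_c_index, "min"),
    "mcclain_rao": (_idx_mcclain_rao, "min"),
    "point_biserial": (_idx_point_biserial, "max"),
    "xie_beni": (_idx_xie_beni, "min"),
    "wb_ratio": (_idx_wb_ratio, "min"),
}

#: indices voting from the trajectory of W(k): Ball-Hall's largest drop of
#: W/k, and Hartigan's rule (smallest k with H(k) <= 10).
_TRAJECTORY_INDICES = ("ball_hall", "hartigan")

DEFAULT_INDICES = tuple(_VALUE_INDICES) + _TRAJECTORY_INDICES


@dataclass
class KSelectionResult:
    k_min: int
    k_max: int
    per_index_k: dict[str, int]
    votes: dict[int, int]
    chosen_k: int
    fallback_applied: bool
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k_min": self.k_min,
            "k_max": self.k_max,
            "per_index_k": self.per_index_k,
            "votes": {str(k): v for k, v in self.votes.items()},
            "chosen_k": self.chosen_k,
            "fallback_applied": self.fallback_applied,
            "warnings": self.warnings,
        }


def _vote(values: Mapping[int, float], direction: str) -> int | None:
    ks = [k for k, v in values.items() if np.isfinite(v)]
    if not ks:
        return None
    if direction == "max":
        return max(ks, key=lambda k: (values[k], -k))
    return min(ks, key=lambda k: (values[k], k))


def _trajectory_votes(W: Mapping[int, float], n: int, ks: Sequence[int]) -> dict[str, int | None]:
    votes: dict[str, int | None] = {}
    # Ball-Hall: largest drop of mean within-cluster dispersion W/k.
    bh = {k: W[k] / k for k in ks}
    drops = {k: bh[prev] - bh[k] for prev, k in zip(ks, ks[1:])}
    votes["ball_hall"] = max(drops, key=lambda k: (drops[k], -k)) if drops else None
    # Hartigan: smallest k with (W(k)/W(k+1) - 1)(n - k - 1) <= 10.
    hart = None
    for prev, nxt in zip(ks, ks[1:]):
        if W[nxt] <= 0:
            hart = prev
            break
        h = (W[prev] / W[nxt] - 1.0) * (n - prev - 1)
        if h <= 10.0:
            hart = prev
            break
    votes["hartigan"] = hart if hart is not None else (ks[-1] if len(ks) > 1 else None)
    return votes


def resolve_votes(
    votes: Mapping[int, int],
    cluster_sizes: Callable[[int], Sequence[int]],
    min_cluster_size: int,
) -> tuple[int, bool, list[str]]:
    """Pick the modal k; ties to the smaller k; if the winning partition has a
    cluster below ``min_cluster_size``, advance to the next-most-voted k,
    exhausting candidates before falling back to the raw winner."""
    if not votes:
        raise GroupingError("empty vote set")
    order = sorted(votes, key=lambda k: (-votes[k], k))
    msgs: list[str] = []
    for rank, k in enumerate(order):
        if min(cluster_sizes(k)) >= min_cluster_size:
            if rank > 0:
                msgs.append(
                    f"k={order[0]} produced a cluster smaller than {min_cluster_size}; "
                    f"fell back to next-most-voted k={k}"
                )
            return k, rank > 0, msgs
    msgs.append(
        f"all voted k produce clusters smaller than {min_cluster_size}; "
        f"keeping most-voted k={order[0]}"
    )
    return order[0], False, msgs


def choose_k(
    data: np.ndarray,
    k_min: int,
    k_max: int,
    clusterer: Callable[[np.ndarray, int], np.ndarray],
    min_cluster_size: int = 1,
    metric: str = "euclidean",
    indices: Sequence[str] = DEFAULT_INDICES,
) -> KSelectionResult:
    """Index-battery majority vote over the candidate cluster numbers.

    ``data`` is a feature matrix (``metric='euclidean'``) or a square
    dissimilarity matrix (``metric='precomputed'``); ``clusterer(data, k)``
    returns a label vector.  Each index proposes one k; the mode of the
    proposals wins (ties toward the smaller k), subject to the
    ``min_cluster_size`` fallback.
    """
    data = np.asarray(data, dtype=float)
    D = data if metric == "precomputed" else squareform(pdist(data))
    n = D.shape[0]
    msgs: list[str] = []
    if k_max > n:
        raise GroupingError(f"k_max={k_max} exceeds n={n}")
    if k_max >= n and n > 1:
        k_max = n - 1
        msgs.append(f"k_max clipped to n-1={k_max} (indices need k < n)")
    if k_min > k_max:
        raise GroupingError(f"empty candidate range [{k_min}, {k_max}]")

    if D.max() == 0:
        msgs.append("all points identical; indices degenerate, returning k_min")
        return KSelectionResult(
            k_min=k_min,
            k_max=k_max,
            per_index_k={},
            votes={k_min: 0},
            chosen_k=k_min,
            fallback_applied=False,
            warnings=msgs,
        )

    ks = list(range(k_min, k_max + 1))
    labelings: dict[int, np.ndarray] = {k: np.asarray(clusterer(data, k)) for k in ks}
    stats = {k: _cluster_stats(D, labelings[k]) for k in ks}

    per_index_k: dict[str, int] = {}
    for name in indices:
        if name in _VALUE_INDICES:
            fn, direction = _VALUE_INDICES[name]
            values = {k: fn(D, labelings[k], stats[k]) for k in ks}
            v = _vote(values, direction)
            if v is not None:
                per_index_k[name] = v
    if any(name in _TRAJECTORY_INDICES for name in indices):
        W = {k: stats[k]["W"] for k in ks}
        for name, v in _trajectory_votes(W, n, ks).items():
            if name in indices and v is not None:
                per_index_k[name] = v

    if not per_index_k:
        raise GroupingError("empty vote set: every index abstained")
    votes: dict[int, int] = {}
    for v in per_index_k.values():
        votes[v] = votes.get(v, 0) + 1

    def sizes(k: int) -> Sequence[int]:
        return np.bincount(labelings[k], minlength=1)[np.unique(labelings[k])]

    chosen, fallback, fb_msgs = resolve_votes(votes, sizes, min_cluster_size)
    msgs.extend(fb_msgs)
    return KSelectionResult(
        k_min=k_min,
        k_max=k_max,
        per_index_k=per_index_k,
        votes=votes,
        chosen_k=chosen,
        fallback_applied=fallback,
        warnings=msgs,
    )


# ---------------------------------------------------------------------------
# Shelf-wise food grouping
# ---------------------------------------------------------------------------

@dataclass
class FoodGroupAssignment:
    food_to_group: dict[str, str]
    groups: dict[str, tuple[str, str]]  # group_id -> (shelf, description)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def group_of(self, food_id: str) -> str:
        return self.food_to_group[food_id]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (fid, gid, *self.groups[gid])
                for fid, gid in self.food_to_group.items()
            ],
            columns=["food_id", "group_id", "shelf", "description"],
        )


@dataclass
class GroupingConfig:
    k_range: tuple[int, int] = (2, 10)
    min_cluster_size: int = 4
    n_restarts: int = 25
    seed: int = 0
    indices: tuple[str, ...] = DEFAULT_INDICES


def build_food_groups(
    food_db: FoodDB, config: GroupingConfig | None = None
) -> tuple[FoodGroupAssignment, dict[str, KSelectionResult]]:
    """Derive the food groups: k-means subgroups per clustered shelf, one
    group for fats/spreads/oils, manual subgroups for the ``other`` shelf.

    Returns the assignment and the per-shelf k-selection diagnostics.
    """
    config = config or GroupingConfig()
    k_min, k_max = config.k_range
    by_shelf: dict[str, list[FoodRecord]] = {}
    for rec in food_db:
        by_shelf.setdefault(rec.pyramid_shelf, []).append(rec)

    food_to_group: dict[str, str] = {}
    groups: dict[str, tuple[str, str]] = {}
    selections: dict[str, KSelectionResult] = {}

    for shelf in CLUSTERED_SHELVES:
        foods = by_shelf.get(shelf, [])
        if not foods:
            continue
        if len(foods) < 2 * config.min_cluster_size:
            raise GroupingError(
                f"shelf {shelf!r} has only {len(foods)} foods; too few to cluster"
            )
        feats = nutrient_features(foods)

        def clusterer(X, k, _seed=config.seed, _r=config.n_restarts):
            return kmeans(X, k, seed=_seed, n_restarts=_r).labels

        sel = choose_k(
            feats.X,
            k_min,
            min(k_max, len(foods)),
            clusterer,
            min_cluster_size=config.min_cluster_size,
            metric="euclidean",
            indices=config.indices,
        )
        selections[shelf] = sel
        fit = kmeans(feats.X, sel.chosen_k, seed=config.seed, n_restarts=config.n_restarts)
        counts = np.bincount(fit.labels, minlength=sel.chosen_k)
        for j in range(sel.chosen_k):
            gid = f"{shelf}:c{j + 1}"
            groups[gid] = (
                shelf,
                f"k-means cluster {j + 1} of {sel.chosen_k} within {shelf} "
                f"({counts[j]} foods)",
            )
        for food, lab in zip(foods, fit.labels):
            food_to_group[food.food_id] = f"{shelf}:c{lab + 1}"

    fats = by_shelf.get(FATS_SHELF, [])
    if fats:
        gid = f"{FATS_SHELF}:all"
        groups[gid] = (FATS_SHELF, f"fats, spreads and oils, not split ({len(fats)} foods)")
        for food in fats:
            food_to_group[food.food_id] = gid

    others = by_shelf.get(OTHER_SHELF, [])
    if others:
        descr = {
            "alcoholic_bev": "alcoholic beverages",
            "nonalcoholic_bev": "non-alcoholic beverages",
            "misc": "soups, sauces and miscellaneous foods",
        }
        for sub in OTHER_GROUPS:
            members = [f for f in others if f.other_subgroup == sub]
            if members:
                gid = f"{OTHER_SHELF}:{sub}"
                groups[gid] = (OTHER_SHELF, f"{descr[sub]} ({len(members)} foods)")
                for food in members:
                    food_to_group[food.food_id] = gid

    return FoodGroupAssignment(food_to_group=food_to_group, groups=groups), selections


def brute_force_kmeans(X: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exhaustive best partition by WCSS — the small-instance oracle k-means
    is checked against in the test suite (n <= ~10 only)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best_labels, best = None, np.inf
    for assignment in itertools.product(range(k), repeat=n):
        labels = np.array(assignment)
        if len(np.unique(labels)) != k:
            continue
        wcss = 0.0
        for c in range(k):
            pts = X[labels == c]
            wcss += ((pts - pts.mean(axis=0)) ** 2).sum()
        if wcss < best - 1e-12:
            best, best_labels = wcss, labels
    return best_labels, float(best)
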