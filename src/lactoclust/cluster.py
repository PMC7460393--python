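"""k-medoids clustering of lactation-curve shapes.

The similarity measure is the root-mean-square (RMS) Euclidean distance
between two aligned curves,

    d(A, B) = sqrt( (1/N) * sum_i (m_A,i - m_B,i)**2 ),

an ordinary Euclidean distance scaled by 1/sqrt(N), hence a metric.
Clustering minimizes the total within-cluster distance to the medoid
(the member minimizing the summed distance to all members of its
cluster), via Voronoi-style alternation (assign, then update medoids)
with a squared-distance-weighted initialization in the k-means++ style:
the first center is uniform, every further center is drawn with
probability proportional to D(x)^2, the squared distance to the nearest
center already chosen.

The number of clusters is selected by the elbow method, automated as the
point of maximum perpendicular distance from the chord joining the first
and last points of the min-max-scaled (k, J(k)) profile.

All ties (assignment, medoid update, best restart, elbow) break to the
lowest index, so results are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ClusteringResult",
    "ElbowProfile",
    "distance_rms",
    "pairwise_distances",
    "init_medoids",
    "kmedoids",
    "elbow_select_k",
]


@dataclass
class ClusteringResult:
    """A fitted k-medoids partition.

    ``labels[i]`` indexes into ``medoid_indices``; ``objective`` is the
    summed RMS distance of every curve to its medoid, recomputable from
    ``labels`` and ``medoid_indices`` to 1e-12.
    """

    k: int
    labels: np.ndarray
    medoid_indices: np.ndarray
    objective: float
    n_iter: int
    seed: int | None
    restarts: int


@dataclass
class ElbowProfile:
    """Objective-vs-k profile with the automatically chosen elbow."""

    ks: np.ndarray
    objectives: np.ndarray
    chosen_k: int
    seed: int | None
    restarts: int


def distance_rms(a, b) -> float:
    """RMS Euclidean distance between two equal-length curves."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("curves must be 1-D and the same length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pairwise_distances(matrix) -> np.ndarray:
    """Symmetric zero-diagonal matrix of RMS distances between rows."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, N = X.shape
    if n == 1:
        return np.zeros((1, 1))
    return squareform(pdist(X, metric="euclidean") / np.sqrt(N))


def init_medoids(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Squared-distance-weighted initial medoids (k-means++ scheme).

    The first index is uniform; each subsequent index is drawn with
    probability proportional to the squared distance to the nearest
    already-chosen center. Points coinciding with a chosen center have
    probability zero unless every remaining distance is zero, in which
    case the draw is uniform over the remaining points.
    """
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    chosen = [int(rng.integers(n))]
    while len(chosen) < k:
        d_near = D[:, chosen].min(axis=1)
        w = d_near**2
        w[chosen] = 0.0
        total = w.sum()
        if total <= 0.0:
            p = np.ones(n)
            p[chosen] = 0.0
            p /= p.sum()
        else:
            p = w / total
        chosen.append(int(rng.choice(n, p=p)))
    return np.array(chosen, dtype=int)


def _assign(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # medoids are kept sorted, so argmin's first-minimum tie rule resolves
    # ties to the lowest medoid index
    return np.argmin(D[:, medoids], axis=1)


def _objective(D: np.ndarray, medoids: np.ndarray, labels: np.ndarray) -> float:
    return float(D[np.arange(D.shape[0]), medoids[labels]].sum())


def kmedoids(
    D: np.ndarray,
    k: int,
    seed: int | None = 0,
    max_iter: int = 100,
    restarts: int = 10,
    init=None,
) -> ClusteringResult:
    """Best-of-restarts Voronoi k-medoids on a precomputed distance matrix.

    Each restart alternates (a) assignment of every point to its nearest
    medoid and (b) replacement of each medoid by the cluster member that
    minimizes the summed distance to the cluster, until the medoid set is
    stable or ``max_iter`` is reached. The within-restart objective is
    non-increasing by construction (asserted). A medoid left with no
    members is re-seeded with the point currently farthest from its own
    medoid. The restart with the lowest objective wins; ties go to the
    earliest restart.

    ``init`` fixes the initial medoid set explicitly (k distinct row
    indices); it implies a single run and ignores the seed, which is
    useful for auditing the alternation against exhaustive search.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if init is not None:
        init = np.asarray(init, dtype=int)
        if len(np.unique(init)) != k or np.any(init < 0) or np.any(init >= n):
            raise ValueError(f"init must be {k} distinct indices in 0..{n - 1}")
        restarts = 1
    rng = np.random.default_rng(seed)
    best: ClusteringResult | None = None
    for r in range(restarts):
        medoids = np.sort(init) if init is not None else np.sort(init_medoids(D, k, rng))
        prev_obj = np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            labels = _assign(D, medoids)
            # re-seed empty clusters with the farthest point from its medoid;
            # a re-seed may raise the objective, so it suspends the
            # monotonicity assertion for this iteration
            reseeded = False
            for j in range(k):
                if not np.any(labels == j):
                    point_dists = D[np.arange(n), medoids[labels]]
                    if point_dists.max() <= 0.0:
                        continue  # duplicate-heavy data: cluster stays empty
                    reseeded = True
                    medoids = medoids.copy()
                    medoids[j] = int(np.argmax(point_dists))
                    medoids = np.sort(medoids)
                    labels = _assign(D, medoids)
            new_medoids = medoids.copy()
            for j in range(k):
                members = np.flatnonzero(labels == j)
                if len(members) == 0:
                    continue
                sums = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[j] = members[int(np.argmin(sums))]
            new_medoids = np.sort(new_medoids)
            labels = _assign(D, new_medoids)
            obj = _objective(D, new_medoids, labels)
            assert reseeded or obj <= prev_obj + 1e-9, "k-medoids objective increased"
            if np.array_equal(new_medoids, medoids):
                medoids = new_medoids
                break
            medoids = new_medoids
            prev_obj = obj
        labels = _assign(D, medoids)
        obj = _objective(D, medoids, labels)
        if best is None or obj < best.objective - 1e-15:
            best = ClusteringResult(
                k=k,
                labels=labels,
                medoid_indices=medoids,
                objective=obj,
                n_iter=n_iter,
                seed=seed,
                restarts=restarts,
            )
    assert best is not None
    return best


def elbow_select_k(
    matrix,
    k_range=range(2, 11),
    seed: int | None = 0,
    restarts: int = 10,
    max_iter: int = 100,
) -> ElbowProfile:
    """Run k-medoids over a range of k and pick the elbow of J(k).

    The elbow is the k whose point on the min-max-scaled (k, J(k))
    profile lies farthest (perpendicular distance) from the chord joining
    the profile's endpoints. A profile with no curvature (all distances
    ~0, e.g. J exactly linear in k) falls back to the smallest k.
    """
    ks = np.array(sorted(k_range), dtype=int)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if ks.max() > X.shape[0]:
        raise ValueError("max(k_range) exceeds the number of curves")
    D = pairwise_distances(X)
    objectives = np.array(
        [
            kmedoids(D, int(k), seed=None if seed is None else seed + int(k),
                     max_iter=max_iter, restarts=restarts).objective
            for k in ks
        ]
    )
    chosen = _kneedle(ks, objectives)
    return ElbowProfile(ks=ks, objectives=objectives, chosen_k=int(chosen),
                        seed=seed, restarts=restarts)


def _kneedle(ks: np.ndarray, J: np.ndarray) -> int:
    x = (ks - ks.min()) / max(ks.max() - ks.min(), 1)
    rng_j = J.max() - J.min()
    y = (J - J.min()) / rng_j if rng_j > 0 else np.zeros_like(J)
    x0, y0 = x[0], y[0]
    x1, y1 = x[-1], y[-1]
    chord = np.hypot(x1 - x0, y1 - y0)
    if chord == 0:
        return int(ks[0])
    dist = np.abs((x1 - x0) * (y0 - y) - (x0 - x) * (y1 - y0)) / chord
    if np.all(dist < 1e-12):
        return int(ks[0])
    return int(ks[int(np.argmax(dist))])
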