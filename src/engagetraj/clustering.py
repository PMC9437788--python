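"""k-medoids clustering of FPC scores with prediction-strength selection.

PAM (Partitioning Around Medoids) with the classical BUILD + SWAP phases
is the inner solver; CLARA (Clustering Large Applications) runs PAM on
random subsamples — carrying the incumbent medoids into later subsamples —
and keeps the medoid set with the lowest full-data dissimilarity.  The
number of groups is chosen by prediction strength: the data are split into
random halves, both halves are clustered, test points are classified by
their nearest train-half medoid, and the statistic is the worst-case
proportion of test-cluster point pairs whose co-membership the train
classification reproduces.  Candidate k must reach a prediction-strength
threshold (default 0.6) and keep every group at or above a minimum share
of the sample (default 5%); the largest qualifying k wins.

Groups are named by engagement persistence: the last week in which the
group's mean weekly log-in days stay at or above 1.0 ("1-week users",
"4-week users", ...).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from engagetraj.preprocess import DailyEngagementMatrix, weekly_login_sums


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _assign(points: np.ndarray, medoid_rows: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid labels (ties -> lowest medoid position) and total cost."""
    D = cdist(medoid_rows, points)
    labels = D.argmin(axis=0)
    return labels, float(D.min(axis=0).sum())


def pam(points: np.ndarray, k: int, rng=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Partitioning Around Medoids with Euclidean dissimilarity.

    BUILD greedily seeds the k medoids; SWAP repeatedly applies the best
    (medoid, non-medoid) exchange while the total dissimilarity strictly
    decreases.  BUILD + SWAP is only 1-swap optimal, so tiny instances
    (at most 5000 medoid subsets) are solved exactly by enumeration
    instead — same contract, guaranteed optimum.  Deterministic: ties
    resolve to the lowest index.  Returns (medoid indices sorted
    ascending, labels, total dissimilarity).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    D = cdist(points, points)

    if math.comb(n, k) <= 5000:
        best = min(
            itertools.combinations(range(n), k),
            key=lambda c: (D[list(c)].min(axis=0).sum(), c),
        )
        med = np.array(best)
        labels, total = _assign(points, points[med])
        return med, labels, total

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dmin = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        dmin = np.minimum(dmin, D[c])

    # SWAP (best improvement)
    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        Dm = D[med]                       # k x n
        nearest = Dm.argmin(axis=0)
        dmin = Dm[nearest, np.arange(n)]
        if k > 1:
            part = np.partition(Dm, 1, axis=0)
            dsec = part[1]
        else:
            dsec = np.full(n, np.inf)
        cost = dmin.sum()
        others = np.setdiff1d(np.arange(n), med)
        if len(others) == 0:
            return med, nearest, float(cost)
        best = (cost - 1e-12, None)
        for mi, m in enumerate(medoids):
            base = np.where(nearest == mi, dsec, dmin)      # cost without m
            newcosts = np.minimum(base[None, :], D[others]).sum(axis=1)
            j = int(np.argmin(newcosts))
            if newcosts[j] < best[0]:
                best = (newcosts[j], (mi, int(others[j])))
        if best[1] is None:
            labels, total = _assign(points, points[med])
            return med, labels, total
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)


def clara(
    points: np.ndarray,
    k: int,
    n_subsamples: int = 5,
    subsample_size: int | None = None,
    rng=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """CLARA: PAM on subsamples, scored on the full data.

    Default subsample size is min(n, 40 + 2k) (the classical recipe);
    the incumbent best medoids are forced into each subsequent subsample.
    With subsample_size >= n this reduces exactly to PAM on all points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if subsample_size is None:
        subsample_size = min(n, 40 + 2 * k)
    if subsample_size < k:
        raise ValueError("subsample_size must be >= k")
    if subsample_size >= n:
        return pam(points, k)
    rng = _as_rng(rng)
    best: tuple[float, np.ndarray] | None = None
    for _ in range(n_subsamples):
        forced = best[1] if best is not None else np.array([], dtype=int)
        pool = np.setdiff1d(np.arange(n), forced)
        extra = rng.choice(pool, size=subsample_size - len(forced), replace=False)
        sub = np.sort(np.concatenate([forced, extra]))
        sub_med, _, _ = pam(points[sub], k)
        med = sub[sub_med]
        _, total = _assign(points, points[med])
        if best is None or total < best[0]:
            best = (total, np.sort(med))
    med = best[1]
    labels, total = _assign(points, points[med])
    return med, labels, total


def prediction_strength(
    points: np.ndarray,
    k: int,
    n_splits: int = 10,
    rng=None,
    **clara_kwargs,
) -> float:
    """Mean over random half-splits of the worst-case co-assignment rate.

    Per split: cluster the train and test halves separately; classify test
    points by their nearest train medoid; for each test cluster with at
    least two members, compute the fraction of its point pairs that the
    train classification keeps together; take the minimum over test
    clusters.  k = 1 is defined as 1.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points")
    if k == 1:
        return 1.0
    rng = _as_rng(rng)
    values = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        train, test = points[perm[:half]], points[perm[half:]]
        train_med, _, _ = clara(train, k, rng=rng, **clara_kwargs)
        _, test_labels, _ = clara(test, k, rng=rng, **clara_kwargs)
        by_train = cdist(train[train_med], test).argmin(axis=0)
        cluster_ps = []
        for j in range(k):
            members = by_train[test_labels == j]
            nj = len(members)
            if nj < 2:
                continue
            counts = np.bincount(members, minlength=k)
            same = (counts * (counts - 1)).sum()
            cluster_ps.append(same / (nj * (nj - 1)))
        values.append(min(cluster_ps) if cluster_ps else 1.0)
    return float(np.mean(values))


@dataclass
class SelectKResult:
    """Diagnostics of the cluster-number search."""

    chosen_k: int
    prediction_strengths: dict[int, float]
    group_sizes: dict[int, np.ndarray]
    separations: dict[int, float]
    candidates: list[int]
    fell_back: bool


def _separation(points: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Min pairwise distance between group means over pooled within-group SD."""
    means = np.stack([points[labels == g].mean(axis=0) for g in range(k)])
    ss = sum(((points[labels == g] - means[g]) ** 2).sum() for g in range(k))
    pooled = np.sqrt(ss / max(len(points) - k, 1))
    dists = cdist(means, means)
    off = dists[np.triu_indices(k, 1)]
    return float(off.min() / pooled) if pooled > 0 else np.inf


def select_k(
    points: np.ndarray,
    k_range: Iterable[int] = range(2, 7),
    ps_threshold: float = 0.6,
    min_group_frac: float = 0.05,
    n_splits: int = 10,
    rng=None,
    **clara_kwargs,
) -> SelectKResult:
    """Choose the number of groups by prediction strength + size rule.

    Candidates are the k with prediction strength >= ps_threshold whose
    full-data CLARA solution keeps every group at >= min_group_frac of the
    sample; the largest candidate is chosen.  If none qualifies, the k
    with maximal prediction strength is returned with a warning.  A
    separation diagnostic (min between-group mean distance over pooled
    within-group SD) is reported per k, not enforced.
    """
    k_range = sorted(set(k_range))
    if not k_range:
        raise ValueError("k_range must be nonempty")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    rng = _as_rng(rng)
    seeds = rng.integers(0, 2**31 - 1, size=2 * len(k_range))
    ps: dict[int, float] = {}
    sizes: dict[int, np.ndarray] = {}
    seps: dict[int, float] = {}
    for i, k in enumerate(k_range):
        ps[k] = prediction_strength(points, k, n_splits,
                                    rng=np.random.default_rng(seeds[2 * i]),
                                    **clara_kwargs)
        _, labels, _ = clara(points, k, rng=np.random.default_rng(seeds[2 * i + 1]),
                             **clara_kwargs)
        sizes[k] = np.bincount(labels, minlength=k)
        seps[k] = _separation(points, labels, k)
    candidates = [k for k in k_range
                  if ps[k] >= ps_threshold and sizes[k].min() >= min_group_frac * n]
    if candidates:
        chosen, fell_back = max(candidates), False
    else:
        chosen = max(ps, key=lambda k: (ps[k], -k))
        fell_back = True
        warnings.warn(
            f"no k in {k_range} met prediction strength >= {ps_threshold} with "
            f"all groups >= {min_group_frac:.0%} of n; falling back to k={chosen} "
            f"with maximal prediction strength {ps[chosen]:.3f}",
            stacklevel=2,
        )
    return SelectKResult(chosen, ps, sizes, seps, candidates, fell_back)


@dataclass
class ClusterSolution:
    """A k-medoids solution plus group naming and summaries."""

    k: int
    medoid_indices: np.ndarray
    labels: np.ndarray
    total_dissimilarity: float
    prediction_strength: float | None = None
    group_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]
    group_names: list[str] | None = None
    group_weekly_means: np.ndarray | None = None
    persistence: np.ndarray | None = None
    order: np.ndarray | None = None        # group indices sorted by persistence

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.medoid_indices = np.asarray(self.medoid_indices)
        if self.group_sizes is None:
            self.group_sizes = np.bincount(self.labels, minlength=self.k)
        if (self.labels[self.medoid_indices] != np.arange(self.k)).any():
            raise ValueError("medoids must be labeled to their own cluster")

    @property
    def n(self) -> int:
        return len(self.labels)

    def groups_by_persistence(self) -> list[int]:
        """Group indices from least to most persistent (requires naming)."""
        if self.order is None:
            raise ValueError("call name_groups first")
        return list(self.order)


def solve(points: np.ndarray, k: int, rng=None, **clara_kwargs) -> ClusterSolution:
    """Cluster score vectors into k groups with CLARA."""
    med, labels, total = clara(points, k, rng=rng, **clara_kwargs)
    return ClusterSolution(k=k, medoid_indices=med, labels=labels,
                           total_dissimilarity=total)


def name_groups(
    solution: ClusterSolution, matrix: DailyEngagementMatrix
) -> ClusterSolution:
    """Attach persistence-based names and weekly summaries to a solution.

    Persistence of a group is the last (1-based) week whose group mean
    weekly log-in days is >= 1.0 (0 if never).  Groups are ordered by
    ascending persistence, ties broken by total mean log-ins, and named
    "<persistence>-week users".
    """
    if len(solution.labels) != matrix.n:
        raise ValueError("solution labels must align with matrix rows")
    weekly = weekly_login_sums(matrix.values)
    k = solution.k
    means = np.stack([weekly[solution.labels == g].mean(axis=0) for g in range(k)])
    persistence = np.zeros(k, dtype=int)
    for g in range(k):
        hits = np.flatnonzero(means[g] >= 1.0)
        persistence[g] = hits[-1] + 1 if len(hits) else 0
    totals = means.sum(axis=1)
    order = np.array(sorted(range(k), key=lambda g: (persistence[g], totals[g], g)))
    solution.group_names = [f"{persistence[g]}-week users" for g in range(k)]
    solution.group_weekly_means = means
    solution.persistence = persistence
    solution.order = order
    return solution
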