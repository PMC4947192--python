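"""Partition Around Medoids and the per-area two-level cluster hierarchy.

PAM is the classic Kaufman–Rousseeuw k-medoids algorithm: a greedy BUILD
phase picks k medoids one at a time, each minimising the summed distance of
all points to their nearest chosen medoid; the SWAP phase then repeatedly
applies the single (medoid, non-medoid) exchange with the largest cost
decrease until none improves.  Medoids are always actual members of the
clustered set, never averaged fictitious points, which is what lets a new
case be classified by comparing against stored cases only.

The hierarchy mirrors the recommender's retrieval path: for every
speech-language area, a first level clusters the corpus by area-relevant
medical features (level-1 distance) and, nested inside each first-level
cluster, a second level re-clusters its members by the fine-grained
evaluation-plus-ages metric (level-2 distance).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .model import AreaCatalogue, PatientCase
from .similarity import MetricConfig, pairwise_level1, pairwise_level2

__all__ = [
    "PartitionAroundMedoids",
    "ClusterLevel",
    "AreaHierarchy",
    "ClusterHierarchy",
    "pam",
    "choose_k",
    "build_hierarchy",
]


def _validate_distance_matrix(dist: np.ndarray, k: int) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {d.shape}")
    n = d.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if (d < 0).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    return d


def _assign(d: np.ndarray, medoids: Sequence[int]) -> np.ndarray:
    """Index (into medoids) of each point's nearest medoid; ties → first listed."""
    sub = d[:, list(medoids)]
    order = np.argsort(list(medoids), kind="stable")
    # evaluate candidates in ascending medoid index so argmin tie-breaks low
    sub_sorted = sub[:, order]
    return order[np.argmin(sub_sorted, axis=1)]


def _build_phase(d: np.ndarray, k: int, rng: np.random.Generator | None) -> list[int]:
    n = d.shape[0]
    candidates = np.arange(n)
    if rng is not None:
        candidates = rng.permutation(n)  # optional tie-shuffle of scan order
    medoids: list[int] = []
    nearest = np.full(n, np.inf)
    for _ in range(k):
        best_c, best_cost = -1, np.inf
        for c in candidates:
            if c in medoids:
                continue
            cost = np.minimum(nearest, d[:, c]).sum()
            # strict improvement keeps the first (lowest-index) candidate on ties
            if cost < best_cost - 1e-12:
                best_c, best_cost = int(c), cost
        medoids.append(best_c)
        nearest = np.minimum(nearest, d[:, best_c])
    return sorted(medoids)


def _swap_phase(
    d: np.ndarray, medoids: list[int], max_iter: int
) -> tuple[list[int], float, list[float]]:
    n = d.shape[0]
    medoids = sorted(medoids)
    trace: list[float] = []
    for _ in range(max_iter):
        sub = d[:, medoids]
        part = np.argsort(sub, axis=1, kind="stable")
        d1 = sub[np.arange(n), part[:, 0]]
        cost = d1.sum()
        trace.append(float(cost))
        if len(medoids) == 1:
            d2 = np.full(n, np.inf)
        else:
            d2 = sub[np.arange(n), part[:, 1]]
        best_delta, best_swap = -1e-12, None
        for mi, m in enumerate(medoids):
            is_mine = part[:, 0] == mi
            base = np.where(is_mine, d2, d1)  # cost per point if m is removed
            # total cost after swapping m for every candidate h, vectorised over h
            newd = np.minimum(d, base[:, None]).sum(axis=0)
            deltas = newd - cost
            deltas[medoids] = np.inf
            h = int(np.argmin(deltas))  # argmin keeps lowest h on ties
            # strict improvement keeps lowest (m, h) pair across ties
            if deltas[h] < best_delta:
                best_delta, best_swap = float(deltas[h]), (m, h)
        if best_swap is None:
            break
        m, h = best_swap
        medoids = sorted(set(medoids) - {m} | {h})
    sub = d[:, medoids]
    total = sub.min(axis=1).sum()
    trace.append(float(total))
    return medoids, float(total), trace


class PartitionAroundMedoids(ClusterMixin, BaseEstimator):
    """k-medoids clustering by BUILD + best-improvement SWAP on a precomputed
    distance matrix.

    Parameters
    ----------
    n_clusters : int
        Number of medoids k.
    max_iter : int
        Cap on SWAP exchanges.
    n_restarts : int
        Additional seeded SWAP descents from random initial medoid sets;
        the best-cost solution wins (the deterministic BUILD solution is
        kept on ties).  Guards against the rare swap-stable local optimum.
    shuffle_build : bool
        If True, the BUILD scan order is shuffled with ``random_state``;
        the default keeps the algorithm fully deterministic.
    random_state : int or None
        Seed for the optional BUILD shuffle.

    Attributes
    ----------
    medoid_indices_ : ndarray of shape (n_clusters,)
        Sorted indices of the chosen medoids.
    labels_ : ndarray of shape (n,)
        Index into ``medoid_indices_`` of each point's nearest medoid
        (ties broken toward the lowest medoid index).
    inertia_ : float
        Total cost: sum over points of distance to their medoid.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        max_iter: int = 300,
        n_restarts: int = 10,
        shuffle_build: bool = False,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.shuffle_build = shuffle_build
        self.random_state = random_state

    def fit(self, X, y=None):
        d = _validate_distance_matrix(X, self.n_clusters)
        n, k = d.shape[0], self.n_clusters
        rng = (
            np.random.default_rng(self.random_state) if self.shuffle_build else None
        )
        medoids = _build_phase(d, k, rng)
        medoids, total, trace = _swap_phase(d, medoids, self.max_iter)
        # SWAP stops at a swap-stable medoid set, which on occasion is a local
        # optimum; seeded random restarts of the SWAP descent escape those.
        # The BUILD solution is kept unless a restart is strictly better.
        if self.n_restarts > 0 and k < n:
            rrng = np.random.default_rng(
                0 if self.random_state is None else self.random_state
            )
            for _ in range(self.n_restarts):
                start = sorted(rrng.choice(n, size=k, replace=False).tolist())
                cand, cand_total, cand_trace = _swap_phase(d, start, self.max_iter)
                if cand_total < total - 1e-12:
                    medoids, total, trace = cand, cand_total, cand_trace
        self.medoid_indices_ = np.asarray(medoids, dtype=int)
        self.labels_ = _assign(d, medoids)
        self.inertia_ = total
        #: total cost at each SWAP iteration of the winning run (non-increasing)
        self.cost_trace_ = trace
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ClusterLevel:
    """One flat medoid partition: medoid case IDs, the assignment of every
    clustered case to its medoid, and the summed within-cluster cost."""

    medoid_ids: list[str]
    assignment: dict[str, str]
    total_cost: float

    def members(self, medoid_id: str) -> list[str]:
        return [cid for cid, m in self.assignment.items() if m == medoid_id]


def pam(
    dist: np.ndarray,
    k: int,
    seed: int | None = None,
    ids: Sequence[str] | None = None,
    shuffle_build: bool = False,
    n_restarts: int = 10,
) -> ClusterLevel:
    """Cluster a symmetric distance matrix into k medoids.

    ``ids`` names the rows (defaults to stringified indices); assignment
    ties are broken toward the lowest row index, so callers wanting
    case-ID lexicographic tie-breaking should order rows accordingly.
    """
    est = PartitionAroundMedoids(
        n_clusters=k, n_restarts=n_restarts, shuffle_build=shuffle_build,
        random_state=seed,
    ).fit(dist)
    names = [str(i) for i in range(dist.shape[0])] if ids is None else list(ids)
    medoid_ids = [names[i] for i in est.medoid_indices_]
    assignment = {
        names[i]: names[est.medoid_indices_[lab]] for i, lab in enumerate(est.labels_)
    }
    return ClusterLevel(medoid_ids=medoid_ids, assignment=assignment, total_cost=est.inertia_)


def choose_k(
    dist: np.ndarray,
    k_range: Iterable[int],
    seed: int | None = None,
) -> int:
    """Pick k from ``k_range`` maximising mean silhouette width; ties → smallest k.

    A degenerate (all-zero) matrix yields the smallest k in range with a warning.
    """
    d = np.asarray(dist, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    n = d.shape[0]
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k_range {ks} must lie within [2, n-1] for n={n}")
    if not d.any():
        warnings.warn("degenerate all-zero distance matrix; returning smallest k")
        return ks[0]
    best_k, best_s = ks[0], -np.inf
    for k in ks:
        level = pam(d, k, seed=seed)
        labels = np.array([level.medoid_ids.index(level.assignment[str(i)]) for i in range(n)])
        if len(set(labels.tolist())) < 2:
            continue
        s = silhouette_score(d, labels, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


@dataclass
class AreaHierarchy:
    """Two-level medoid structure for one speech-language area."""

    area: str
    level1: ClusterLevel
    #: second-level partition of each first-level cluster, keyed by its medoid ID
    level2: dict[str, ClusterLevel]


@dataclass
class ClusterHierarchy:
    """Per-area two-level medoid hierarchy over a training corpus."""

    areas: dict[str, AreaHierarchy]
    metric: MetricConfig
    case_ids: list[str]
    k1: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "metric": {"scale_weight": self.metric.scale_weight,
                       "age_norm_months": self.metric.age_norm_months},
            "case_ids": self.case_ids,
            "k1": self.k1,
            "areas": {
                name: {
                    "level1": vars(ah.level1),
                    "level2": {m: vars(cl) for m, cl in ah.level2.items()},
                }
                for name, ah in self.areas.items()
            },
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClusterHierarchy":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        areas = {
            name: AreaHierarchy(
                area=name,
                level1=ClusterLevel(**entry["level1"]),
                level2={m: ClusterLevel(**cl) for m, cl in entry["level2"].items()},
            )
            for name, entry in doc["areas"].items()
        }
        return cls(
            areas=areas,
            metric=MetricConfig(**doc["metric"]),
            case_ids=doc["case_ids"],
            k1={k: int(v) for k, v in doc.get("k1", {}).items()},
        )


def _auto_k(d: np.ndarray, k: int | str, k_max: int, seed: int | None) -> int:
    n = d.shape[0]
    if k != "auto":
        return int(k)
    if n <= 3:
        return 1 if n <= 2 else 2
    hi = min(k_max, n - 1)
    if hi < 2 or not d.any():
        return 1 if not d.any() else 2
    return choose_k(d, range(2, hi + 1), seed=seed)


def build_hierarchy(
    corpus: list[PatientCase],
    catalogue: AreaCatalogue,
    cfg: MetricConfig | None = None,
    k1: int | str = "auto",
    k2: int | str = "auto",
    k_max: int = 8,
    seed: int | None = None,
) -> ClusterHierarchy:
    """Build the per-area two-level medoid hierarchy over a training corpus.

    For every area: PAM over the level-1 (medical-feature) distances, then
    PAM inside each first-level cluster over the level-2
    (evaluation + cognitive-age) distances.  First-level clusters with fewer
    than 3 members are kept whole as a single second-level cluster.  Cases
    are sorted by ``case_id`` before clustering so all tie-breaks are
    lexicographic and the result is reproducible.
    """
    if len(corpus) < 2:
        raise ValueError("corpus must contain at least 2 cases")
    missing = [c.case_id for c in corpus if c.plan is None]
    if missing:
        raise ValueError(f"training cases without plans: {missing[:5]}")
    cfg = cfg or MetricConfig()
    cases = sorted(corpus, key=lambda c: c.case_id)
    ids = [c.case_id for c in cases]
    by_id = {c.case_id: c for c in cases}
    areas: dict[str, AreaHierarchy] = {}
    k1_used: dict[str, int] = {}
    for area in catalogue.area_names:
        d1 = pairwise_level1(cases, area, catalogue)
        ka = _auto_k(d1, k1, k_max, seed)
        level1 = pam(d1, ka, seed=seed, ids=ids)
        k1_used[area] = ka
        level2: dict[str, ClusterLevel] = {}
        for medoid in level1.medoid_ids:
            member_ids = sorted(level1.members(medoid))
            members = [by_id[cid] for cid in member_ids]
            if len(members) < 3:
                # tiny cluster: keep as one second-level cluster around its medoid
                d2 = pairwise_level2(members, area, catalogue, cfg)
                level2[medoid] = pam(d2, 1, ids=member_ids)
                continue
            d2 = pairwise_level2(members, area, catalogue, cfg)
            kb = _auto_k(d2, k2, k_max, seed)
            level2[medoid] = pam(d2, kb, seed=seed, ids=member_ids)
        areas[area] = AreaHierarchy(area=area, level1=level1, level2=level2)
    return ClusterHierarchy(areas=areas, metric=cfg, case_ids=ids, k1=k1_used)
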