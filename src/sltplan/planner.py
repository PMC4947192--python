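"""Case-based assembly of five-area therapy plans.

A new patient is classified per speech-language area by walking the medoid
hierarchy: nearest first-level medoid under the medical-feature distance,
nearest second-level medoid under the evaluation-plus-ages distance, then
K-nearest-neighbour retrieval inside that second-level cluster.  The area
subplan is copied (or set-combined, when several prior cases are equally
distant) from the retrieved cases' stored subplans, and every subplan
carries provenance: which prior cases it came from, the coincidence percent
of the binary evaluations, and the evaluation dimensions on which query and
source agree.

``TherapyPlanRecommender`` wraps training (hierarchy construction) and
prediction (plan generation) in the scikit-learn estimator idiom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .clustering import ClusterHierarchy, build_hierarchy
from .model import (
    AreaCatalogue,
    PatientCase,
    Provenance,
    TherapyPlan,
    TherapySubplan,
    default_catalogue,
)
from .similarity import MetricConfig, cross_level1, cross_level2

__all__ = [
    "Neighbor",
    "RetrievalResult",
    "TherapyPlanRecommender",
    "classify_case",
    "assemble_subplan",
    "generate_plan",
    "render_plan_report",
    "plan_report_frame",
]

#: distances are rationals built from small integer sums; exact at this scale
TIE_TOL = 1e-9

MODES = ("nearest", "superset", "intersection", "disjunction")


@dataclass(frozen=True)
class Neighbor:
    case_id: str
    distance: float
    coincidence_percent: float
    matched_features: tuple[str, ...]


@dataclass
class RetrievalResult:
    """Ranked prior cases for one area, with tie groups of equidistant neighbours."""

    area: str
    neighbors: list[Neighbor]
    tie_groups: list[list[str]] = field(default_factory=list)

    @property
    def top_tie_group(self) -> list[str]:
        return self.tie_groups[0] if self.tie_groups else []


def _group_ties(neighbors: list[Neighbor], tol: float) -> list[list[str]]:
    groups: list[list[str]] = []
    last = None
    for nb in neighbors:
        if last is not None and abs(nb.distance - last) <= tol:
            groups[-1].append(nb.case_id)
        else:
            groups.append([nb.case_id])
        last = nb.distance
    return groups


def _matched_dimensions(
    query: PatientCase, source: PatientCase, area: str, catalogue: AreaCatalogue
) -> tuple[str, ...]:
    dims = catalogue.area(area).dimensions
    q = np.asarray(query.evaluation.areas[area])
    s = np.asarray(source.evaluation.areas[area])
    return tuple(name for name, qv, sv in zip(dims, q, s) if qv == sv)


def classify_case(
    new_case: PatientCase,
    hierarchy: ClusterHierarchy,
    corpus: list[PatientCase],
    catalogue: AreaCatalogue,
    cfg: MetricConfig | None = None,
    k: int = 1,
    tie_tol: float = TIE_TOL,
) -> dict[str, RetrievalResult]:
    """Hierarchy-guided K-nearest retrieval of prior cases, per area.

    If the selected second-level cluster holds fewer than ``k`` members the
    search falls back to the whole first-level cluster.  Neighbour ranking
    ties are broken by case ID.
    """
    cfg = cfg or hierarchy.metric
    catalogue.validate_case(new_case)
    by_id = {c.case_id: c for c in corpus}
    missing = [cid for cid in hierarchy.case_ids if cid not in by_id]
    if missing:
        raise ValueError(f"hierarchy references cases absent from corpus: {missing[:5]}")
    results: dict[str, RetrievalResult] = {}
    for area in catalogue.area_names:
        ah = hierarchy.areas[area]
        # 1. nearest first-level medoid under the medical-feature distance
        l1_medoids = sorted(ah.level1.medoid_ids)
        d1 = cross_level1([new_case], [by_id[m] for m in l1_medoids], area, catalogue)[0]
        m1 = l1_medoids[int(np.argmin(d1))]
        # 2. nearest second-level medoid under the evaluation+ages distance
        l2 = ah.level2[m1]
        l2_medoids = sorted(l2.medoid_ids)
        d2 = cross_level2(
            [new_case], [by_id[m] for m in l2_medoids], area, catalogue, cfg
        )[0]
        m2 = l2_medoids[int(np.argmin(d2))]
        pool_ids = sorted(l2.members(m2))
        if len(pool_ids) < k:  # fall back to the whole first-level cluster
            pool_ids = sorted(ah.level1.members(m1))
        pool = [by_id[cid] for cid in pool_ids]
        dists = cross_level2([new_case], pool, area, catalogue, cfg)[0]
        order = np.lexsort((pool_ids, dists))

        def neighbor(i: int) -> Neighbor:
            src = pool[i]
            coin = (
                1.0
                - float(
                    np.abs(
                        np.asarray(new_case.evaluation.areas[area])
                        - np.asarray(src.evaluation.areas[area])
                    ).mean()
                )
            ) * 100.0
            return Neighbor(
                case_id=src.case_id,
                distance=float(dists[i]),
                coincidence_percent=coin,
                matched_features=_matched_dimensions(new_case, src, area, catalogue),
            )

        ranked = [neighbor(int(i)) for i in order[:k]]
        # extend the last rank across its full tie group
        cutoff = ranked[-1].distance
        for i in order[k:]:
            if abs(float(dists[int(i)]) - cutoff) > tie_tol:
                break
            ranked.append(neighbor(int(i)))
        results[area] = RetrievalResult(
            area=area, neighbors=ranked, tie_groups=_group_ties(ranked, tie_tol)
        )
    return results


def _combine(sets: list[list[str]], mode: str) -> list[str]:
    """Order-preserving set combination across tied sources."""
    if mode == "superset":
        out, seen = [], set()
        for s in sets:
            for item in s:
                if item not in seen:
                    seen.add(item)
                    out.append(item)
        return out
    if mode == "intersection":
        common = set(sets[0]).intersection(*map(set, sets[1:])) if sets else set()
        return [item for item in sets[0] if item in common]
    if mode == "disjunction":
        counts: dict[str, int] = {}
        order: list[str] = []
        for s in sets:
            for item in set(s):
                if item not in counts:
                    counts[item] = 0
                    order.append(item)
                counts[item] += 1
        return [item for item in order if counts[item] == 1]
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def assemble_subplan(
    result: RetrievalResult,
    corpus: list[PatientCase],
    mode: str = "nearest",
) -> TherapySubplan:
    """Turn a retrieval result into an area subplan with provenance.

    ``nearest`` copies the top-ranked neighbour's subplan verbatim; the set
    modes combine the activity/exercise sets of the rank-1 tie group
    (superset = union, intersection = common items, disjunction =
    symmetric difference).
    """
    if not result.neighbors:
        raise ValueError(f"area {result.area!r}: empty retrieval (untrained area?)")
    by_id = {c.case_id: c for c in corpus}
    area = result.area

    def subplan_of(cid: str) -> TherapySubplan:
        case = by_id[cid]
        if case.plan is None or area not in case.plan.subplans:
            raise ValueError(f"source case {cid} lacks a subplan for area {area!r}")
        return case.plan.subplans[area]

    if mode == "nearest":
        sources = [result.neighbors[0].case_id]
    elif mode in MODES:
        sources = sorted(result.top_tie_group)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")

    act_sets = [list(subplan_of(cid).activities) for cid in sources]
    exe_sets = [list(subplan_of(cid).exercises) for cid in sources]
    if mode == "nearest":
        activities, exercises = act_sets[0], exe_sets[0]
    else:
        activities = _combine(act_sets, mode)
        exercises = _combine(exe_sets, mode)

    nb_by_id = {nb.case_id: nb for nb in result.neighbors}
    provenance = [
        Provenance(
            source_case_id=cid,
            coincidence_percent=nb_by_id[cid].coincidence_percent,
            matched_features=list(nb_by_id[cid].matched_features),
        )
        for cid in sources
    ]
    return TherapySubplan(
        area=area, activities=activities, exercises=exercises, provenance=provenance
    )


def generate_plan(
    new_case: PatientCase,
    hierarchy: ClusterHierarchy,
    corpus: list[PatientCase],
    catalogue: AreaCatalogue,
    cfg: MetricConfig | None = None,
    k: int = 1,
    mode: str = "nearest",
    tie_tol: float = TIE_TOL,
) -> TherapyPlan:
    """Assemble the full five-area plan for one new case."""
    results = classify_case(new_case, hierarchy, corpus, catalogue, cfg, k, tie_tol)
    subplans = {
        area: assemble_subplan(results[area], corpus, mode=mode)
        for area in catalogue.area_names
    }
    return TherapyPlan(subplans=subplans)


def plan_report_frame(plan: TherapyPlan, catalogue: AreaCatalogue) -> pd.DataFrame:
    """Tabular plan view: one row per area — activities and source-case sentences."""
    rows = []
    for area in catalogue.area_names:
        sp = plan.subplans[area]
        sources = "; ".join(
            f"Case {p.source_case_id}: {p.coincidence_percent:.0f}% coincidence "
            f"({len(p.matched_features)} shared evaluation features)"
            for p in sp.provenance
        )
        rows.append(
            {
                "area": area,
                "activities": " | ".join(sp.activities),
                "exercises": " | ".join(sp.exercises),
                "source_subplans": sources,
            }
        )
    return pd.DataFrame(rows, columns=["area", "activities", "exercises", "source_subplans"])


def render_plan_report(plan: TherapyPlan, catalogue: AreaCatalogue) -> str:
    """Deterministic human-readable report (markdown-ish table by area)."""
    frame = plan_report_frame(plan, catalogue)
    lines = ["# Therapy plan", ""]
    for _, row in frame.iterrows():
        lines.append(f"## {row['area']}")
        sp = plan.subplans[row["area"]]
        for a in sp.activities:
            lines.append(f"- activity: {a}")
        for e in sp.exercises:
            lines.append(f"- exercise: {e}")
        for p in sp.provenance:
            lines.append(
                f"- source: Case {p.source_case_id} "
                f"({p.coincidence_percent:.0f}% coincidence in the evaluation)"
            )
        lines.append("")
    return "\n".join(lines)


class TherapyPlanRecommender(BaseEstimator):
    """Case-based therapy-plan recommender in the scikit-learn idiom.

    ``fit`` takes a list of :class:`PatientCase` with plans, builds the
    per-area two-level medoid hierarchy; ``predict`` maps new cases (plans
    ignored) to :class:`TherapyPlan` objects with provenance.

    Parameters
    ----------
    scale_weight, age_norm_months
        Level-2 metric knobs (see :class:`~sltplan.similarity.MetricConfig`).
    k1, k2
        First/second-level cluster counts, or ``"auto"`` for silhouette
        selection.
    k_max
        Upper bound of the automatic k search.
    n_neighbors
        K of the nearest-neighbour retrieval (default 1 with tie expansion).
    mode
        Subplan assembly: ``nearest`` (copy top neighbour) or ``superset`` /
        ``intersection`` / ``disjunction`` over the rank-1 tie group.
    tie_tol
        Absolute tolerance for distance ties.
    random_state
        Seed forwarded to clustering (only used by the optional BUILD shuffle).
    """

    def __init__(
        self,
        catalogue: AreaCatalogue | None = None,
        scale_weight: float = 1.0,
        age_norm_months: int = 216,
        k1: int | str = "auto",
        k2: int | str = "auto",
        k_max: int = 8,
        n_neighbors: int = 1,
        mode: str = "nearest",
        tie_tol: float = TIE_TOL,
        random_state: int | None = None,
    ):
        self.catalogue = catalogue
        self.scale_weight = scale_weight
        self.age_norm_months = age_norm_months
        self.k1 = k1
        self.k2 = k2
        self.k_max = k_max
        self.n_neighbors = n_neighbors
        self.mode = mode
        self.tie_tol = tie_tol
        self.random_state = random_state

    def _metric(self) -> MetricConfig:
        return MetricConfig(
            scale_weight=self.scale_weight, age_norm_months=self.age_norm_months
        )

    def fit(self, X: list[PatientCase], y=None) -> "TherapyPlanRecommender":
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        self.catalogue_ = self.catalogue or default_catalogue()
        for case in X:
            self.catalogue_.validate_case(case)
        self.cases_ = sorted(X, key=lambda c: c.case_id)
        self.hierarchy_ = build_hierarchy(
            self.cases_,
            self.catalogue_,
            cfg=self._metric(),
            k1=self.k1,
            k2=self.k2,
            k_max=self.k_max,
            seed=self.random_state,
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "hierarchy_"):
            raise RuntimeError("recommender is not fitted; call fit() first")

    def retrieve(self, case: PatientCase) -> dict[str, RetrievalResult]:
        """Per-area ranked prior cases for one query."""
        self._check_fitted()
        return classify_case(
            case,
            self.hierarchy_,
            self.cases_,
            self.catalogue_,
            self._metric(),
            k=self.n_neighbors,
            tie_tol=self.tie_tol,
        )

    def predict_one(self, case: PatientCase) -> TherapyPlan:
        self._check_fitted()
        return generate_plan(
            case,
            self.hierarchy_,
            self.cases_,
            self.catalogue_,
            self._metric(),
            k=self.n_neighbors,
            mode=self.mode,
            tie_tol=self.tie_tol,
        )

    def predict(self, X: list[PatientCase]) -> list[TherapyPlan]:
        """Generate one five-area plan per query case."""
        return [self.predict_one(case) for case in X]
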