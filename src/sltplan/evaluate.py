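"""Cross-validation harness with overlap-based proxy scoring.

Each round trains the recommender on k−1 folds and generates plans for the
held-out fold's cases (their stored plans hidden), then scores every area
subplan by the Jaccard overlap of activity-ID sets against the case's stored
subplan.  A subplan is *valid* when its Jaccard reaches the threshold τ; a
whole plan is valid only when all five subplans are (a plan containing an
invalid subplan is discarded).  The report tables are areas × rounds with a
trailing average column.

These Jaccard-based figures are a computable stand-in for clinician Likert
ratings of generated plans, which depend on expert judgment and are out of
scope here; exercises are scored by a second, separate Jaccard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AreaCatalogue, PatientCase, TherapySubplan
from .planner import TherapyPlanRecommender

__all__ = [
    "FoldSpec",
    "SubplanScore",
    "CrossValidationReport",
    "kfold_split",
    "jaccard",
    "score_subplan",
    "cross_validate",
]


@dataclass(frozen=True)
class FoldSpec:
    index: int
    case_ids: tuple[str, ...]


@dataclass(frozen=True)
class SubplanScore:
    case_id: str
    area: str
    jaccard: float
    exercise_jaccard: float
    valid: bool


def kfold_split(
    case_ids: list[str],
    k: int,
    seed: int | None = None,
    labels: dict[str, str] | None = None,
) -> list[FoldSpec]:
    """Seeded shuffle then round-robin deal into k folds of near-equal size.

    With ``labels`` (case_id → stratum) the deal is round-robin within each
    stratum, approximately balancing strata across folds.
    """
    n = len(case_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds number of cases n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    shuffled = [case_ids[i] for i in rng.permutation(n)]
    folds: list[list[str]] = [[] for _ in range(k)]
    if labels is None:
        for i, cid in enumerate(shuffled):
            folds[i % k].append(cid)
    else:
        strata: dict[str, list[str]] = {}
        for cid in shuffled:
            strata.setdefault(labels[cid], []).append(cid)
        i = 0
        for group in strata.values():
            for cid in group:
                folds[i % k].append(cid)
                i += 1
    return [FoldSpec(index=i, case_ids=tuple(f)) for i, f in enumerate(folds)]


def jaccard(a: set[str], b: set[str]) -> float:
    """|a ∩ b| / |a ∪ b|, with empty ∪ empty defined as 1."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def score_subplan(
    generated: TherapySubplan, reference: TherapySubplan, tau: float = 0.5,
    case_id: str = "",
) -> SubplanScore:
    """Jaccard of activity-ID sets (validity) plus a separate exercise Jaccard."""
    j = jaccard(set(generated.activities), set(reference.activities))
    je = jaccard(set(generated.exercises), set(reference.exercises))
    return SubplanScore(
        case_id=case_id, area=generated.area, jaccard=j, exercise_jaccard=je,
        valid=j >= tau,
    )


@dataclass
class CrossValidationReport:
    """Per-area and whole-plan results of a k-fold cross-validation run."""

    per_area_jaccard: pd.DataFrame  # areas × rounds + Average
    per_area_validity: pd.DataFrame  # percent, areas × rounds + Average
    whole_plan_validity: pd.Series  # percent per round + Average
    scores: list[SubplanScore] = field(default_factory=list)
    leakage_violations: int = 0

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_area_jaccard.to_csv(out / "per_area_scores.csv")
        validity = self.per_area_validity.copy()
        validity.loc["overall plans"] = self.whole_plan_validity
        validity.to_csv(out / "validity.csv")
        pd.DataFrame([vars(s) for s in self.scores]).to_csv(
            out / "subplan_scores.csv", index=False
        )


def _audit_leakage(
    recommender: TherapyPlanRecommender,
    held_out: list[PatientCase],
    neighbor_ids: set[str],
) -> int:
    """Count held-out IDs appearing among hierarchy medoids or retrieved neighbours."""
    held = {c.case_id for c in held_out}
    medoids: set[str] = set()
    for ah in recommender.hierarchy_.areas.values():
        medoids.update(ah.level1.medoid_ids)
        for cl in ah.level2.values():
            medoids.update(cl.medoid_ids)
    return len(held & (medoids | neighbor_ids))


def cross_validate(
    corpus: list[PatientCase],
    catalogue: AreaCatalogue,
    k_folds: int = 4,
    tau: float = 0.5,
    seed: int | None = None,
    labels: dict[str, str] | None = None,
    **recommender_params,
) -> CrossValidationReport:
    """Run the k-fold protocol and tabulate per-area Jaccard and validity.

    ``recommender_params`` are forwarded to :class:`TherapyPlanRecommender`.
    Training cases must all carry plans; a held-out case's own plan is never
    visible to the round that scores it (audited, reported as
    ``leakage_violations``).
    """
    ids = [c.case_id for c in corpus]
    by_id = {c.case_id: c for c in corpus}
    folds = kfold_split(ids, k_folds, seed=seed, labels=labels)
    areas = catalogue.area_names
    round_names = [f"round {f.index + 1}" for f in folds]
    jac = pd.DataFrame(index=areas, columns=round_names, dtype=float)
    val = pd.DataFrame(index=areas, columns=round_names, dtype=float)
    whole = pd.Series(index=round_names, dtype=float)
    scores: list[SubplanScore] = []
    leakage = 0

    for fold in folds:
        held = [by_id[cid] for cid in fold.case_ids]
        train = [c for c in corpus if c.case_id not in set(fold.case_ids)]
        rec = TherapyPlanRecommender(**recommender_params).fit(train)
        neighbor_ids: set[str] = set()
        fold_scores: dict[str, list[SubplanScore]] = {a: [] for a in areas}
        plan_valid: list[bool] = []
        for case in held:
            query = case.model_copy(update={"plan": None})
            retrieved = rec.retrieve(query)
            for res in retrieved.values():
                neighbor_ids.update(nb.case_id for nb in res.neighbors)
            plan = rec.predict_one(query)
            case_valid = True
            for area in areas:
                s = score_subplan(
                    plan.subplans[area], case.plan.subplans[area], tau, case.case_id
                )
                fold_scores[area].append(s)
                scores.append(s)
                case_valid &= s.valid
            plan_valid.append(case_valid)
        leakage += _audit_leakage(rec, held, neighbor_ids)
        col = f"round {fold.index + 1}"
        for area in areas:
            jac.loc[area, col] = float(np.mean([s.jaccard for s in fold_scores[area]]))
            val.loc[area, col] = 100.0 * float(
                np.mean([s.valid for s in fold_scores[area]])
            )
        whole[col] = 100.0 * float(np.mean(plan_valid))

    jac["average"] = jac[round_names].mean(axis=1)
    val["average"] = val[round_names].mean(axis=1)
    whole["average"] = whole[round_names].mean()
    return CrossValidationReport(
        per_area_jaccard=jac,
        per_area_validity=val,
        whole_plan_validity=whole,
        scores=scores,
        leakage_violations=leakage,
    )
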