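"""Seeded synthetic cohorts with the structure of a special-education
speech-language therapy caseload.

The generator assumes a latent-template model: each clinical condition owns
a template of area-relevant medical findings, per-area binary evaluation
vectors, per-area activity/exercise sets (the condition's canonical therapy
plan), and per-condition age distributions.  Individual cases are drawn by
flipping each binary feature independently with a small probability, drawing
ages from the condition's normal distributions (clipped to the paediatric
range 0–216 months), and perturbing the plan with seeded add/drop edits.

The default condition mix mirrors a cohort of 117 children: cerebral palsy
22, Down syndrome 19, intellectual disability 10, autistic disorder 9,
fetal alcohol syndrome 5, and the remainder a mixed-language-disorder
group.  Templates are kept pairwise separated on every area's relevant
feature block, so low-noise cohorts are identifiable by the level-1
clustering — the property the recommender's retrieval relies on.

Ground truth (condition label and template plan per case) is returned
separately and never stored inside a case, so the planner cannot leak it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ActivityItem,
    AreaCatalogue,
    CognitiveRecord,
    MedicalRecord,
    PatientCase,
    SLTEvaluation,
    TherapyPlan,
    TherapySubplan,
)

__all__ = [
    "AgeParams",
    "SimConfig",
    "ConditionTemplate",
    "make_templates",
    "generate_corpus",
    "generate_new_cases",
    "activity_catalogue",
    "DEFAULT_CONDITIONS",
]

#: condition name -> (ICD-10-CM code, corpus count); remainder of n_cases goes
#: to the mixed-language-disorder group
DEFAULT_CONDITIONS: dict[str, tuple[str, int]] = {
    "cerebral palsy": ("G80.1", 22),
    "down syndrome": ("Q90.9", 19),
    "intellectual disability": ("F79", 10),
    "autistic disorder": ("F84.0", 9),
    "fetal alcohol syndrome": ("Q86.0", 5),
    "mixed language disorder": ("F80.2", 0),  # count filled with the remainder
}


def proportional_mix(n_cases: int) -> dict[str, int]:
    """Scale the default 117-case condition mix down/up to ``n_cases``.

    Counts are floored; the remainder goes to the mixed-language-disorder group.
    """
    return {
        name: (cnt * n_cases) // 117
        for name, (_, cnt) in DEFAULT_CONDITIONS.items()
        if cnt > 0
    }


@dataclass(frozen=True)
class AgeParams:
    """Mean/sd (months) of the ages drawn for one condition.

    Placeholder paediatric values: per-condition age distributions of the
    source caseload are not published.
    """

    chronological: tuple[float, float] = (96.0, 20.0)
    cognitive: tuple[float, float] = (60.0, 12.0)
    language_gap: tuple[float, float] = (36.0, 10.0)
    expressive: tuple[float, float] = (48.0, 12.0)
    receptive: tuple[float, float] = (56.0, 12.0)


_DEFAULT_AGE_PARAMS: dict[str, AgeParams] = {
    "cerebral palsy": AgeParams((100, 22), (55, 12), (42, 10), (44, 10), (54, 10)),
    "down syndrome": AgeParams((95, 20), (50, 10), (46, 10), (40, 10), (50, 10)),
    "intellectual disability": AgeParams((100, 20), (62, 12), (34, 10), (50, 12), (60, 12)),
    "autistic disorder": AgeParams((90, 18), (70, 14), (30, 10), (48, 12), (56, 12)),
    "fetal alcohol syndrome": AgeParams((95, 18), (58, 12), (34, 10), (46, 10), (56, 10)),
    "mixed language disorder": AgeParams((85, 18), (76, 15), (24, 8), (56, 12), (66, 12)),
}


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort generator."""

    n_cases: int = 117
    #: condition -> count; any shortfall against n_cases goes to the last condition
    condition_mix: dict[str, int] = field(
        default_factory=lambda: {name: cnt for name, (_, cnt) in DEFAULT_CONDITIONS.items()}
    )
    icd10_codes: dict[str, str] = field(
        default_factory=lambda: {name: code for name, (code, _) in DEFAULT_CONDITIONS.items()}
    )
    eval_flip_prob: float = 0.02
    med_flip_prob: float = 0.02
    plan_flip_prob: float = 0.10
    plan_template_size: int = 5
    min_separation: int = 2
    age_params: dict[str, AgeParams] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_PARAMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.eval_flip_prob, self.med_flip_prob, self.plan_flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"flip probabilities must lie in [0,1], got {p}")
        if any(v < 0 for v in self.condition_mix.values()):
            raise ValueError("condition counts must be non-negative")
        if sum(self.condition_mix.values()) > self.n_cases:
            raise ValueError(
                f"condition counts sum to {sum(self.condition_mix.values())} "
                f"> n_cases {self.n_cases}"
            )

    def counts(self) -> dict[str, int]:
        """Condition counts with the remainder assigned to the last condition."""
        counts = dict(self.condition_mix) or {"mixed language disorder": 0}
        rest = self.n_cases - sum(counts.values())
        if rest:
            last = list(counts)[-1]
            counts[last] += rest
        return counts


@dataclass
class ConditionTemplate:
    """The latent profile a condition's cases are drawn from."""

    condition: str
    icd10_code: str
    medical_features: list[int]
    evaluations: dict[str, list[int]]
    activities: dict[str, list[str]]
    exercises: dict[str, list[str]]
    age_params: AgeParams


def _separated_vectors(
    rng: np.random.Generator, n_vectors: int, length: int, min_sep: int
) -> list[np.ndarray]:
    """Greedy seeded sampling of binary vectors pairwise >= min_sep apart."""
    min_sep = min(min_sep, length)
    for _restart in range(50):
        chosen: list[np.ndarray] = []
        for _ in range(n_vectors):
            ok = False
            for _try in range(2000):
                v = (rng.random(length) < 0.5).astype(int)
                if all(int(np.abs(v - w).sum()) >= min_sep for w in chosen):
                    chosen.append(v)
                    ok = True
                    break
            if not ok:
                break
        if len(chosen) == n_vectors:
            return chosen
    raise RuntimeError(
        f"could not place {n_vectors} vectors of length {length} "
        f"with pairwise separation {min_sep}"
    )


def _area_code(area: str) -> str:
    return "".join(w[0] for w in area.replace("&", " ").split()).upper()


def make_templates(
    catalogue: AreaCatalogue, cfg: SimConfig, seed: int | None = None
) -> list[ConditionTemplate]:
    """Draw one latent template per condition, pairwise separated by at least
    ``cfg.min_separation`` Hamming distance on every area's medical-feature
    block and evaluation dimensions."""
    # dedicated stream so template structure is independent of case draws
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 0])
    conditions = list(cfg.counts())
    n_cond = len(conditions)
    n_med = len(catalogue.medical_features)

    med = np.zeros((n_cond, n_med), dtype=int)
    for area in catalogue.areas:
        block = _separated_vectors(rng, n_cond, len(area.features_mr), cfg.min_separation)
        for ci in range(n_cond):
            med[ci, area.features_mr] = block[ci]

    evals: list[dict[str, list[int]]] = [dict() for _ in range(n_cond)]
    for area in catalogue.areas:
        vecs = _separated_vectors(
            rng, n_cond, len(area.dimensions), cfg.min_separation
        )
        for ci in range(n_cond):
            evals[ci][area.name] = vecs[ci].astype(int).tolist()

    templates = []
    for ci, cond in enumerate(conditions):
        code = _area_code
        acts = {
            a.name: [
                f"ACT-{code(a.name)}-C{ci}-{j:02d}" for j in range(cfg.plan_template_size)
            ]
            for a in catalogue.areas
        }
        exes = {
            a.name: [
                f"EXE-{code(a.name)}-C{ci}-{j:02d}" for j in range(cfg.plan_template_size)
            ]
            for a in catalogue.areas
        }
        templates.append(
            ConditionTemplate(
                condition=cond,
                icd10_code=cfg.icd10_codes.get(cond, "F80.9"),
                medical_features=med[ci].tolist(),
                evaluations=evals[ci],
                activities=acts,
                exercises=exes,
                age_params=cfg.age_params.get(cond, AgeParams()),
            )
        )
    return templates


def _distractor_pool(area: str, size: int = 10) -> list[str]:
    code = _area_code(area)
    return [f"ACT-{code}-GEN-{j:02d}" for j in range(size)]


def _exercise_distractors(area: str, size: int = 10) -> list[str]:
    code = _area_code(area)
    return [f"EXE-{code}-GEN-{j:02d}" for j in range(size)]


def activity_catalogue(
    catalogue: AreaCatalogue, templates: list[ConditionTemplate]
) -> list[ActivityItem]:
    """Flat catalogue of every activity/exercise ID the generator can emit."""
    items: list[ActivityItem] = []
    for area in catalogue.area_names:
        for t in templates:
            for aid in t.activities[area]:
                items.append(
                    ActivityItem(
                        id=aid, area=area, kind="activity",
                        description=f"semiannual activity for {t.condition} ({area})",
                    )
                )
            for eid in t.exercises[area]:
                items.append(
                    ActivityItem(
                        id=eid, area=area, kind="exercise",
                        description=f"daily exercise for {t.condition} ({area})",
                    )
                )
        for aid in _distractor_pool(area):
            items.append(
                ActivityItem(id=aid, area=area, kind="activity",
                             description=f"general-purpose activity ({area})")
            )
        for eid in _exercise_distractors(area):
            items.append(
                ActivityItem(id=eid, area=area, kind="exercise",
                             description=f"general-purpose exercise ({area})")
            )
    return items


def _flip(rng: np.random.Generator, vec: list[int], p: float) -> list[int]:
    arr = np.asarray(vec, dtype=int)
    if p > 0:
        mask = rng.random(arr.size) < p
        arr = np.where(mask, 1 - arr, arr)
    return arr.astype(int).tolist()


def _draw_age(rng: np.random.Generator, mean_sd: tuple[float, float]) -> int:
    mean, sd = mean_sd
    return int(np.clip(round(rng.normal(mean, sd)), 0, 216))


def _perturbed_plan(
    rng: np.random.Generator,
    template: ConditionTemplate,
    catalogue: AreaCatalogue,
    p: float,
) -> TherapyPlan:
    subplans = {}
    for area in catalogue.area_names:
        acts = list(template.activities[area])
        exes = list(template.exercises[area])
        if p > 0:
            if rng.random() < p and len(acts) > 1:
                acts.pop(int(rng.integers(len(acts))))
            if rng.random() < p:
                pool = _distractor_pool(area)
                acts.append(pool[int(rng.integers(len(pool)))])
            if rng.random() < p and len(exes) > 1:
                exes.pop(int(rng.integers(len(exes))))
            if rng.random() < p:
                pool = _exercise_distractors(area)
                exes.append(pool[int(rng.integers(len(pool)))])
        subplans[area] = TherapySubplan(area=area, activities=acts, exercises=exes)
    return TherapyPlan(subplans=subplans)


def _draw_case(
    rng: np.random.Generator,
    case_id: str,
    template: ConditionTemplate,
    catalogue: AreaCatalogue,
    cfg: SimConfig,
    with_plan: bool,
) -> PatientCase:
    ap = template.age_params
    chrono = _draw_age(rng, ap.chronological)
    cognitive = CognitiveRecord(
        cognitive_age=_draw_age(rng, ap.cognitive),
        language_gap=_draw_age(rng, ap.language_gap),
        expressive_language_age=_draw_age(rng, ap.expressive),
        receptive_language_age=_draw_age(rng, ap.receptive),
    )
    medical = MedicalRecord(
        icd10_codes=[template.icd10_code],
        features=_flip(rng, template.medical_features, cfg.med_flip_prob),
    )
    evaluation = SLTEvaluation(
        areas={
            area: _flip(rng, template.evaluations[area], cfg.eval_flip_prob)
            for area in catalogue.area_names
        }
    )
    plan = (
        _perturbed_plan(rng, template, catalogue, cfg.plan_flip_prob)
        if with_plan
        else None
    )
    return PatientCase(
        case_id=case_id,
        chronological_age=chrono,
        gender="F" if rng.random() < 0.5 else "M",
        medical=medical,
        cognitive=cognitive,
        evaluation=evaluation,
        plan=plan,
    )


def _truth_entry(template: ConditionTemplate, catalogue: AreaCatalogue) -> dict:
    return {
        "condition": template.condition,
        "template_activities": {a: template.activities[a] for a in catalogue.area_names},
        "template_exercises": {a: template.exercises[a] for a in catalogue.area_names},
    }


def generate_corpus(
    cfg: SimConfig, catalogue: AreaCatalogue
) -> tuple[list[PatientCase], dict[str, dict]]:
    """Draw the training cohort (all cases carry plans).

    Returns ``(cases, truth)`` where ``truth`` maps case_id to its generating
    condition and template plan — a sidecar oracle, never stored in a case.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    templates = make_templates(catalogue, cfg)
    by_cond = {t.condition: t for t in templates}
    cases, truth = [], {}
    i = 0
    for cond, count in cfg.counts().items():
        for _ in range(count):
            cid = f"case-{i:03d}"
            cases.append(_draw_case(rng, cid, by_cond[cond], catalogue, cfg, True))
            truth[cid] = _truth_entry(by_cond[cond], catalogue)
            i += 1
    return cases, truth


def generate_new_cases(
    cfg: SimConfig,
    catalogue: AreaCatalogue,
    n_new: int = 13,
    seed: int | None = None,
) -> tuple[list[PatientCase], dict[str, dict]]:
    """Draw held-out query cases (no plans) from the same templates.

    Conditions are assigned round-robin in mix proportion order; ground truth
    (condition + template plan) is returned separately as the test oracle.
    """
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 2])
    templates = make_templates(catalogue, cfg)
    conditions = list(cfg.counts())
    cases, truth = [], {}
    for i in range(n_new):
        t = templates[i % len(conditions)]
        cid = f"new-{i:02d}"
        cases.append(_draw_case(rng, cid, t, catalogue, cfg, False))
        truth[cid] = _truth_entry(t, catalogue)
    return cases, truth
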