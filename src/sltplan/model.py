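"""Patient/plan data model, the five-area catalogue, and corpus I/O.

A patient case bundles personal data, a medical record (ICD-10-CM codes plus a
binary vector of clinical findings), cognitive-development ages, a five-area
binary speech-language evaluation, and optionally a therapy plan of five
subplans.  Corpora are stored as JSON Lines (one case per line) with the area
catalogue in a separate JSON document.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, NonNegativeInt, ValidationError, field_validator

__all__ = [
    "AgeMonths",
    "parse_age",
    "format_age",
    "MedicalRecord",
    "CognitiveRecord",
    "SLTEvaluation",
    "AreaSpec",
    "AreaCatalogue",
    "Provenance",
    "TherapySubplan",
    "TherapyPlan",
    "PatientCase",
    "ActivityItem",
    "SchemaError",
    "default_catalogue",
    "load_catalogue",
    "save_catalogue",
    "load_corpus",
    "save_corpus",
    "load_cases",
]

#: Ages are plain non-negative integer counts of months; keeping them integral
#: avoids float drift in the age-difference scale factor.
AgeMonths = NonNegativeInt

_AGE_RE = re.compile(r"^\s*(\d+)\s*years?,\s*(\d+)\s*months?\s*$")
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,4})?$")


class SchemaError(ValueError):
    """A corpus document violates the data-model contract."""


def parse_age(text: str) -> int:
    """Parse a ``"Y years, M months"`` string into integer months.

    >>> parse_age("4 years, 6 months")
    54
    """
    m = _AGE_RE.match(text)
    if m is None:
        raise SchemaError(f"malformed age string: {text!r} (expected 'Y years, M months')")
    years, months = int(m.group(1)), int(m.group(2))
    if months > 11:
        raise SchemaError(f"malformed age string: {text!r} (months component {months} > 11)")
    return 12 * years + months


def format_age(months: int) -> str:
    """Render integer months as ``"Y years, M months"``."""
    if months < 0:
        raise SchemaError(f"age must be non-negative, got {months}")
    return f"{months // 12} years, {months % 12} months"


def _check_binary(vec: list[int], where: str) -> list[int]:
    for v in vec:
        if v not in (0, 1):
            raise ValueError(f"{where}: entries must be 0/1, found {v!r}")
    return vec


class MedicalRecord(BaseModel):
    """ICD-10-CM diagnoses plus a binary vector over the medical-finding catalogue."""

    icd10_codes: list[str] = Field(default_factory=list)
    features: list[int]

    @field_validator("icd10_codes")
    @classmethod
    def _codes_wellformed(cls, codes: list[str]) -> list[str]:
        for c in codes:
            if not _ICD10_RE.match(c):
                raise ValueError(f"invalid ICD-10-CM code: {c!r}")
        return codes

    @field_validator("features")
    @classmethod
    def _features_binary(cls, v: list[int]) -> list[int]:
        return _check_binary(v, "medical features")


class CognitiveRecord(BaseModel):
    """The four cognitive-development ages (months) feeding the level-2 scale factor."""

    cognitive_age: AgeMonths
    language_gap: AgeMonths
    expressive_language_age: AgeMonths
    receptive_language_age: AgeMonths

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.cognitive_age,
            self.language_gap,
            self.expressive_language_age,
            self.receptive_language_age,
        )


class SLTEvaluation(BaseModel):
    """Per-area binary pass/fail vectors over the evaluation-dimension catalogue."""

    areas: dict[str, list[int]]

    @field_validator("areas")
    @classmethod
    def _check(cls, areas: dict[str, list[int]]) -> dict[str, list[int]]:
        if len(areas) != 5:
            raise ValueError(f"evaluation must cover exactly 5 areas, found {len(areas)}")
        for name, vec in areas.items():
            _check_binary(vec, f"evaluation area {name!r}")
        return areas


class AreaSpec(BaseModel):
    name: str
    #: index set into the medical-finding catalogue relevant to this area
    features_mr: list[int]
    #: named evaluation dimensions of this area
    dimensions: list[str]

    @field_validator("features_mr")
    @classmethod
    def _nonempty(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("features_mr must be non-empty")
        return v

    @field_validator("dimensions")
    @classmethod
    def _unique(cls, v: list[str]) -> list[str]:
        if len(set(v)) != len(v):
            raise ValueError("dimension names must be unique within an area")
        return v


class AreaCatalogue(BaseModel):
    """The five speech-language areas with their medical-feature index sets and
    evaluation dimensions, plus the named medical-finding catalogue."""

    medical_features: list[str]
    areas: list[AreaSpec]

    @field_validator("areas")
    @classmethod
    def _five(cls, v: list[AreaSpec]) -> list[AreaSpec]:
        if len(v) != 5:
            raise ValueError(f"catalogue must define exactly 5 areas, found {len(v)}")
        names = [a.name for a in v]
        if len(set(names)) != 5:
            raise ValueError("area names must be unique")
        return v

    def model_post_init(self, __context) -> None:
        n = len(self.medical_features)
        for a in self.areas:
            bad = [i for i in a.features_mr if not (0 <= i < n)]
            if bad:
                raise ValueError(f"area {a.name!r}: features_mr indices {bad} out of bounds")

    @property
    def area_names(self) -> list[str]:
        return [a.name for a in self.areas]

    @property
    def total_dimensions(self) -> int:
        return sum(len(a.dimensions) for a in self.areas)

    def area(self, name: str) -> AreaSpec:
        for a in self.areas:
            if a.name == name:
                return a
        raise KeyError(f"unknown area: {name!r}")

    def validate_case(self, case: "PatientCase") -> None:
        """Enforce catalogue consistency for one case; raises SchemaError."""
        cid = case.case_id
        if len(case.medical.features) != len(self.medical_features):
            raise SchemaError(
                f"case {cid}: medical feature vector length "
                f"{len(case.medical.features)} != catalogue {len(self.medical_features)}"
            )
        got = set(case.evaluation.areas)
        want = set(self.area_names)
        if got != want:
            raise SchemaError(f"case {cid}: evaluation areas {sorted(got)} != catalogue areas")
        for a in self.areas:
            vec = case.evaluation.areas[a.name]
            if len(vec) != len(a.dimensions):
                raise SchemaError(
                    f"case {cid}: evaluation[{a.name!r}] length {len(vec)} "
                    f"!= {len(a.dimensions)} dimensions"
                )
        if case.plan is not None:
            if set(case.plan.subplans) != want:
                raise SchemaError(f"case {cid}: plan areas != catalogue areas")


class Provenance(BaseModel):
    """Where a recommended subplan came from: source case, coincidence, shared features."""

    source_case_id: str
    coincidence_percent: float = Field(ge=0.0, le=100.0)
    matched_features: list[str] = Field(default_factory=list)


class TherapySubplan(BaseModel):
    area: str
    activities: list[str] = Field(default_factory=list)
    exercises: list[str] = Field(default_factory=list)
    provenance: list[Provenance] = Field(default_factory=list)


class TherapyPlan(BaseModel):
    """Exactly one subplan per speech-language area, keyed by area name."""

    subplans: dict[str, TherapySubplan]

    @field_validator("subplans")
    @classmethod
    def _five(cls, v: dict[str, TherapySubplan]) -> dict[str, TherapySubplan]:
        if len(v) != 5:
            raise ValueError(f"plan must hold exactly 5 subplans, found {len(v)}")
        for name, sp in v.items():
            if sp.area != name:
                raise ValueError(f"subplan keyed {name!r} declares area {sp.area!r}")
        return v


class PatientCase(BaseModel):
    case_id: str
    chronological_age: AgeMonths
    gender: str = "unspecified"
    medical: MedicalRecord
    cognitive: CognitiveRecord
    evaluation: SLTEvaluation
    plan: Optional[TherapyPlan] = None


class ActivityItem(BaseModel):
    """One entry of the flat activity/exercise catalogue."""

    id: str
    area: str
    kind: str = "activity"  # "activity" | "exercise"
    description: str = ""


# ---------------------------------------------------------------------------
# catalogue and corpus I/O


def default_catalogue() -> AreaCatalogue:
    """The packaged 102-parameter catalogue (5/25/10/52/10 dimensions per area)."""
    text = resources.files("sltplan.data").joinpath("default_catalogue.json").read_text()
    return AreaCatalogue.model_validate_json(text)


def load_catalogue(path: str | Path) -> AreaCatalogue:
    return AreaCatalogue.model_validate_json(Path(path).read_text())


def save_catalogue(catalogue: AreaCatalogue, path: str | Path) -> None:
    Path(path).write_text(catalogue.model_dump_json(indent=1))


def load_cases(
    path: str | Path,
    catalogue: AreaCatalogue,
    require_plans: bool = False,
) -> list[PatientCase]:
    """Read a JSON-Lines corpus, validating every case against the catalogue.

    Cases are returned in file order.  Raises :class:`SchemaError` naming the
    offending case and field on any contract violation.
    """
    cases: list[PatientCase] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            case = PatientCase.model_validate_json(line)
        except ValidationError as err:
            first = err.errors()[0]
            loc = ".".join(str(p) for p in first["loc"])
            raise SchemaError(f"line {lineno}: field {loc!r}: {first['msg']}") from err
        if case.case_id in seen:
            raise SchemaError(f"duplicate case_id {case.case_id!r} at line {lineno}")
        seen.add(case.case_id)
        catalogue.validate_case(case)
        if require_plans and case.plan is None:
            raise SchemaError(f"case {case.case_id}: training corpus requires a plan")
        cases.append(case)
    return cases


def load_corpus(
    corpus_path: str | Path,
    catalogue_path: str | Path | None = None,
    require_plans: bool = False,
) -> tuple[list[PatientCase], AreaCatalogue]:
    """Load (cases, catalogue); with no catalogue path the packaged default is used."""
    catalogue = default_catalogue() if catalogue_path is None else load_catalogue(catalogue_path)
    return load_cases(corpus_path, catalogue, require_plans=require_plans), catalogue


def save_corpus(cases: list[PatientCase], path: str | Path) -> None:
    """Write cases as JSON Lines, one case per line, stable key order."""
    with open(path, "w") as fh:
        for case in cases:
            fh.write(json.dumps(case.model_dump(mode="json"), sort_keys=True))
            fh.write("\n")
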