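"""Distance metrics between patient cases.

Two bespoke metrics drive the two clustering levels:

* level 1 — mean-Manhattan binary distance between medical-record feature
  vectors, restricted to the features relevant to one speech-language area,
  ``features_MR(A)``;
* level 2 — mean-Manhattan binary distance between the speech-language
  evaluations restricted to the area's dimensions, ``dimensions_IE(A)``,
  plus a scale factor built from the absolute differences of the four
  cognitive-development ages (cognitive age, language gap, expressive and
  receptive language ages).

The scale factor is additive: ``λ · (1/4) Σ_c min(|Δage_c| / age_norm, 1)``.
Each age difference is normalised by ``age_norm`` months (default 216, i.e.
18 years, the top of the paediatric range) and capped at 1 so a single
extreme gap cannot dominate, keeping the term commensurate with the [0, 1]
binary summand; ``λ = 0`` recovers the pure evaluation distance.

The coincidence percent, ``(1 − mean-Manhattan) × 100`` over the relevant
index set, is the similarity figure clinicians see in plan provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AreaCatalogue, CognitiveRecord, PatientCase

__all__ = [
    "MetricConfig",
    "mean_manhattan",
    "level1_distance",
    "scale_factor",
    "level2_distance",
    "coincidence_percent",
    "coincidence_from_vectors",
    "pairwise_level1",
    "pairwise_level2",
    "cross_level1",
    "cross_level2",
]


@dataclass(frozen=True)
class MetricConfig:
    """Knobs of the level-2 metric.

    scale_weight
        λ ≥ 0, weight of the age-difference term (0 disables it).
    age_norm_months
        positive number of months each absolute age difference is divided by
        before capping at 1.
    """

    scale_weight: float = 1.0
    age_norm_months: int = 216

    def __post_init__(self) -> None:
        if self.scale_weight < 0:
            raise ValueError(f"scale_weight must be >= 0, got {self.scale_weight}")
        if self.age_norm_months <= 0:
            raise ValueError(f"age_norm_months must be > 0, got {self.age_norm_months}")


def _as_binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name}: expected a non-empty 1-d vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name}: entries must be 0/1")
    return arr.astype(np.int64)


def mean_manhattan(x, y) -> float:
    """Mean-Manhattan binary distance ``(1/n) Σ |x_i − y_i|`` ∈ [0, 1]."""
    xv = _as_binary(x, "x")
    yv = _as_binary(y, "y")
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    return float(np.abs(xv - yv).sum() / xv.size)


def coincidence_from_vectors(x, y) -> float:
    """Coincidence percent of two binary vectors: ``(1 − mean_manhattan) × 100``."""
    return (1.0 - mean_manhattan(x, y)) * 100.0


def level1_distance(
    si: PatientCase, sj: PatientCase, area: str, catalogue: AreaCatalogue
) -> float:
    """Mean-Manhattan distance of the medical features relevant to *area*."""
    idx = catalogue.area(area).features_mr
    xi = np.asarray(si.medical.features)[idx]
    xj = np.asarray(sj.medical.features)[idx]
    return mean_manhattan(xi, xj)


def scale_factor(ci: CognitiveRecord, cj: CognitiveRecord, cfg: MetricConfig) -> float:
    """λ-weighted mean of normalised, capped absolute cognitive-age differences."""
    ai = np.asarray(ci.as_tuple(), dtype=float)
    aj = np.asarray(cj.as_tuple(), dtype=float)
    capped = np.minimum(np.abs(ai - aj) / cfg.age_norm_months, 1.0)
    return float(cfg.scale_weight * capped.mean())


def level2_distance(
    si: PatientCase,
    sj: PatientCase,
    area: str,
    catalogue: AreaCatalogue,
    cfg: MetricConfig,
) -> float:
    """Evaluation mean-Manhattan over the area's dimensions plus the age scale factor."""
    catalogue.area(area)  # raises KeyError for unknown areas
    d_eval = mean_manhattan(si.evaluation.areas[area], sj.evaluation.areas[area])
    return d_eval + scale_factor(si.cognitive, sj.cognitive, cfg)


def coincidence_percent(
    si: PatientCase,
    sj: PatientCase,
    area: str,
    catalogue: AreaCatalogue,
    level: int = 2,
) -> float:
    """Coincidence reported to clinicians, over the binary part of a level's metric.

    ``level=1`` uses the area-relevant medical features, ``level=2`` the
    area's evaluation dimensions.  The age scale factor never enters.
    """
    if level == 1:
        return (1.0 - level1_distance(si, sj, area, catalogue)) * 100.0
    if level == 2:
        catalogue.area(area)
        return coincidence_from_vectors(
            si.evaluation.areas[area], sj.evaluation.areas[area]
        )
    raise ValueError(f"level must be 1 or 2, got {level}")


# ---------------------------------------------------------------------------
# vectorised pairwise forms used by clustering and retrieval


def _medical_matrix(cases: list[PatientCase], area: str, catalogue: AreaCatalogue) -> np.ndarray:
    idx = catalogue.area(area).features_mr
    return np.asarray([case.medical.features for case in cases], dtype=np.int64)[:, idx]


def _eval_matrix(cases: list[PatientCase], area: str, catalogue: AreaCatalogue) -> np.ndarray:
    catalogue.area(area)
    return np.asarray([case.evaluation.areas[area] for case in cases], dtype=np.int64)


def _age_matrix(cases: list[PatientCase]) -> np.ndarray:
    return np.asarray([case.cognitive.as_tuple() for case in cases], dtype=float)


def _mean_manhattan_cross(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    return np.abs(xa[:, None, :] - xb[None, :, :]).sum(axis=2) / xa.shape[1]


def _scale_cross(aa: np.ndarray, ab: np.ndarray, cfg: MetricConfig) -> np.ndarray:
    capped = np.minimum(np.abs(aa[:, None, :] - ab[None, :, :]) / cfg.age_norm_months, 1.0)
    return cfg.scale_weight * capped.mean(axis=2)


def pairwise_level1(
    cases: list[PatientCase], area: str, catalogue: AreaCatalogue
) -> np.ndarray:
    """Symmetric n×n level-1 distance matrix over *cases* for one area."""
    x = _medical_matrix(cases, area, catalogue)
    return _mean_manhattan_cross(x, x)


def pairwise_level2(
    cases: list[PatientCase], area: str, catalogue: AreaCatalogue, cfg: MetricConfig
) -> np.ndarray:
    """Symmetric n×n level-2 distance matrix over *cases* for one area."""
    x = _eval_matrix(cases, area, catalogue)
    a = _age_matrix(cases)
    return _mean_manhattan_cross(x, x) + _scale_cross(a, a, cfg)


def cross_level1(
    queries: list[PatientCase],
    references: list[PatientCase],
    area: str,
    catalogue: AreaCatalogue,
) -> np.ndarray:
    """|queries| × |references| level-1 distances for one area."""
    xq = _medical_matrix(queries, area, catalogue)
    xr = _medical_matrix(references, area, catalogue)
    return _mean_manhattan_cross(xq, xr)


def cross_level2(
    queries: list[PatientCase],
    references: list[PatientCase],
    area: str,
    catalogue: AreaCatalogue,
    cfg: MetricConfig,
) -> np.ndarray:
    """|queries| × |references| level-2 distances for one area."""
    xq = _eval_matrix(queries, area, catalogue)
    xr = _eval_matrix(references, area, catalogue)
    aq = _age_matrix(queries)
    ar = _age_matrix(references)
    return _mean_manhattan_cross(xq, xr) + _scale_cross(aq, ar, cfg)
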