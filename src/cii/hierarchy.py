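"""Evidence-hierarchy weighting and qualification rules.

The hierarchy separates two notions of authority.  *Functional* tiers govern
override rights: meta-analyses and systematic reviews sit at the top and may
disqualify earlier evidence.  *Numerical* weights drive scoring: individual
randomised trials carry the highest numerical weight, while meta-analyses
are weighted lower so that disease areas rich in controversy (and hence in
pooled re-analyses of the same trials) are not artificially inflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import MissingKeyError
from .models import Outcome, PieceOfEvidence, PieceStatus, StudyType


class EvidenceHierarchy(BaseModel):
    """Study-type weights plus the functional-tier ordering.

    ``numeric_weight`` maps each study type to a non-negative scoring weight.
    ``functional_tier`` ranks study types for override authority (higher =
    more authoritative); meta-analyses and systematic reviews must share the
    top tier.  Group evidence is split 1/k among the k class members.
    """

    numeric_weight: dict[StudyType, float]
    functional_tier: dict[StudyType, int]
    group_fraction_rule: Literal["one_over_k"] = "one_over_k"

    @field_validator("numeric_weight")
    @classmethod
    def _nonneg(cls, v: dict[StudyType, float]) -> dict[StudyType, float]:
        for st, w in v.items():
            if w < 0:
                raise ValueError(f"numeric weight for {st.value} must be >= 0")
        return v

    @model_validator(mode="after")
    def _top_tier_shared(self) -> "EvidenceHierarchy":
        tiers = self.functional_tier
        if StudyType.meta_analysis in tiers and StudyType.systematic_review in tiers:
            top = max(tiers.values())
            if (
                tiers[StudyType.meta_analysis] != top
                or tiers[StudyType.systematic_review] != top
            ):
                raise ValueError(
                    "meta_analysis and systematic_review must share the top "
                    "functional tier"
                )
        return self

    def top_tier(self) -> int:
        return max(self.functional_tier.values())


def default_hierarchy() -> EvidenceHierarchy:
    """Default weights: RCTs highest numerically; pooled reviews top tier
    functionally but weighted below RCTs."""
    return EvidenceHierarchy(
        numeric_weight={
            StudyType.rct: 1.0,
            StudyType.meta_analysis: 0.5,
            StudyType.systematic_review: 0.5,
            StudyType.observational: 0.5,
            StudyType.retrospective: 0.25,
            StudyType.historical: 0.25,
        },
        functional_tier={
            StudyType.meta_analysis: 2,
            StudyType.systematic_review: 2,
            StudyType.rct: 1,
            StudyType.observational: 0,
            StudyType.retrospective: 0,
            StudyType.historical: 0,
        },
    )


class ScoringConfig(BaseModel):
    """Inclusion thresholds and outcome scope for score computation."""

    outcomes_in_scope: frozenset[Outcome] = frozenset({Outcome.overall_survival})
    require_multiple_testing: bool = True
    count_threshold: float = Field(default=0.0, ge=0)
    milestone_levels: list[float] = Field(default_factory=lambda: [1.0, 3.0])

    @field_validator("milestone_levels")
    @classmethod
    def _ascending(cls, v: list[float]) -> list[float]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("milestone_levels must be strictly ascending")
        return v


def evidence_weight(
    piece: PieceOfEvidence,
    hierarchy: EvidenceHierarchy,
    *,
    study_type: Optional[StudyType] = None,
    store=None,
) -> float:
    """Numerical weight of one piece: the study-type weight, divided by the
    group size for group evidence (fractional 1/k attribution).

    The study type lives on the piece's reference; pass it directly or give
    a store to resolve it.
    """
    if study_type is None:
        if store is None:
            raise ValueError("provide study_type or a store to resolve it")
        study_type = store.study_type(piece)
    if study_type not in hierarchy.numeric_weight:
        raise MissingKeyError(
            f"study type {study_type.value!r} missing from hierarchy weights"
        )
    base = (
        piece.weight_override
        if piece.weight_override is not None
        else hierarchy.numeric_weight[study_type]
    )
    if piece.group_evidence:
        return base / piece.group_size
    return base


@dataclass(frozen=True)
class QualificationResult:
    ok: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:  # allows `if qualifies(...)`
        return self.ok


def qualifies(piece: PieceOfEvidence, cfg: ScoringConfig) -> QualificationResult:
    """Whether a piece may increment scores, with the first failing reason.

    A piece qualifies iff its outcome is in scope, it is significant after
    multiple-testing correction (when required), it did not fail on
    toxicity, its status still counts, and no quality-control flag is still
    to-do.  Trials whose nominally significant effect was outweighed by
    severe side effects are recorded but never increment scores.

    A piece flagged ``disqualified_pending`` by a review override keeps
    counting: disqualification takes effect only at the next data release,
    never decreasing scores in real time.
    """
    if piece.outcome not in cfg.outcomes_in_scope:
        return QualificationResult(False, "outcome_out_of_scope")
    if cfg.require_multiple_testing and not piece.significant_after_correction:
        return QualificationResult(False, "not_significant")
    if piece.failed_due_to_toxicity:
        return QualificationResult(False, "toxicity")
    if piece.status not in (PieceStatus.active, PieceStatus.disqualified_pending):
        return QualificationResult(False, piece.status.value)
    if piece.has_todo_flag():
        return QualificationResult(False, "flag_todo")
    return QualificationResult(True)


def strength_tier(cumulative_weight: float, cfg: ScoringConfig) -> int:
    """Evidence-strength tier: how many milestone levels the cumulative
    weight has reached (tier 0 = below the first milestone)."""
    if cumulative_weight < 0:
        raise ValueError("cumulative_weight must be >= 0")
    return sum(1 for level in cfg.milestone_levels if level <= cumulative_weight)
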