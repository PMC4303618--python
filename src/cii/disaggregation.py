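"""Split a structured study description into distinct pieces of evidence.

A publication usually reports several analyses: multiple treatment arms
against a comparator, initial versus long-term follow-up readouts, the
entire population versus biomarker-defined subgroups, superiority versus
non-inferiority goals.  Each such combination becomes its own piece of
evidence, so one piece always carries exactly one disease state, goal,
treatment and outcome.  Only pre-planned analyses should be entered; the
curator asserts this when writing the study description.
"""

from __future__ import annotations

from typing import Literal, Optional, Union

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import CIIError, MissingKeyError
from .models import (
    AnalysisGoal,
    DiseaseState,
    EffectType,
    Outcome,
    PieceOfEvidence,
    TherapeuticGoal,
    normalize_tag,
)

NOT_REPORTED = "not_reported"


class Arm(BaseModel):
    """One non-control comparison arm.  Control/placebo arms appear only as
    comparator text; the comparison, not the arm per se, is the unit."""

    treatment_id: str
    comparator: str = ""


class ResultEntry(BaseModel):
    """The curated result for one (arm, timepoint, subgroup, goal) cell."""

    significant_after_correction: bool
    effect_size: Optional[float] = None
    effect_type: Optional[EffectType] = None
    failed_due_to_toxicity: bool = False


class StudySpec(BaseModel):
    """A structured study description ready for disaggregation.

    ``results`` is keyed by the combination index string
    ``"<arm>.<timepoint>.<subgroup>.<goal>"`` (0-based); a cell may be the
    literal ``"not_reported"`` to suppress that combination.
    """

    ref_id: str
    arms: list[Arm]
    timepoints: list[str] = Field(default_factory=lambda: ["initial"])
    subgroups: list[list[str]] = Field(default_factory=lambda: [[]])
    analysis_goals: list[AnalysisGoal] = Field(
        default_factory=lambda: [AnalysisGoal.superiority]
    )
    disease_state: DiseaseState
    therapeutic_goal: TherapeuticGoal
    outcome: Outcome = Outcome.overall_survival
    group_evidence: bool = False
    group_size: int = 1
    results: dict[str, Union[ResultEntry, Literal["not_reported"]]] = Field(
        default_factory=dict
    )

    @field_validator("subgroups")
    @classmethod
    def _norm_subgroups(cls, v: list[list[str]]) -> list[list[str]]:
        return [sorted({normalize_tag(t) for t in sg}) for sg in v]

    @model_validator(mode="after")
    def _nonempty(self) -> "StudySpec":
        for name in ("arms", "timepoints", "subgroups", "analysis_goals"):
            if not getattr(self, name):
                raise ValueError(f"study {self.ref_id!r}: {name} must be non-empty")
        return self


def combination_key(a: int, t: int, s: int, g: int) -> str:
    return f"{a}.{t}.{s}.{g}"


def piece_id_for(ref_id: str, a: int, t: int, s: int, g: int) -> str:
    """Deterministic, human-auditable piece id for one combination."""
    return f"{ref_id}:{a}.{t}.{s}.{g}"


def disaggregate(spec: StudySpec, store=None) -> list[PieceOfEvidence]:
    """Emit one piece per (arm x timepoint x subgroup x goal) combination,
    minus combinations explicitly marked not-reported.

    Deterministic and idempotent: re-running yields identical piece ids.
    A combination with no result entry and no not-reported marker is an
    error naming the combination.
    """
    if store is not None:
        if spec.ref_id not in store.references:
            raise MissingKeyError(f"study references missing ref_id {spec.ref_id!r}")
        for arm in spec.arms:
            if arm.treatment_id not in store.treatments:
                raise MissingKeyError(
                    f"study {spec.ref_id!r}: missing treatment "
                    f"{arm.treatment_id!r}"
                )
    pieces = []
    for a, arm in enumerate(spec.arms):
        for t, timepoint in enumerate(spec.timepoints):
            for s, subgroup in enumerate(spec.subgroups):
                for g, goal in enumerate(spec.analysis_goals):
                    key = combination_key(a, t, s, g)
                    result = spec.results.get(key)
                    if result is None:
                        raise CIIError(
                            f"study {spec.ref_id!r}: no result entry for "
                            f"combination {key} (arm={arm.treatment_id!r}, "
                            f"timepoint={timepoint!r}, subgroup={subgroup}, "
                            f"goal={goal.value}); mark it {NOT_REPORTED!r} to skip"
                        )
                    if result == NOT_REPORTED:
                        continue
                    pieces.append(
                        PieceOfEvidence(
                            piece_id=piece_id_for(spec.ref_id, a, t, s, g),
                            ref_id=spec.ref_id,
                            treatment_id=arm.treatment_id,
                            disease_state=spec.disease_state,
                            therapeutic_goal=spec.therapeutic_goal,
                            outcome=spec.outcome,
                            comparator=arm.comparator,
                            analysis_goal=goal,
                            timepoint_label=timepoint,
                            subgroup_tags=frozenset(subgroup),
                            significant_after_correction=result.significant_after_correction,
                            effect_size=result.effect_size,
                            effect_type=result.effect_type,
                            group_evidence=spec.group_evidence,
                            group_size=spec.group_size,
                            failed_due_to_toxicity=result.failed_due_to_toxicity,
                        )
                    )
    return pieces
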