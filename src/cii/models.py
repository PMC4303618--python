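"""Domain model for disaggregated clinical evidence records.

The unit of analysis is the *piece of evidence*: one analysis result for one
disease state, one therapeutic goal, one treatment and one outcome, carried
by a dated literature reference.  Treatments, references and pieces live in
separate relational tables linked by opaque string keys.
"""

from __future__ import annotations

import datetime
import enum
import re
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class StudyType(str, enum.Enum):
    meta_analysis = "meta_analysis"
    systematic_review = "systematic_review"
    rct = "rct"
    observational = "observational"
    retrospective = "retrospective"
    historical = "historical"


class Modality(str, enum.Enum):
    surgery = "surgery"
    radiotherapy = "radiotherapy"
    chemotherapy = "chemotherapy"
    immunotherapy = "immunotherapy"
    group = "group"
    other = "other"


class NoveltyClass(str, enum.Enum):
    new = "new"
    improvement = "improvement"
    combination = "combination"


class DiseaseState(str, enum.Enum):
    advanced = "advanced"
    regional = "regional"
    localized = "localized"
    resected = "resected"


class TherapeuticGoal(str, enum.Enum):
    become_disease_free = "become_disease_free"
    stop_progression = "stop_progression"
    shrink_or_slow = "shrink_or_slow"
    symptom_relief = "symptom_relief"


class Outcome(str, enum.Enum):
    """Outcomes in scope.  The first release tracks overall survival only."""

    overall_survival = "overall_survival"


class AnalysisGoal(str, enum.Enum):
    superiority = "superiority"
    non_inferiority = "non_inferiority"


class EffectType(str, enum.Enum):
    hazard_ratio = "hazard_ratio"
    median_survival_difference_months = "median_survival_difference_months"
    other = "other"


class PieceStatus(str, enum.Enum):
    active = "active"
    disqualified_pending = "disqualified_pending"
    disqualified = "disqualified"
    to_review = "to_review"


class FlagValue(str, enum.Enum):
    yes = "yes"
    no = "no"
    todo = "todo"


class PatientShare(str, enum.Enum):
    some = "some"
    most = "most"
    all = "all"


class ReviewConclusion(str, enum.Enum):
    supports = "supports"
    insufficient_support = "insufficient_support"


_WS = re.compile(r"\s+")


def normalize_tag(tag: str) -> str:
    """Exact-string, case-sensitive tags after whitespace normalization."""
    return _WS.sub(" ", tag.strip())


class Reference(BaseModel):
    """A dated literature source (keyed e.g. by a PubMed identifier)."""

    model_config = ConfigDict(use_enum_values=False)

    ref_id: str
    publication_date: datetime.date
    study_type: StudyType
    description: str = ""
    version: int = 1
    supersedes: Optional[int] = None
    audit_note: Optional[str] = None


class ShareEntry(BaseModel):
    """One dated entry of a treatment's patient-share history."""

    date: datetime.date
    share: PatientShare


class Treatment(BaseModel):
    """A therapy record: modality, novelty class, components, eligibility."""

    treatment_id: str
    name: str = ""
    modality: Modality = Modality.other
    novelty_class: NoveltyClass = NoveltyClass.new
    component_ids: list[str] = Field(default_factory=list)
    drug_class: Optional[str] = None
    eligibility: list[str] = Field(default_factory=list)
    molecular_eligibility: bool = False
    patient_share_history: list[ShareEntry] = Field(default_factory=list)
    version: int = 1
    supersedes: Optional[int] = None
    audit_note: Optional[str] = None

    @field_validator("eligibility")
    @classmethod
    def _norm_eligibility(cls, v: list[str]) -> list[str]:
        return [normalize_tag(t) for t in v]

    @model_validator(mode="after")
    def _check(self) -> "Treatment":
        if self.treatment_id in self.component_ids:
            raise ValueError(
                f"treatment {self.treatment_id!r} cannot be its own component"
            )
        needs_components = (
            self.novelty_class is NoveltyClass.combination
            or self.modality is Modality.group
        )
        if needs_components and not self.component_ids:
            raise ValueError(
                f"treatment {self.treatment_id!r}: component_ids required for "
                "combination or group treatments"
            )
        if not needs_components and self.component_ids:
            raise ValueError(
                f"treatment {self.treatment_id!r}: component_ids only allowed for "
                "combination or group treatments"
            )
        dates = [e.date for e in self.patient_share_history]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"treatment {self.treatment_id!r}: patient_share_history dates "
                "must be strictly increasing"
            )
        return self

    def share_as_of(self, date: datetime.date) -> Optional[PatientShare]:
        """Latest patient-share entry dated on or before ``date``."""
        current = None
        for entry in self.patient_share_history:
            if entry.date <= date:
                current = entry.share
        return current


class PieceOfEvidence(BaseModel):
    """One disaggregated analysis result.

    Exactly one disease state, therapeutic goal, treatment and outcome per
    piece; the piece's date is the publication date of its reference.
    """

    piece_id: str
    ref_id: str
    treatment_id: str
    disease_state: DiseaseState
    therapeutic_goal: TherapeuticGoal
    outcome: Outcome = Outcome.overall_survival
    comparator: str = ""
    analysis_goal: AnalysisGoal = AnalysisGoal.superiority
    timepoint_label: str = "initial"
    subgroup_tags: frozenset[str] = frozenset()
    significant_after_correction: bool = False
    effect_size: Optional[float] = None
    effect_type: Optional[EffectType] = None
    group_evidence: bool = False
    group_size: int = 1
    failed_due_to_toxicity: bool = False
    status: PieceStatus = PieceStatus.active
    flags: dict[str, FlagValue] = Field(default_factory=dict)
    review_conclusion: Optional[ReviewConclusion] = None
    weight_override: Optional[float] = None
    # versioning (never-delete rule): updates append a new version row
    version: int = 1
    supersedes: Optional[int] = None
    audit_note: Optional[str] = None

    @field_validator("subgroup_tags", mode="before")
    @classmethod
    def _norm_tags(cls, v) -> frozenset[str]:
        return frozenset(normalize_tag(t) for t in v)

    @model_validator(mode="after")
    def _check(self) -> "PieceOfEvidence":
        if self.group_evidence and self.group_size < 2:
            raise ValueError(
                f"piece {self.piece_id!r}: group evidence requires group_size >= 2"
            )
        if not self.group_evidence and self.group_size != 1:
            raise ValueError(
                f"piece {self.piece_id!r}: group_size must be 1 unless group evidence"
            )
        if self.weight_override is not None and self.weight_override < 0:
            raise ValueError(f"piece {self.piece_id!r}: weight_override must be >= 0")
        return self

    def has_todo_flag(self) -> bool:
        return any(v is FlagValue.todo for v in self.flags.values())


class AuditEntry(BaseModel):
    """One append-only record of a piece status transition.

    ``release_id`` is None while the transition is pending between releases
    and is stamped when a release applies or records it.
    """

    entry_id: int
    piece_id: str
    old_status: PieceStatus
    new_status: PieceStatus
    cause_piece_id: Optional[str] = None
    release_id: Optional[int] = None
    timestamp: datetime.date


class Query(BaseModel):
    """Conjunctive filter over piece / treatment / reference fields.

    ``where`` maps a field name (bare piece field, or ``treatment.x`` /
    ``reference.x``) to a required value; ``tags`` requires set containment in
    the piece's subgroup tags; the optional date range bounds the piece date
    (its reference's publication date).  An empty query matches everything.
    """

    where: dict[str, object] = Field(default_factory=dict)
    tags: frozenset[str] = frozenset()
    date_from: Optional[datetime.date] = None
    date_to: Optional[datetime.date] = None

    @field_validator("tags", mode="before")
    @classmethod
    def _norm_tags(cls, v) -> frozenset[str]:
        return frozenset(normalize_tag(t) for t in v)

    def describe(self) -> str:
        parts = [f"{k}={v}" for k, v in sorted(self.where.items(), key=lambda kv: kv[0])]
        parts += [f"tag:{t}" for t in sorted(self.tags)]
        if self.date_from:
            parts.append(f"from:{self.date_from.isoformat()}")
        if self.date_to:
            parts.append(f"to:{self.date_to.isoformat()}")
        return " AND ".join(parts) if parts else "ALL"
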