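"""Seeded synthetic evidence corpora and deterministic scenario fixtures.

The generator emulates the structural features of a curated clinical
evidence base — treatments with modalities and eligibility, dated
references of mixed study types, disaggregated pieces with significance,
toxicity failures, group evidence and subgroup tags, and occasional
top-tier review overrides — without mimicking real literature growth
curves or effect-size distributions.  Generation is a pure function of
(params, seed): the master seed spawns one independent random stream per
table, so adding a table never perturbs existing ones.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import UnknownScenarioError
from .hierarchy import (
    EvidenceHierarchy,
    ScoringConfig,
    default_hierarchy,
)
from .escore import CustomWeights
from .models import (
    AnalysisGoal,
    DiseaseState,
    EffectType,
    Modality,
    NoveltyClass,
    Outcome,
    PatientShare,
    PieceOfEvidence,
    Reference,
    ReviewConclusion,
    ShareEntry,
    StudyType,
    TherapeuticGoal,
    Treatment,
)
from .store import EvidenceStore
from .value_matrix import (
    DEFAULT_SQUARES,
    MatrixLayout,
    ValueMatrix,
    default_layout,
    uniform_matrix,
)

DEFAULT_TAG_VOCABULARY = (
    "breast",
    "colon",
    "lung",
    "prostate",
    "melanoma",
    "stomach",
    "her2-positive",
    "egfr-mutant",
    "anti-angiogenesis",
    "postmenopausal",
    "elderly",
    "early-onset",
)

_STUDY_TYPES = list(StudyType)
_MODALITIES = [m for m in Modality if m is not Modality.group]


class CorpusParams(BaseModel):
    """Study conditions for corpus generation.

    Defaults describe a mid-sized curated corpus: 20 treatments averaging
    8 pieces each over 1995-2015, an RCT-heavy study-type mix, 60% of
    analyses significant after correction, 5% toxicity failures, 10% group
    evidence, and a 10% chance per treatment of a later review override.
    """

    n_treatments: int = Field(default=20, ge=0)
    pieces_per_treatment_mean: float = Field(default=8.0, gt=0)
    study_type_mix: dict[StudyType, float] = Field(
        default_factory=lambda: {
            StudyType.rct: 0.50,
            StudyType.meta_analysis: 0.10,
            StudyType.systematic_review: 0.05,
            StudyType.observational: 0.20,
            StudyType.retrospective: 0.10,
            StudyType.historical: 0.05,
        }
    )
    year_range: tuple[int, int] = (1995, 2015)
    p_significant: float = Field(default=0.6, ge=0, le=1)
    p_toxicity_failure: float = Field(default=0.05, ge=0, le=1)
    p_group_evidence: float = Field(default=0.1, ge=0, le=1)
    group_size_range: tuple[int, int] = (2, 5)
    p_override_event: float = Field(default=0.1, ge=0, le=1)
    matrix_schedule: list[ValueMatrix] = Field(
        default_factory=lambda: [uniform_matrix(datetime.date(1990, 1, 1))]
    )
    tag_vocabulary: tuple[str, ...] = DEFAULT_TAG_VOCABULARY
    max_tags_per_piece: int = Field(default=2, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CorpusParams":
        total = sum(self.study_type_mix.values())
        if any(p < 0 for p in self.study_type_mix.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("study_type_mix must be non-negative and sum to 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be non-empty")
        lo, hi = self.group_size_range
        if lo < 2 or hi < lo:
            raise ValueError("group_size_range must satisfy 2 <= lo <= hi")
        return self


@dataclass
class GeneratedCorpus:
    """A generated store with its matrices and any override review ids."""

    store: EvidenceStore
    matrices: list[ValueMatrix]
    override_review_ids: list[str] = field(default_factory=list)


def _random_date(rng: np.random.Generator, year_lo: int, year_hi: int) -> datetime.date:
    start = datetime.date(year_lo, 1, 1)
    end = datetime.date(year_hi, 12, 31)
    offset = int(rng.integers(0, (end - start).days + 1))
    return start + datetime.timedelta(days=offset)


def generate_corpus(params: CorpusParams) -> GeneratedCorpus:
    """Generate a referentially intact, schema-valid store from params."""
    master = np.random.SeedSequence(params.seed)
    treatment_ss, reference_ss, piece_ss, override_ss = master.spawn(4)
    rng_t = np.random.default_rng(treatment_ss)
    rng_r = np.random.default_rng(reference_ss)
    rng_p = np.random.default_rng(piece_ss)
    rng_o = np.random.default_rng(override_ss)

    store = EvidenceStore()
    year_lo, year_hi = params.year_range

    treatments = []
    for i in range(params.n_treatments):
        tid = f"T{i:03d}"
        share_date = _random_date(rng_t, year_lo, year_hi)
        history = [ShareEntry(date=share_date, share=PatientShare.some)]
        if rng_t.random() < 0.4 and share_date.year < year_hi:
            history.append(
                ShareEntry(
                    date=_random_date(rng_t, share_date.year + 1, year_hi + 1),
                    share=PatientShare.most,
                )
            )
        treatment = Treatment(
            treatment_id=tid,
            name=f"treatment-{i:03d}",
            modality=_MODALITIES[int(rng_t.integers(len(_MODALITIES)))],
            novelty_class=NoveltyClass.new
            if rng_t.random() < 0.7
            else NoveltyClass.improvement,
            molecular_eligibility=bool(rng_t.random() < 0.3),
            patient_share_history=history,
        )
        store.add_record(treatment)
        treatments.append(treatment)

    mix_types = list(params.study_type_mix)
    mix_probs = np.array([params.study_type_mix[t] for t in mix_types])
    states = list(DiseaseState)
    goals = list(TherapeuticGoal)
    tags = list(params.tag_vocabulary)

    override_reviews = []
    ref_counter = 0
    piece_counter = 0
    for treatment in treatments:
        n_pieces = max(1, int(rng_p.poisson(params.pieces_per_treatment_mean)))
        # keep one recurring context per treatment so overrides have targets
        home_state = states[int(rng_p.integers(len(states)))]
        home_goal = goals[int(rng_p.integers(len(goals)))]
        last_date = None
        for _ in range(n_pieces):
            ref_counter += 1
            ref_id = f"R{ref_counter:05d}"
            pub_date = _random_date(rng_r, year_lo, year_hi)
            study_type = mix_types[int(rng_r.choice(len(mix_types), p=mix_probs))]
            store.add_record(
                Reference(
                    ref_id=ref_id,
                    publication_date=pub_date,
                    study_type=study_type,
                    description=f"synthetic study of {treatment.treatment_id}",
                )
            )
            in_home_context = rng_p.random() < 0.7
            state = home_state if in_home_context else states[int(rng_p.integers(len(states)))]
            goal = home_goal if in_home_context else goals[int(rng_p.integers(len(goals)))]
            group = bool(rng_p.random() < params.p_group_evidence)
            lo, hi = params.group_size_range
            group_size = int(rng_p.integers(lo, hi + 1)) if group else 1
            n_tags = int(rng_p.integers(0, params.max_tags_per_piece + 1))
            piece_tags = (
                rng_p.choice(tags, size=n_tags, replace=False) if n_tags else []
            )
            significant = bool(rng_p.random() < params.p_significant)
            piece_counter += 1
            store.add_record(
                PieceOfEvidence(
                    piece_id=f"P{piece_counter:05d}",
                    ref_id=ref_id,
                    treatment_id=treatment.treatment_id,
                    disease_state=state,
                    therapeutic_goal=goal,
                    outcome=Outcome.overall_survival,
                    analysis_goal=AnalysisGoal.superiority
                    if rng_p.random() < 0.9
                    else AnalysisGoal.non_inferiority,
                    subgroup_tags=frozenset(str(t) for t in piece_tags),
                    significant_after_correction=significant,
                    effect_size=round(float(rng_p.uniform(0.5, 1.0)), 3)
                    if significant
                    else None,
                    effect_type=EffectType.hazard_ratio if significant else None,
                    group_evidence=group,
                    group_size=group_size,
                    failed_due_to_toxicity=bool(
                        rng_p.random() < params.p_toxicity_failure
                    ),
                )
            )
            if last_date is None or pub_date > last_date:
                last_date = pub_date
        # occasional override event: a later top-tier review of the home context
        if rng_o.random() < params.p_override_event and last_date is not None:
            ref_counter += 1
            review_ref = f"R{ref_counter:05d}"
            review_date = last_date + datetime.timedelta(
                days=int(rng_o.integers(30, 400))
            )
            store.add_record(
                Reference(
                    ref_id=review_ref,
                    publication_date=review_date,
                    study_type=StudyType.meta_analysis,
                    description=f"synthetic pooled review of {treatment.treatment_id}",
                )
            )
            piece_counter += 1
            review_id = f"P{piece_counter:05d}"
            store.add_record(
                PieceOfEvidence(
                    piece_id=review_id,
                    ref_id=review_ref,
                    treatment_id=treatment.treatment_id,
                    disease_state=home_state,
                    therapeutic_goal=home_goal,
                    outcome=Outcome.overall_survival,
                    significant_after_correction=False,
                    review_conclusion=ReviewConclusion.insufficient_support,
                )
            )
            override_reviews.append(review_id)

    store.validate()
    return GeneratedCorpus(
        store=store,
        matrices=list(params.matrix_schedule),
        override_review_ids=override_reviews,
    )


# -- deterministic scenario fixtures --------------------------------------


@dataclass
class ScenarioFixture:
    """A small, fully deterministic store with matching configs."""

    name: str
    store: EvidenceStore
    layout: MatrixLayout
    hierarchy: EvidenceHierarchy
    scoring: ScoringConfig
    custom: CustomWeights
    matrices: dict[str, list[ValueMatrix]]
    review_ids: list[str] = field(default_factory=list)
    description: str = ""


SCENARIOS = (
    "stepwise_accumulation",
    "reversal",
    "targeted_then_broadened",
    "curative_vs_uniform",
)


def _base_fixture(name: str, description: str) -> ScenarioFixture:
    return ScenarioFixture(
        name=name,
        store=EvidenceStore(),
        layout=default_layout(),
        hierarchy=default_hierarchy(),
        scoring=ScoringConfig(),
        custom=CustomWeights(),
        matrices={"uniform": [uniform_matrix(datetime.date(1990, 1, 1))]},
        description=description,
    )


def _add_rct_piece(
    store: EvidenceStore,
    piece_id: str,
    treatment_id: str,
    year: int,
    state: DiseaseState,
    goal: TherapeuticGoal,
    *,
    month: int = 6,
    significant: bool = True,
    tags: Sequence[str] = (),
    study_type: StudyType = StudyType.rct,
) -> PieceOfEvidence:
    ref_id = f"ref-{piece_id}"
    store.add_record(
        Reference(
            ref_id=ref_id,
            publication_date=datetime.date(year, month, 15),
            study_type=study_type,
        )
    )
    piece = PieceOfEvidence(
        piece_id=piece_id,
        ref_id=ref_id,
        treatment_id=treatment_id,
        disease_state=state,
        therapeutic_goal=goal,
        significant_after_correction=significant,
        subgroup_tags=frozenset(tags),
    )
    store.add_record(piece)
    return piece


def scenario(name: str) -> ScenarioFixture:
    """Deterministic small fixtures with documented qualitative behaviour."""
    if name == "stepwise_accumulation":
        fx = _base_fixture(
            name,
            "one chemotherapy treatment gathering six significant trials in "
            "six distinct years: the uniform-weight series is a staircase",
        )
        fx.store.add_record(
            Treatment(
                treatment_id="T1",
                name="stepwise chemo",
                modality=Modality.chemotherapy,
                patient_share_history=[
                    ShareEntry(date=datetime.date(2000, 1, 1), share=PatientShare.most)
                ],
            )
        )
        for i, year in enumerate([2001, 2003, 2005, 2008, 2010, 2013]):
            _add_rct_piece(
                fx.store,
                f"S{i+1}",
                "T1",
                year,
                DiseaseState.regional,
                TherapeuticGoal.stop_progression,
            )
        return fx

    if name == "reversal":
        fx = _base_fixture(
            name,
            "three active trials for one treatment in square D, then an "
            "insufficient-support meta-analysis overriding them",
        )
        fx.store.add_record(
            Treatment(
                treatment_id="T1",
                name="reversed drug",
                modality=Modality.chemotherapy,
            )
        )
        for i, year in enumerate([2002, 2004, 2006]):
            _add_rct_piece(
                fx.store,
                f"E{i+1}",
                "T1",
                year,
                DiseaseState.advanced,
                TherapeuticGoal.stop_progression,
            )
        fx.store.add_record(
            Reference(
                ref_id="ref-REV",
                publication_date=datetime.date(2008, 3, 1),
                study_type=StudyType.meta_analysis,
            )
        )
        fx.store.add_record(
            PieceOfEvidence(
                piece_id="REV",
                ref_id="ref-REV",
                treatment_id="T1",
                disease_state=DiseaseState.advanced,
                therapeutic_goal=TherapeuticGoal.stop_progression,
                significant_after_correction=False,
                review_conclusion=ReviewConclusion.insufficient_support,
            )
        )
        fx.review_ids = ["REV"]
        return fx

    if name == "targeted_then_broadened":
        fx = _base_fixture(
            name,
            "a molecularly targeted treatment first offered to some patients "
            "(small circle), later broadened to most (circle grows)",
        )
        fx.store.add_record(
            Treatment(
                treatment_id="T1",
                name="targeted agent",
                modality=Modality.immunotherapy,
                molecular_eligibility=True,
                patient_share_history=[
                    ShareEntry(date=datetime.date(2008, 1, 1), share=PatientShare.some),
                    ShareEntry(date=datetime.date(2013, 1, 1), share=PatientShare.most),
                ],
            )
        )
        _add_rct_piece(
            fx.store,
            "N1",
            "T1",
            2009,
            DiseaseState.advanced,
            TherapeuticGoal.stop_progression,
            tags=["egfr-mutant"],
        )
        _add_rct_piece(
            fx.store,
            "N2",
            "T1",
            2014,
            DiseaseState.advanced,
            TherapeuticGoal.stop_progression,
        )
        return fx

    if name == "curative_vs_uniform":
        fx = _base_fixture(
            name,
            "one treatment with only curative-square evidence and one with "
            "only square-D evidence; curative up-weighting separates them",
        )
        for tid, nm in (("TCURE", "curative surgery"), ("TSTOP", "stabilising drug")):
            fx.store.add_record(
                Treatment(
                    treatment_id=tid,
                    name=nm,
                    modality=Modality.surgery if tid == "TCURE" else Modality.chemotherapy,
                )
            )
        for i, year in enumerate([2001, 2004, 2007]):
            _add_rct_piece(
                fx.store,
                f"C{i+1}",
                "TCURE",
                year,
                DiseaseState.advanced,
                TherapeuticGoal.become_disease_free,  # square A (curative)
            )
        for i, year in enumerate([2002, 2005, 2008]):
            _add_rct_piece(
                fx.store,
                f"D{i+1}",
                "TSTOP",
                year,
                DiseaseState.advanced,
                TherapeuticGoal.stop_progression,  # square D
            )
        curative_weights = {
            s: (2.0 if s in fx.layout.curative_set else 1.0) for s in DEFAULT_SQUARES
        }
        fx.matrices["curative"] = [
            ValueMatrix(
                effective_date=datetime.date(1990, 1, 1), weights=curative_weights
            )
        ]
        return fx

    raise UnknownScenarioError(
        f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}"
    )
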