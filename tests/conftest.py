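import datetime

import pytest

from cii import (
    CustomWeights,
    DiseaseState,
    EvidenceStore,
    Modality,
    Outcome,
    PieceOfEvidence,
    Reference,
    ScoringConfig,
    StudyType,
    TherapeuticGoal,
    Treatment,
    default_hierarchy,
    default_layout,
    uniform_matrix,
)


def add_piece(
    store: EvidenceStore,
    piece_id: str,
    treatment_id: str,
    year: int,
    state: DiseaseState = DiseaseState.advanced,
    goal: TherapeuticGoal = TherapeuticGoal.stop_progression,
    *,
    month: int = 6,
    day: int = 15,
    study_type: StudyType = StudyType.rct,
    significant: bool = True,
    **piece_kwargs,
) -> PieceOfEvidence:
    """Insert a reference + piece pair with sensible defaults."""
    ref_id = f"ref-{piece_id}"
    store.add_record(
        Reference(
            ref_id=ref_id,
            publication_date=datetime.date(year, month, day),
            study_type=study_type,
        )
    )
    piece = PieceOfEvidence(
        piece_id=piece_id,
        ref_id=ref_id,
        treatment_id=treatment_id,
        disease_state=state,
        therapeutic_goal=goal,
        outcome=Outcome.overall_survival,
        significant_after_correction=significant,
        **piece_kwargs,
    )
    store.add_record(piece)
    return piece


def make_store(treatment_ids=("T1",), modality=Modality.chemotherapy) -> EvidenceStore:
    store = EvidenceStore()
    for tid in treatment_ids:
        store.add_record(Treatment(treatment_id=tid, name=tid, modality=modality))
    return store


@pytest.fixture
def hierarchy():
    return default_hierarchy()


@pytest.fixture
def layout():
    return default_layout()


@pytest.fixture
def scoring():
    return ScoringConfig()


@pytest.fixture
def custom():
    return CustomWeights()


@pytest.fixture
def matrices():
    return [uniform_matrix(datetime.date(1990, 1, 1))]
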