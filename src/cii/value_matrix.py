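"""Value Matrix: stakeholder weights over (disease state, therapeutic goal).

The matrix is a grid of labelled squares.  Each combination of disease
state and therapeutic goal resolves to exactly one square; stakeholders
assign each square a non-negative weight expressing how much they value
achieving that goal in that state (e.g. a curative-minded stakeholder
up-weights the cure squares A, C, F, J).  Because values drift over time,
several dated matrices may be supplied; scoring uses the closest matrix
whose effective date precedes (or equals) the date of interest.

Square labels are for classification only and confer no value judgment;
the engine never orders squares by label.  The full 16-cell layout below
is provisional apart from the anchored cells (A, D, H, J, and the cure
column C, F): edit the layout file to change the rest.
"""

from __future__ import annotations

import datetime
from typing import Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import MissingKeyError
from .models import DiseaseState, TherapeuticGoal

# cells fixed by the matrix semantics; a layout that relabels them is invalid
_ANCHORS = {
    (DiseaseState.advanced, TherapeuticGoal.become_disease_free): "A",
    (DiseaseState.advanced, TherapeuticGoal.stop_progression): "D",
    (DiseaseState.regional, TherapeuticGoal.stop_progression): "H",
    (DiseaseState.resected, TherapeuticGoal.become_disease_free): "J",
}

DEFAULT_SQUARES = ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J"]
DEFAULT_CURATIVE = frozenset({"A", "C", "F", "J"})


class MatrixLayout(BaseModel):
    """Square labels and the total (state, goal) -> square mapping."""

    squares: list[str] = Field(default_factory=lambda: list(DEFAULT_SQUARES))
    mapping: dict[DiseaseState, dict[TherapeuticGoal, str]]
    curative_set: frozenset[str] = DEFAULT_CURATIVE

    @model_validator(mode="after")
    def _check(self) -> "MatrixLayout":
        for state in DiseaseState:
            goals = self.mapping.get(state)
            if goals is None:
                raise ValueError(f"layout mapping missing disease state {state.value}")
            for goal in TherapeuticGoal:
                label = goals.get(goal)
                if label is None:
                    raise ValueError(
                        f"layout mapping missing cell ({state.value}, {goal.value})"
                    )
                if label not in self.squares:
                    raise ValueError(
                        f"cell ({state.value}, {goal.value}) maps to unknown "
                        f"square {label!r}"
                    )
        missing = self.curative_set - set(self.squares)
        if missing:
            raise ValueError(f"curative squares not in layout: {sorted(missing)}")
        if set(_ANCHORS.values()) <= set(self.squares):
            for (state, goal), label in _ANCHORS.items():
                if self.mapping[state][goal] != label:
                    raise ValueError(
                        f"anchored cell ({state.value}, {goal.value}) must map to "
                        f"{label!r}, got {self.mapping[state][goal]!r}"
                    )
        return self


def default_layout() -> MatrixLayout:
    """Ten squares A-J; cure of each disease state occupies the curative
    column {A, C, F, J}; unanchored cells are provisional."""
    return MatrixLayout(
        mapping={
            DiseaseState.advanced: {
                TherapeuticGoal.become_disease_free: "A",
                TherapeuticGoal.stop_progression: "D",
                TherapeuticGoal.shrink_or_slow: "B",
                TherapeuticGoal.symptom_relief: "G",
            },
            DiseaseState.regional: {
                TherapeuticGoal.become_disease_free: "C",
                TherapeuticGoal.stop_progression: "H",
                TherapeuticGoal.shrink_or_slow: "E",
                TherapeuticGoal.symptom_relief: "G",
            },
            DiseaseState.localized: {
                TherapeuticGoal.become_disease_free: "F",
                TherapeuticGoal.stop_progression: "I",
                TherapeuticGoal.shrink_or_slow: "I",
                TherapeuticGoal.symptom_relief: "I",
            },
            DiseaseState.resected: {
                TherapeuticGoal.become_disease_free: "J",
                TherapeuticGoal.stop_progression: "J",
                TherapeuticGoal.shrink_or_slow: "J",
                TherapeuticGoal.symptom_relief: "J",
            },
        },
    )


class ValueMatrix(BaseModel):
    """One dated set of stakeholder weights, one per square."""

    effective_date: datetime.date
    weights: dict[str, float]

    @field_validator("weights")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for square, w in v.items():
            if w < 0:
                raise ValueError(f"weight for square {square!r} must be >= 0")
        return v


def uniform_matrix(
    effective_date: datetime.date = datetime.date(1900, 1, 1),
    squares: Sequence[str] = DEFAULT_SQUARES,
    value: float = 1.0,
) -> ValueMatrix:
    """Every square valued equally (the neutral baseline)."""
    return ValueMatrix(
        effective_date=effective_date, weights={s: value for s in squares}
    )


class TreatmentGoalPath(BaseModel):
    """An annotated multimodal-synergy link between treatments and squares
    (e.g. neo-adjuvant therapy enabling curative surgery).  Annotation and
    visualization only: paths do not alter scores."""

    path_id: str
    nodes: list[tuple[str, str]]  # (treatment_id, square label)
    annotation: str = ""

    @field_validator("nodes")
    @classmethod
    def _at_least_two(cls, v):
        if len(v) < 2:
            raise ValueError("a treatment goal path needs at least 2 nodes")
        return v


def resolve_square(
    disease_state: DiseaseState,
    therapeutic_goal: TherapeuticGoal,
    layout: MatrixLayout,
) -> str:
    """The unique square for a (disease state, goal) combination."""
    try:
        return layout.mapping[disease_state][therapeutic_goal]
    except KeyError:
        raise MissingKeyError(
            f"no square mapped for ({disease_state.value}, {therapeutic_goal.value})"
        ) from None


def select_matrix(
    date: datetime.date, matrices: Sequence[ValueMatrix]
) -> ValueMatrix:
    """The matrix with the latest effective date on or before ``date``.

    Dates before the earliest matrix fall back to the earliest matrix, so a
    matrix always applies (no zero-weight dead zone).
    """
    if not matrices:
        raise MissingKeyError("no value matrices supplied")
    dates = [m.effective_date for m in matrices]
    if len(set(dates)) != len(dates):
        raise ValueError("value matrix effective_dates must be unique")
    ordered = sorted(matrices, key=lambda m: m.effective_date)
    chosen = ordered[0]
    for m in ordered:
        if m.effective_date <= date:
            chosen = m
        else:
            break
    return chosen


def value_weight(
    square: str, date: datetime.date, matrices: Sequence[ValueMatrix]
) -> float:
    """Stakeholder weight of a square under the matrix in force at ``date``."""
    matrix = select_matrix(date, matrices)
    if square not in matrix.weights:
        raise MissingKeyError(
            f"square {square!r} absent from value matrix dated "
            f"{matrix.effective_date.isoformat()}"
        )
    return matrix.weights[square]
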