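"""Cumulative Evidence-Score (E-Score) computation.

An E-Score series is the running sum, by calendar year, of the
contributions of qualifying pieces of evidence.  Each contribution is the
product

    evidence weight  x  value weight  x  custom weight

where the evidence weight comes from the study-type hierarchy (with the
1/k split for group evidence), the value weight is the stakeholder weight
of the piece's matrix square under the value matrix in force at the
piece's publication date, and the custom weight folds in optional
modality multipliers, effect-size adjustments and per-piece overrides.
Non-qualifying pieces contribute exactly 0, so within one data release a
series can never decrease.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, Field, field_validator

from .errors import CIIError
from .hierarchy import (
    EvidenceHierarchy,
    ScoringConfig,
    evidence_weight,
    qualifies,
)
from .models import EffectType, Modality, PieceOfEvidence, Query
from .store import EvidenceStore
from .value_matrix import MatrixLayout, ValueMatrix, resolve_square, value_weight


class CustomWeights(BaseModel):
    """Optional stakeholder adjustments; the default is the constant 1.

    ``effect_size_rule='linear_in_benefit'`` scales by 1 + s*(1-HR) for
    hazard ratios below 1, or 1 + s*(months gained)/12 for median-survival
    differences, with slope ``effect_slope`` (default 0, i.e. inert).
    """

    modality_multiplier: dict[Modality, float] = Field(default_factory=dict)
    effect_size_rule: Literal["none", "linear_in_benefit"] = "none"
    effect_slope: float = 0.0
    per_piece_override: dict[str, float] = Field(default_factory=dict)

    @field_validator("modality_multiplier", "per_piece_override")
    @classmethod
    def _nonneg(cls, v):
        for k, m in v.items():
            if m < 0:
                raise ValueError(f"multiplier for {k!r} must be >= 0")
        return v

    def multiplier(self, piece: PieceOfEvidence, modality: Modality) -> float:
        m = self.modality_multiplier.get(modality, 1.0)
        if self.effect_size_rule == "linear_in_benefit" and piece.effect_size is not None:
            if piece.effect_type is EffectType.hazard_ratio:
                m *= 1.0 + self.effect_slope * max(0.0, 1.0 - piece.effect_size)
            elif piece.effect_type is EffectType.median_survival_difference_months:
                m *= 1.0 + self.effect_slope * max(0.0, piece.effect_size) / 12.0
        m *= self.per_piece_override.get(piece.piece_id, 1.0)
        return m


@dataclass
class EScoreSeries:
    """Yearly cumulative score with the query and config that produced it."""

    scores: dict[int, float]  # ascending years -> cumulative score
    n_pieces: dict[int, int]  # cumulative count of pieces counted
    query_descriptor: str = "ALL"
    fingerprint: str = ""

    @property
    def years(self) -> list[int]:
        return list(self.scores)

    def final(self) -> float:
        return next(reversed(self.scores.values()), 0.0) if self.scores else 0.0

    def as_rows(self) -> list[dict]:
        return [
            {"year": y, "score": self.scores[y], "n_pieces_counted": self.n_pieces[y]}
            for y in self.scores
        ]


def config_fingerprint(
    hierarchy: EvidenceHierarchy,
    matrices: Sequence[ValueMatrix],
    custom: CustomWeights,
    layout: Optional[MatrixLayout] = None,
    cfg: Optional[ScoringConfig] = None,
) -> str:
    """Stable hash of every weight input; changes iff any input changes."""
    payload = {
        "hierarchy": hierarchy.model_dump(mode="json"),
        "matrices": sorted(
            (m.model_dump(mode="json") for m in matrices),
            key=lambda d: d["effective_date"],
        ),
        "custom": custom.model_dump(mode="json"),
        "layout": layout.model_dump(mode="json") if layout else None,
        "scoring": (
            {
                **cfg.model_dump(mode="json"),
                "outcomes_in_scope": sorted(
                    o.value for o in cfg.outcomes_in_scope
                ),
            }
            if cfg
            else None
        ),
    }
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def piece_contribution(
    piece: PieceOfEvidence,
    store: EvidenceStore,
    hierarchy: EvidenceHierarchy,
    matrices: Sequence[ValueMatrix],
    custom: CustomWeights,
    layout: MatrixLayout,
    cfg: ScoringConfig,
) -> float:
    """evidence weight x value weight x custom weight; 0 if non-qualifying."""
    if not qualifies(piece, cfg):
        return 0.0
    ew = evidence_weight(piece, hierarchy, store=store)
    square = resolve_square(piece.disease_state, piece.therapeutic_goal, layout)
    vw = value_weight(square, store.piece_date(piece), matrices)
    cw = custom.multiplier(piece, store.get_treatment(piece.treatment_id).modality)
    return ew * vw * cw


@dataclass
class _Counted:
    """One qualifying piece with its contribution, in scoring order."""

    year: int
    piece_id: str
    contribution: float
    ev_weight: float
    key: tuple  # (treatment_id, square) pooling key


def _counted_pieces(
    pieces: Sequence[PieceOfEvidence],
    store: EvidenceStore,
    hierarchy: EvidenceHierarchy,
    matrices: Sequence[ValueMatrix],
    custom: CustomWeights,
    layout: MatrixLayout,
    cfg: ScoringConfig,
) -> list[_Counted]:
    ordered = sorted(pieces, key=lambda p: (store.piece_date(p), p.piece_id))
    out = []
    for piece in ordered:
        if not qualifies(piece, cfg):
            continue
        ew = evidence_weight(piece, hierarchy, store=store)
        square = resolve_square(piece.disease_state, piece.therapeutic_goal, layout)
        vw = value_weight(square, store.piece_date(piece), matrices)
        cw = custom.multiplier(
            piece, store.get_treatment(piece.treatment_id).modality
        )
        out.append(
            _Counted(
                year=store.piece_date(piece).year,
                piece_id=piece.piece_id,
                contribution=ew * vw * cw,
                ev_weight=ew,
                key=(piece.treatment_id, square),
            )
        )
    return out


def _apply_count_threshold(
    counted: list[_Counted], threshold: float
) -> list[tuple[int, float, int]]:
    """(year, amount, n_pieces) increments after threshold pooling.

    Contributions for a (treatment, square) accrue in a pending pool until
    the pool's cumulative *evidence* weight reaches the threshold; then the
    whole pool counts in the year of the piece that crossed it, and later
    pieces count immediately.  Threshold 0 makes this a no-op.
    """
    if threshold <= 0:
        return [(c.year, c.contribution, 1) for c in counted]
    increments: list[tuple[int, float, int]] = []
    pending: dict[tuple, list[_Counted]] = {}
    pending_weight: dict[tuple, float] = {}
    released: set[tuple] = set()
    for c in counted:
        if c.key in released:
            increments.append((c.year, c.contribution, 1))
            continue
        pool = pending.setdefault(c.key, [])
        pool.append(c)
        pending_weight[c.key] = pending_weight.get(c.key, 0.0) + c.ev_weight
        if pending_weight[c.key] >= threshold:
            total = sum(p.contribution for p in pool)
            increments.append((c.year, total, len(pool)))
            released.add(c.key)
            del pending[c.key]
    return increments


def _series_from_pieces(
    pieces: Sequence[PieceOfEvidence],
    store: EvidenceStore,
    hierarchy: EvidenceHierarchy,
    matrices: Sequence[ValueMatrix],
    custom: CustomWeights,
    layout: MatrixLayout,
    cfg: ScoringConfig,
    start_year: int,
    end_year: int,
    descriptor: str,
    fingerprint: str,
) -> EScoreSeries:
    counted = _counted_pieces(
        pieces, store, hierarchy, matrices, custom, layout, cfg
    )
    increments = _apply_count_threshold(counted, cfg.count_threshold)
    by_year: dict[int, float] = {}
    n_by_year: dict[int, int] = {}
    for year, amount, n in increments:
        by_year[year] = by_year.get(year, 0.0) + amount
        n_by_year[year] = n_by_year.get(year, 0) + n
    scores: dict[int, float] = {}
    counts: dict[int, int] = {}
    running, running_n = 0.0, 0
    for year in range(start_year, end_year + 1):
        running += by_year.get(year, 0.0)
        running_n += n_by_year.get(year, 0)
        scores[year] = running
        counts[year] = running_n
    return EScoreSeries(
        scores=scores,
        n_pieces=counts,
        query_descriptor=descriptor,
        fingerprint=fingerprint,
    )


def compute_escore_series(
    query: Query,
    store: EvidenceStore,
    hierarchy: EvidenceHierarchy,
    matrices: Sequence[ValueMatrix],
    custom: CustomWeights,
    layout: MatrixLayout,
    cfg: ScoringConfig,
    end_year: int,
    start_year: Optional[int] = None,
) -> EScoreSeries:
    """Cumulative E-Score by year for the pieces matching ``query``.

    The year axis runs from the year before the earliest matched piece
    (a visible zero baseline) through ``end_year``; an empty match yields
    an all-zero series.
    """
    matched = store.query_pieces(query)
    if matched:
        first = min(store.piece_date(p).year for p in matched)
        if end_year < first:
            raise CIIError(
                f"end_year {end_year} precedes earliest piece year {first}"
            )
        if start_year is None:
            start_year = first - 1
    elif start_year is None:
        start_year = end_year
    fp = config_fingerprint(hierarchy, matrices, custom, layout, cfg)
    return _series_from_pieces(
        matched,
        store,
        hierarchy,
        matrices,
        custom,
        layout,
        cfg,
        start_year,
        end_year,
        query.describe(),
        fp,
    )


def stratified_scores(
    partition_tag_values: Sequence[str],
    query: Query,
    store: EvidenceStore,
    hierarchy: EvidenceHierarchy,
    matrices: Sequence[ValueMatrix],
    custom: CustomWeights,
    layout: MatrixLayout,
    cfg: ScoringConfig,
    end_year: int,
) -> dict[str, EScoreSeries]:
    """One series per stratum tag, all on the same year axis and config.

    The tag values must partition the matched pieces: a piece carrying two
    partition tags, or none, is rejected (otherwise per-stratum series
    could not sum to the unstratified series).
    """
    matched = store.query_pieces(query)
    strata: dict[str, list[PieceOfEvidence]] = {t: [] for t in partition_tag_values}
    overlapping, uncovered = [], []
    for piece in matched:
        hits = [t for t in partition_tag_values if t in piece.subgroup_tags]
        if len(hits) > 1:
            overlapping.append(piece.piece_id)
        elif not hits:
            uncovered.append(piece.piece_id)
        else:
            strata[hits[0]].append(piece)
    if overlapping:
        raise CIIError(
            "strata overlap: pieces matched by more than one partition tag: "
            + ", ".join(overlapping)
        )
    if uncovered:
        raise CIIError(
            "partition does not cover matched pieces: " + ", ".join(uncovered)
        )
    if matched:
        start_year = min(store.piece_date(p).year for p in matched) - 1
    else:
        start_year = end_year
    fp = config_fingerprint(hierarchy, matrices, custom, layout, cfg)
    return {
        tag: _series_from_pieces(
            strata[tag],
            store,
            hierarchy,
            matrices,
            custom,
            layout,
            cfg,
            start_year,
            end_year,
            f"{query.describe()} | stratum tag:{tag}",
            fp,
        )
        for tag in partition_tag_values
    }
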