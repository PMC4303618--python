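"""Immutable data releases, systematic-review overrides, audit trail.

A top-functional-tier review (meta-analysis or systematic review)
concluding that the evidence for a treatment in a given context no longer
supports it causes all prior pieces in that context to be *disregarded,
not deleted*.  The disqualification is deferred: pieces are flagged
pending and take effect only at the next data release, so published score
curves never dip mid-release — the whole curve is lower in the following
release, but its slope is never negative.  Every status change writes
exactly one append-only audit entry, and no record is ever deleted, which
keeps the full history accountable and lets analysts count how often
treatments that once showed significant effects were later re-assessed
and found ineffective.
"""

from __future__ import annotations

import copy
import datetime
from dataclasses import dataclass, field
from typing import Optional

from .errors import CIIError, FunctionalTierError
from .hierarchy import EvidenceHierarchy, default_hierarchy
from .models import (
    AuditEntry,
    Outcome,
    PieceOfEvidence,
    PieceStatus,
    ReviewConclusion,
)
from .store import EvidenceStore
from .value_matrix import MatrixLayout, resolve_square


@dataclass(frozen=True)
class Context:
    """The width of an override: one treatment, one matrix square, one
    outcome; a tagged review additionally restricts to same-tagged pieces."""

    treatment_id: str
    square: str
    outcome: Outcome
    tags: frozenset[str] = frozenset()


@dataclass
class Release:
    """An immutable snapshot: frozen copy of the store, content hash, and
    the transitions applied when the release was cut."""

    release_id: int
    created_date: datetime.date
    snapshot_hash: str
    applied_transitions: list[AuditEntry] = field(default_factory=list)
    snapshot: Optional[EvidenceStore] = None


def piece_context(
    piece: PieceOfEvidence, layout: MatrixLayout, *, with_tags: bool = False
) -> Context:
    return Context(
        treatment_id=piece.treatment_id,
        square=resolve_square(piece.disease_state, piece.therapeutic_goal, layout),
        outcome=piece.outcome,
        tags=piece.subgroup_tags if with_tags else frozenset(),
    )


def apply_override(
    review_piece: PieceOfEvidence,
    store: EvidenceStore,
    layout: MatrixLayout,
    hierarchy: Optional[EvidenceHierarchy] = None,
) -> list[str]:
    """Disregard (not delete) all prior pieces in the review's context.

    Only a review from the top functional tier with an insufficient-support
    conclusion may override.  Matching active pieces dated on or before the
    review date become ``disqualified_pending``; scores computed against any
    existing release snapshot are untouched.  Returns the affected ids in
    deterministic (date, piece_id) order.
    """
    hierarchy = hierarchy or default_hierarchy()
    if review_piece.piece_id not in store.pieces:
        store.add_record(review_piece)
    review_type = store.study_type(review_piece)
    if hierarchy.functional_tier.get(review_type, -1) != hierarchy.top_tier():
        raise FunctionalTierError(
            f"study type {review_type.value!r} is below the top functional tier; "
            "only meta-analyses and systematic reviews may override"
        )
    if review_piece.review_conclusion is not ReviewConclusion.insufficient_support:
        raise CIIError(
            "only a review concluding insufficient_support triggers an override"
        )
    review_date = store.piece_date(review_piece)
    review_square = resolve_square(
        review_piece.disease_state, review_piece.therapeutic_goal, layout
    )
    targets = []
    for piece in store.pieces.values():
        if piece.piece_id == review_piece.piece_id:
            continue
        if piece.status is not PieceStatus.active:
            continue
        if piece.treatment_id != review_piece.treatment_id:
            continue
        if piece.outcome is not review_piece.outcome:
            continue
        square = resolve_square(piece.disease_state, piece.therapeutic_goal, layout)
        if square != review_square:
            continue
        # a tagged review disqualifies only same-tagged pieces
        if review_piece.subgroup_tags and not (
            review_piece.subgroup_tags <= piece.subgroup_tags
        ):
            continue
        if store.piece_date(piece) > review_date:
            continue
        targets.append(piece)
    targets.sort(key=lambda p: (store.piece_date(p), p.piece_id))
    for piece in targets:
        store.transition_status(
            piece.piece_id,
            PieceStatus.disqualified_pending,
            cause_piece_id=review_piece.piece_id,
            timestamp=review_date,
            note=f"override by review {review_piece.piece_id}",
        )
    return [p.piece_id for p in targets]


def create_release(
    store: EvidenceStore, created_date: Optional[datetime.date] = None
) -> Release:
    """Cut an immutable release: pending disqualifications take effect, the
    tables are content-hashed, and a frozen snapshot is kept for scoring."""
    if created_date is None:
        dates = [
            r.publication_date for r in store.references.values()
        ]
        created_date = max(dates) if dates else datetime.date(1970, 1, 1)
    release_id = len(store.releases) + 1
    applied = []
    pending = sorted(
        (
            p
            for p in store.pieces.values()
            if p.status is PieceStatus.disqualified_pending
        ),
        key=lambda p: (store.piece_date(p), p.piece_id),
    )
    for piece in pending:
        entry = store.transition_status(
            piece.piece_id,
            PieceStatus.disqualified,
            release_id=release_id,
            timestamp=created_date,
            note=f"disqualified in release {release_id}",
        )
        applied.append(entry)
    snapshot = copy.deepcopy(store)
    snapshot.releases = []
    snapshot._frozen = True
    release = Release(
        release_id=release_id,
        created_date=created_date,
        snapshot_hash=store.content_hash(),
        applied_transitions=applied,
        snapshot=snapshot,
    )
    store.releases.append(release)
    return release


def requalify(
    new_evidence_piece: PieceOfEvidence,
    store: EvidenceStore,
    layout: MatrixLayout,
) -> list[str]:
    """Flag disqualified pieces in the new piece's context for re-review.

    New qualifying evidence in an overridden context does not silently
    restore old pieces: it marks them ``to_review``; an explicit curator
    :func:`reactivate` decision returns them to active.
    """
    if new_evidence_piece.piece_id not in store.pieces:
        store.add_record(new_evidence_piece)
    square = resolve_square(
        new_evidence_piece.disease_state, new_evidence_piece.therapeutic_goal, layout
    )
    date = store.piece_date(new_evidence_piece)
    targets = []
    for piece in store.pieces.values():
        if piece.status is not PieceStatus.disqualified:
            continue
        if piece.treatment_id != new_evidence_piece.treatment_id:
            continue
        if piece.outcome is not new_evidence_piece.outcome:
            continue
        if resolve_square(piece.disease_state, piece.therapeutic_goal, layout) != square:
            continue
        targets.append(piece)
    targets.sort(key=lambda p: (store.piece_date(p), p.piece_id))
    for piece in targets:
        store.transition_status(
            piece.piece_id,
            PieceStatus.to_review,
            cause_piece_id=new_evidence_piece.piece_id,
            timestamp=date,
            note=f"re-review triggered by {new_evidence_piece.piece_id}",
        )
    return [p.piece_id for p in targets]


def reactivate(
    piece_ids: list[str],
    store: EvidenceStore,
    *,
    timestamp: datetime.date,
    note: str = "curator re-activation",
) -> list[str]:
    """Explicit curator decision returning to_review pieces to active."""
    out = []
    for piece_id in piece_ids:
        store.transition_status(
            piece_id,
            PieceStatus.active,
            timestamp=timestamp,
            note=note,
        )
        out.append(piece_id)
    return out


def reversal_stats(
    store: EvidenceStore,
    layout: MatrixLayout,
    *,
    require_release: bool = True,
) -> dict:
    """How often evidence was reversed, from the append-only audit trail.

    Per (treatment, square): pieces ever disqualified, reactivated, and
    currently active.  Corpus totals include the number of override events
    (times treatments did not work out as planned) and contexts where a
    reversal was later restored.
    """
    if require_release and not store.releases:
        raise CIIError("reversal_stats requires at least one release")
    ever_disqualified: dict[tuple, set] = {}
    reactivated: dict[tuple, set] = {}
    override_events: set[str] = set()
    ctx_of_piece = {
        p.piece_id: (
            p.treatment_id,
            resolve_square(p.disease_state, p.therapeutic_goal, layout),
        )
        for p in store.pieces.values()
    }
    for entry in store.audit_log:
        ctx = ctx_of_piece.get(entry.piece_id)
        if ctx is None:
            continue
        if entry.new_status is PieceStatus.disqualified:
            ever_disqualified.setdefault(ctx, set()).add(entry.piece_id)
        if (
            entry.old_status is PieceStatus.active
            and entry.new_status is PieceStatus.disqualified_pending
            and entry.cause_piece_id
        ):
            override_events.add(entry.cause_piece_id)
        if (
            entry.old_status is PieceStatus.to_review
            and entry.new_status is PieceStatus.active
        ):
            reactivated.setdefault(ctx, set()).add(entry.piece_id)
    contexts = sorted(set(ever_disqualified) | set(reactivated))
    by_context = []
    for ctx in contexts:
        treatment_id, square = ctx
        active_now = sum(
            1
            for p in store.pieces.values()
            if ctx_of_piece[p.piece_id] == ctx and p.status is PieceStatus.active
        )
        by_context.append(
            {
                "treatment_id": treatment_id,
                "square": square,
                "pieces_ever_disqualified": len(ever_disqualified.get(ctx, set())),
                "pieces_reactivated": len(reactivated.get(ctx, set())),
                "pieces_currently_active": active_now,
            }
        )
    reversed_then_restored = sum(
        1
        for ctx in contexts
        if ever_disqualified.get(ctx) and reactivated.get(ctx)
    )
    return {
        "by_context": by_context,
        "totals": {
            "n_override_events": len(override_events),
            "pieces_ever_disqualified": sum(
                len(s) for s in ever_disqualified.values()
            ),
            "pieces_reactivated": sum(len(s) for s in reactivated.values()),
            "reversed_then_restored": reversed_then_restored,
            "n_releases": len(store.releases),
        },
    }
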