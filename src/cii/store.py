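"""Relational evidence store: references, treatments, pieces of evidence.

Three flat tables keyed by opaque string ids.  Nothing is ever overwritten
in place or deleted: updates append a new version row with a ``supersedes``
pointer, and every status transition of a piece appends exactly one audit
entry.  Files (CSV or JSON-lines, one per table) are the interchange format.
"""

from __future__ import annotations

import csv
import datetime
import enum
import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import (
    DuplicateKeyError,
    FrozenStoreError,
    InvalidTransitionError,
    MissingKeyError,
    UnknownFieldError,
)
from .models import (
    AuditEntry,
    FlagValue,
    PieceOfEvidence,
    PieceStatus,
    Query,
    Reference,
    ShareEntry,
    StudyType,
    Treatment,
)

Record = Union[Reference, Treatment, PieceOfEvidence]

# the only edges the status state machine admits
_ALLOWED_TRANSITIONS = {
    (PieceStatus.active, PieceStatus.disqualified_pending),
    (PieceStatus.disqualified_pending, PieceStatus.disqualified),
    (PieceStatus.disqualified, PieceStatus.to_review),
    (PieceStatus.to_review, PieceStatus.active),
}

_REFERENCE_FIELDS = list(Reference.model_fields)
_TREATMENT_FIELDS = list(Treatment.model_fields)
_PIECE_FIELDS = list(PieceOfEvidence.model_fields)


class EvidenceStore:
    """In-memory relational store with append-only version history."""

    def __init__(self) -> None:
        # key -> list of versions, oldest first; the last entry is current
        self._references: dict[str, list[Reference]] = {}
        self._treatments: dict[str, list[Treatment]] = {}
        self._pieces: dict[str, list[PieceOfEvidence]] = {}
        self.audit_log: list[AuditEntry] = []
        self.releases: list = []  # populated by release operations
        self._frozen = False

    # -- basic access -----------------------------------------------------

    @property
    def references(self) -> dict[str, Reference]:
        return {k: v[-1] for k, v in self._references.items()}

    @property
    def treatments(self) -> dict[str, Treatment]:
        return {k: v[-1] for k, v in self._treatments.items()}

    @property
    def pieces(self) -> dict[str, PieceOfEvidence]:
        return {k: v[-1] for k, v in self._pieces.items()}

    def get_reference(self, ref_id: str) -> Reference:
        try:
            return self._references[ref_id][-1]
        except KeyError:
            raise MissingKeyError(f"unknown reference {ref_id!r}") from None

    def get_treatment(self, treatment_id: str) -> Treatment:
        try:
            return self._treatments[treatment_id][-1]
        except KeyError:
            raise MissingKeyError(f"unknown treatment {treatment_id!r}") from None

    def get_piece(self, piece_id: str) -> PieceOfEvidence:
        try:
            return self._pieces[piece_id][-1]
        except KeyError:
            raise MissingKeyError(f"unknown piece {piece_id!r}") from None

    def piece_date(self, piece: PieceOfEvidence) -> datetime.date:
        """A piece is dated by its reference's publication date."""
        return self.get_reference(piece.ref_id).publication_date

    def study_type(self, piece: PieceOfEvidence) -> StudyType:
        return self.get_reference(piece.ref_id).study_type

    def total_row_count(self) -> int:
        """All rows ever written, across versions, plus audit entries."""
        n = sum(len(v) for v in self._references.values())
        n += sum(len(v) for v in self._treatments.values())
        n += sum(len(v) for v in self._pieces.values())
        return n + len(self.audit_log)

    # -- mutation ---------------------------------------------------------

    def _check_mutable(self) -> None:
        if self._frozen:
            raise FrozenStoreError("store is a frozen release snapshot")

    def add_record(self, record: Record) -> str:
        """Insert a new record; duplicate keys and dangling foreign keys are
        rejected and nothing is ever overwritten."""
        self._check_mutable()
        if isinstance(record, Reference):
            if record.ref_id in self._references:
                raise DuplicateKeyError(f"reference {record.ref_id!r} already exists")
            self._references[record.ref_id] = [record]
            return record.ref_id
        if isinstance(record, Treatment):
            if record.treatment_id in self._treatments:
                raise DuplicateKeyError(
                    f"treatment {record.treatment_id!r} already exists"
                )
            self._treatments[record.treatment_id] = [record]
            return record.treatment_id
        if isinstance(record, PieceOfEvidence):
            if record.piece_id in self._pieces:
                raise DuplicateKeyError(f"piece {record.piece_id!r} already exists")
            if record.ref_id not in self._references:
                raise MissingKeyError(
                    f"piece {record.piece_id!r} references missing ref_id "
                    f"{record.ref_id!r}"
                )
            if record.treatment_id not in self._treatments:
                raise MissingKeyError(
                    f"piece {record.piece_id!r} references missing treatment_id "
                    f"{record.treatment_id!r}"
                )
            self._pieces[record.piece_id] = [record]
            return record.piece_id
        raise TypeError(f"unsupported record type {type(record).__name__}")

    def update_record(self, record: Record, note: str) -> str:
        """Append a new version of an existing record (never-delete rule)."""
        self._check_mutable()
        if isinstance(record, Reference):
            table, key = self._references, record.ref_id
        elif isinstance(record, Treatment):
            table, key = self._treatments, record.treatment_id
        elif isinstance(record, PieceOfEvidence):
            table, key = self._pieces, record.piece_id
        else:
            raise TypeError(f"unsupported record type {type(record).__name__}")
        if key not in table:
            raise MissingKeyError(f"cannot update unknown record {key!r}")
        prev = table[key][-1]
        new = record.model_copy(
            update={
                "version": prev.version + 1,
                "supersedes": prev.version,
                "audit_note": note,
            }
        )
        table[key].append(new)
        return key

    def transition_status(
        self,
        piece_id: str,
        new_status: PieceStatus,
        *,
        cause_piece_id: Optional[str] = None,
        release_id: Optional[int] = None,
        timestamp: datetime.date,
        note: str = "",
    ) -> AuditEntry:
        """Move a piece along the status state machine.

        Appends one new piece version and exactly one audit entry; the only
        admissible edges are active -> disqualified_pending -> disqualified
        -> to_review -> active.
        """
        self._check_mutable()
        current = self.get_piece(piece_id)
        if (current.status, new_status) not in _ALLOWED_TRANSITIONS:
            raise InvalidTransitionError(
                f"piece {piece_id!r}: {current.status.value} -> {new_status.value} "
                "is not an admissible status edge"
            )
        updated = current.model_copy(update={"status": new_status})
        self.update_record(updated, note or f"status -> {new_status.value}")
        entry = AuditEntry(
            entry_id=len(self.audit_log) + 1,
            piece_id=piece_id,
            old_status=current.status,
            new_status=new_status,
            cause_piece_id=cause_piece_id,
            release_id=release_id,
            timestamp=timestamp,
        )
        self.audit_log.append(entry)
        return entry

    # -- querying ---------------------------------------------------------

    def query_pieces(self, query: Query) -> list[PieceOfEvidence]:
        """All current pieces satisfying every predicate, ordered by
        (date, piece_id)."""
        self._validate_query_fields(query)
        out = []
        for piece in self.pieces.values():
            if self._matches(piece, query):
                out.append(piece)
        out.sort(key=lambda p: (self.piece_date(p), p.piece_id))
        return out

    def _validate_query_fields(self, query: Query) -> None:
        valid = set(_PIECE_FIELDS)
        valid |= {f"reference.{f}" for f in _REFERENCE_FIELDS}
        valid |= {f"treatment.{f}" for f in _TREATMENT_FIELDS}
        # convenient bare aliases for joined columns
        valid |= set(_REFERENCE_FIELDS) | set(_TREATMENT_FIELDS)
        for field in query.where:
            if field not in valid:
                raise UnknownFieldError(
                    f"unknown query field {field!r}; valid fields: "
                    + ", ".join(sorted(valid))
                )

    def _resolve_field(self, piece: PieceOfEvidence, field: str):
        if field.startswith("reference."):
            return getattr(self.get_reference(piece.ref_id), field[10:])
        if field.startswith("treatment."):
            return getattr(self.get_treatment(piece.treatment_id), field[10:])
        if field in _PIECE_FIELDS:
            return getattr(piece, field)
        if field in _REFERENCE_FIELDS:
            return getattr(self.get_reference(piece.ref_id), field)
        return getattr(self.get_treatment(piece.treatment_id), field)

    @staticmethod
    def _values_equal(actual, wanted) -> bool:
        if isinstance(actual, enum.Enum):
            actual = actual.value
        if isinstance(wanted, enum.Enum):
            wanted = wanted.value
        if isinstance(actual, datetime.date) and isinstance(wanted, str):
            wanted = datetime.date.fromisoformat(wanted)
        if isinstance(actual, bool) and isinstance(wanted, str):
            wanted = wanted.lower() == "true"
        return actual == wanted

    def _matches(self, piece: PieceOfEvidence, query: Query) -> bool:
        for field, wanted in query.where.items():
            if not self._values_equal(self._resolve_field(piece, field), wanted):
                return False
        if query.tags and not query.tags <= piece.subgroup_tags:
            return False
        if query.date_from or query.date_to:
            d = self.piece_date(piece)
            if query.date_from and d < query.date_from:
                return False
            if query.date_to and d > query.date_to:
                return False
        return True

    # -- integrity --------------------------------------------------------

    def validate(self) -> None:
        """Full referential-integrity check over current rows."""
        for piece in self.pieces.values():
            if piece.ref_id not in self._references:
                raise MissingKeyError(
                    f"piece {piece.piece_id!r}: dangling ref_id {piece.ref_id!r}"
                )
            if piece.treatment_id not in self._treatments:
                raise MissingKeyError(
                    f"piece {piece.piece_id!r}: dangling treatment_id "
                    f"{piece.treatment_id!r}"
                )

    def content_hash(self) -> str:
        """Order-independent content hash over all canonicalized table rows."""
        row_hashes = sorted(
            hashlib.sha256(js.encode()).hexdigest()
            for js in self._iter_canonical_rows()
        )
        return hashlib.sha256("\n".join(row_hashes).encode()).hexdigest()

    def _iter_canonical_rows(self) -> Iterable[str]:
        for table, name in (
            (self._references, "references"),
            (self._treatments, "treatments"),
            (self._pieces, "pieces"),
        ):
            for key in sorted(table):
                for rec in table[key]:
                    yield json.dumps(
                        {"table": name, **_record_to_row(rec)}, sort_keys=True
                    )

    # -- persistence ------------------------------------------------------

    def save(self, directory: Union[str, Path], fmt: str = "csv") -> None:
        """Write one file per table plus the audit log (JSON-lines)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tables = {
            "references": (self._references, _REFERENCE_FIELDS),
            "treatments": (self._treatments, _TREATMENT_FIELDS),
            "pieces": (self._pieces, _PIECE_FIELDS),
        }
        for name, (table, fields) in tables.items():
            rows = [
                _record_to_row(rec)
                for key in sorted(table)
                for rec in table[key]
            ]
            if fmt == "csv":
                with open(directory / f"{name}.csv", "w", newline="") as fh:
                    writer = csv.DictWriter(fh, fieldnames=fields)
                    writer.writeheader()
                    writer.writerows(rows)
            elif fmt == "jsonl":
                with open(directory / f"{name}.jsonl", "w") as fh:
                    for row in rows:
                        fh.write(json.dumps(row, sort_keys=True) + "\n")
            else:
                raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'jsonl')")
        with open(directory / "audit.jsonl", "w") as fh:
            for entry in self.audit_log:
                fh.write(entry.model_dump_json() + "\n")
        with open(directory / "releases.jsonl", "w") as fh:
            for release in self.releases:
                fh.write(
                    json.dumps(
                        {
                            "release_id": release.release_id,
                            "created_date": release.created_date.isoformat(),
                            "snapshot_hash": release.snapshot_hash,
                            "applied_entry_ids": [
                                e.entry_id for e in release.applied_transitions
                            ],
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "EvidenceStore":
        """Reconstruct a store saved with :meth:`save` (CSV or JSON-lines)."""
        directory = Path(directory)
        store = cls()
        loaders = {
            "references": (store._references, _row_to_reference, "ref_id"),
            "treatments": (store._treatments, _row_to_treatment, "treatment_id"),
            "pieces": (store._pieces, _row_to_piece, "piece_id"),
        }
        for name, (table, parse, key_field) in loaders.items():
            csv_path = directory / f"{name}.csv"
            jsonl_path = directory / f"{name}.jsonl"
            if csv_path.exists():
                with open(csv_path, newline="") as fh:
                    rows = list(csv.DictReader(fh))
            elif jsonl_path.exists():
                with open(jsonl_path) as fh:
                    rows = [json.loads(line) for line in fh if line.strip()]
            else:
                raise MissingKeyError(f"no {name} table found in {directory}")
            for row in rows:
                rec = parse(row)
                table.setdefault(row[key_field], []).append(rec)
        for versions in list(store._references.values()) + list(
            store._treatments.values()
        ) + list(store._pieces.values()):
            versions.sort(key=lambda r: r.version)
        audit_path = directory / "audit.jsonl"
        if audit_path.exists():
            with open(audit_path) as fh:
                store.audit_log = [
                    AuditEntry.model_validate_json(line)
                    for line in fh
                    if line.strip()
                ]
        releases_path = directory / "releases.jsonl"
        if releases_path.exists():
            from .release import Release  # deferred: release builds on store

            by_id = {e.entry_id: e for e in store.audit_log}
            with open(releases_path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    meta = json.loads(line)
                    store.releases.append(
                        Release(
                            release_id=meta["release_id"],
                            created_date=datetime.date.fromisoformat(
                                meta["created_date"]
                            ),
                            snapshot_hash=meta["snapshot_hash"],
                            applied_transitions=[
                                by_id[i]
                                for i in meta["applied_entry_ids"]
                                if i in by_id
                            ],
                            snapshot=None,  # frozen copies are not serialized
                        )
                    )
        store.validate()
        return store


# -- row (de)serialization -----------------------------------------------


def _scalar(value):
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, datetime.date):
        return value.isoformat()
    return value


def _record_to_row(rec: Record) -> dict:
    row = {}
    for field in type(rec).model_fields:
        value = getattr(rec, field)
        if field == "subgroup_tags":
            row[field] = "|".join(sorted(value))
        elif field in ("component_ids", "eligibility"):
            row[field] = "|".join(value)
        elif field == "flags":
            row[field] = json.dumps(
                {k: v.value for k, v in sorted(value.items())}, sort_keys=True
            )
        elif field == "patient_share_history":
            row[field] = json.dumps(
                [
                    {"date": e.date.isoformat(), "share": e.share.value}
                    for e in value
                ]
            )
        else:
            row[field] = _scalar(value)
    return row


def _opt(row: dict, field: str):
    v = row.get(field, "")
    return None if v in ("", None) else v


def _split(v) -> list[str]:
    if not v:
        return []
    return v.split("|") if isinstance(v, str) else list(v)


def _row_to_reference(row: dict) -> Reference:
    return Reference(
        ref_id=row["ref_id"],
        publication_date=row["publication_date"],
        study_type=row["study_type"],
        description=row.get("description") or "",
        version=int(row.get("version") or 1),
        supersedes=_opt(row, "supersedes"),
        audit_note=_opt(row, "audit_note"),
    )


def _row_to_treatment(row: dict) -> Treatment:
    psh = row.get("patient_share_history") or "[]"
    entries = json.loads(psh) if isinstance(psh, str) else psh
    return Treatment(
        treatment_id=row["treatment_id"],
        name=row.get("name") or "",
        modality=row.get("modality") or "other",
        novelty_class=row.get("novelty_class") or "new",
        component_ids=_split(row.get("component_ids")),
        drug_class=_opt(row, "drug_class"),
        eligibility=_split(row.get("eligibility")),
        molecular_eligibility=_parse_bool(row.get("molecular_eligibility")),
        patient_share_history=[ShareEntry(**e) for e in entries],
        version=int(row.get("version") or 1),
        supersedes=_opt(row, "supersedes"),
        audit_note=_opt(row, "audit_note"),
    )


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).lower() == "true"


def _row_to_piece(row: dict) -> PieceOfEvidence:
    flags_raw = row.get("flags") or "{}"
    flags = json.loads(flags_raw) if isinstance(flags_raw, str) else flags_raw
    effect_size = _opt(row, "effect_size")
    weight_override = _opt(row, "weight_override")
    return PieceOfEvidence(
        piece_id=row["piece_id"],
        ref_id=row["ref_id"],
        treatment_id=row["treatment_id"],
        disease_state=row["disease_state"],
        therapeutic_goal=row["therapeutic_goal"],
        outcome=row.get("outcome") or "overall_survival",
        comparator=row.get("comparator") or "",
        analysis_goal=row.get("analysis_goal") or "superiority",
        timepoint_label=row.get("timepoint_label") or "initial",
        subgroup_tags=frozenset(_split(row.get("subgroup_tags"))),
        significant_after_correction=_parse_bool(
            row.get("significant_after_correction")
        ),
        effect_size=float(effect_size) if effect_size is not None else None,
        effect_type=_opt(row, "effect_type"),
        group_evidence=_parse_bool(row.get("group_evidence")),
        group_size=int(row.get("group_size") or 1),
        failed_due_to_toxicity=_parse_bool(row.get("failed_due_to_toxicity")),
        status=row.get("status") or "active",
        flags={k: FlagValue(v) for k, v in flags.items()},
        review_conclusion=_opt(row, "review_conclusion"),
        weight_override=(
            float(weight_override) if weight_override is not None else None
        ),
        version=int(row.get("version") or 1),
        supersedes=_opt(row, "supersedes"),
        audit_note=_opt(row, "audit_note"),
    )
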