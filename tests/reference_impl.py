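"""Independent brute-force reference for E-Score series.

Deliberately naive and structurally different from the engine: for every
year it rescans all pieces, re-derives qualification, weights and the
dated value matrix inline from raw model fields, and sums.  Valid for
count_threshold 0 (the default study condition).
"""

from __future__ import annotations


def _qualifies(piece, cfg) -> bool:
    if piece.outcome not in cfg.outcomes_in_scope:
        return False
    if cfg.require_multiple_testing and not piece.significant_after_correction:
        return False
    if piece.failed_due_to_toxicity:
        return False
    if piece.status.value not in ("active", "disqualified_pending"):
        return False
    if any(v.value == "todo" for v in piece.flags.values()):
        return False
    return True


def _evidence_weight(piece, reference, hierarchy) -> float:
    if piece.weight_override is not None:
        base = piece.weight_override
    else:
        base = hierarchy.numeric_weight[reference.study_type]
    if piece.group_evidence:
        base = base / piece.group_size
    return base


def _value_weight(square, date, matrices) -> float:
    preceding = [m for m in matrices if m.effective_date <= date]
    if preceding:
        chosen = max(preceding, key=lambda m: m.effective_date)
    else:
        chosen = min(matrices, key=lambda m: m.effective_date)
    return chosen.weights[square]


def _custom_multiplier(piece, treatment, custom) -> float:
    m = custom.modality_multiplier.get(treatment.modality, 1.0)
    if custom.effect_size_rule == "linear_in_benefit" and piece.effect_size is not None:
        if piece.effect_type is not None and piece.effect_type.value == "hazard_ratio":
            m *= 1.0 + custom.effect_slope * max(0.0, 1.0 - piece.effect_size)
        elif (
            piece.effect_type is not None
            and piece.effect_type.value == "median_survival_difference_months"
        ):
            m *= 1.0 + custom.effect_slope * max(0.0, piece.effect_size) / 12.0
    m *= custom.per_piece_override.get(piece.piece_id, 1.0)
    return m


def brute_force_series(
    pieces, store, hierarchy, matrices, custom, layout, cfg, end_year
) -> dict[int, float]:
    """year -> cumulative score, rescanning every piece for every year."""
    assert cfg.count_threshold == 0, "reference only covers threshold 0"
    pieces = list(pieces)
    if pieces:
        start = min(store.references[p.ref_id].publication_date.year for p in pieces) - 1
    else:
        start = end_year
    out = {}
    for year in range(start, end_year + 1):
        total = 0.0
        for piece in pieces:
            reference = store.references[piece.ref_id]
            if reference.publication_date.year > year:
                continue
            if not _qualifies(piece, cfg):
                continue
            square = layout.mapping[piece.disease_state][piece.therapeutic_goal]
            total += (
                _evidence_weight(piece, reference, hierarchy)
                * _value_weight(square, reference.publication_date, matrices)
                * _custom_multiplier(
                    piece, store.treatments[piece.treatment_id], custom
                )
            )
        out[year] = total
    return out
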