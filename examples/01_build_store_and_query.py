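"""Build an evidence store, disaggregate one study, query by tag.

A two-arm trial with initial and long-term follow-up readouts yields four
pieces of evidence; tag queries then retrieve targeted subsets.
"""

import datetime

from cii import (
    Arm,
    DiseaseState,
    EvidenceStore,
    Query,
    Reference,
    ResultEntry,
    StudySpec,
    StudyType,
    TherapeuticGoal,
    Treatment,
    disaggregate,
)

store = EvidenceStore()
store.add_record(
    Treatment(treatment_id="bev", name="anti-VEGF antibody", modality="immunotherapy")
)
store.add_record(
    Treatment(treatment_id="chemo-x", name="doublet chemo", modality="chemotherapy")
)
store.add_record(
    Reference(
        ref_id="pmid-1001",
        publication_date=datetime.date(2006, 4, 1),
        study_type=StudyType.rct,
    )
)

study = StudySpec(
    ref_id="pmid-1001",
    arms=[
        Arm(treatment_id="bev", comparator="chemo alone"),
        Arm(treatment_id="chemo-x", comparator="older doublet"),
    ],
    timepoints=["initial", "long-term follow-up"],
    disease_state=DiseaseState.advanced,
    therapeutic_goal=TherapeuticGoal.stop_progression,
    results={
        "0.0.0.0": ResultEntry(significant_after_correction=True, effect_size=0.79,
                               effect_type="hazard_ratio"),
        "0.1.0.0": ResultEntry(significant_after_correction=True),
        "1.0.0.0": ResultEntry(significant_after_correction=False),
        "1.1.0.0": "not_reported",
    },
)
pieces = disaggregate(study, store)
for piece in pieces:
    piece = piece.model_copy(
        update={"subgroup_tags": frozenset({"colon", "anti-angiogenesis"})}
        if piece.treatment_id == "bev"
        else {}
    )
    store.add_record(piece)

print(f"disaggregated into {len(pieces)} pieces:")
for p in store.query_pieces(Query()):
    print(f"  {p.piece_id}  arm={p.treatment_id:8s} timepoint={p.timepoint_label}")

hits = store.query_pieces(Query(tags={"anti-angiogenesis"}))
print(f"tag query 'anti-angiogenesis' -> {len(hits)} pieces (the bev arm only)")
# One study, one outcome, but several analysable units: each (arm, timepoint)
# combination is its own dated, queryable piece of evidence.
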