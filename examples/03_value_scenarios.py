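"""Stakeholder values change the picture: curative vs uniform weighting.

Two treatments with equal amounts of evidence: one cures (square A), one
stabilises advanced disease (square D).  A stakeholder who doubles the
curative squares {A, C, F, J} sees the curative treatment pull ahead
while the stabilising treatment's series is untouched.
"""

from cii import Query, compute_escore_series, scenario

fx = scenario("curative_vs_uniform")


def final(treatment_id, matrices):
    return compute_escore_series(
        Query(where={"treatment_id": treatment_id}), fx.store, fx.hierarchy,
        matrices, fx.custom, fx.layout, fx.scoring, end_year=2010,
    ).final()


for name in ("uniform", "curative"):
    mats = fx.matrices[name]
    print(
        f"{name:8s} weights: curative treatment E-Score "
        f"{final('TCURE', mats):.1f}, stabilising treatment "
        f"{final('TSTOP', mats):.1f}"
    )
# Same evidence base, different values, different portrait of progress:
# that is what the value matrix is for.
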