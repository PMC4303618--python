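"""Review override, deferred disqualification, audited release.

Three positive trials accumulate; a later meta-analysis finds the
evidence insufficient.  The override never moves scores in real time —
the drop appears only in the next data release, the old trials stay in
the database, and the audit trail records every transition.
"""

from cii import (
    Query,
    apply_override,
    compute_escore_series,
    create_release,
    reversal_stats,
    scenario,
)

fx = scenario("reversal")
args = (fx.hierarchy, fx.matrices["uniform"], fx.custom, fx.layout, fx.scoring, 2010)

before = compute_escore_series(Query(), fx.store, *args)
affected = apply_override(fx.store.get_piece("REV"), fx.store, fx.layout, fx.hierarchy)
during = compute_escore_series(Query(), fx.store, *args)
print(f"override marked {len(affected)} pieces disqualified_pending: {affected}")
print(f"series before release unchanged: {during.scores == before.scores}")

release = create_release(fx.store)
after = compute_escore_series(Query(), fx.store, *args)
print(f"release {release.release_id} applied {len(release.applied_transitions)} transitions")
print(f"final E-Score before: {before.final():.1f}, after release: {after.final():.1f}")

stats = reversal_stats(fx.store, fx.layout)
print("reversal totals:", stats["totals"])
print(f"audit entries: {len(fx.store.audit_log)} (append-only, nothing deleted)")
# The whole curve is lower in the new release, but within any release the
# slope is never negative, and every disqualified record remains retrievable.
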