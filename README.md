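# cii — continuous innovation indicators

`cii` is an engine for tracking progress in cancer treatment (or any
therapeutic area) as the *accumulation of evidence*, not as a single
outcome statistic. It implements value-weighted cumulative Evidence
Scores (E-Scores) over a relational store of disaggregated clinical
evidence records, with evidence-hierarchy weighting, systematic-review
override semantics, immutable audited data releases, and declarative
Value Matrix visualisation output.

It is written for analysts and health-policy researchers who curate
bodies of clinical literature and want reproducible, value-explicit
progress trackers — not survival estimates and not clinical guidance.

## The model

The unit of analysis is the **piece of evidence**: one pre-planned
analysis result, carrying exactly one disease state, one therapeutic
goal, one treatment and one outcome, dated by its literature reference.
A publication reporting several arms, timepoints, subgroups or analysis
goals is *disaggregated* into one piece per combination.

The cumulative score for a query (a disease site, a drug class, a
biomarker tag, …) in year *y* is

```
E(y) = Σ over qualifying pieces p with year(p) ≤ y of
           w_evidence(p) · w_value(p) · w_custom(p)
```

where

- **w_evidence** is the study-type weight from the evidence hierarchy
  (default: RCT 1.0; meta-analysis, systematic review, observational
  0.5; retrospective, historical 0.25), divided by *k* for group
  evidence attributable only to a class of *k* treatments. Meta-analyses
  and systematic reviews sit at the top *functional* tier — they alone
  can override earlier evidence — but deliberately not at the top
  *numerical* weight, so controversy-rich areas are not inflated by
  pooled re-analyses.
- **w_value** is the stakeholder weight of the piece's Value Matrix
  square — the cell determined by its (disease state, therapeutic goal)
  pair, e.g. square A = cure advanced disease, D = stop progression of
  advanced disease, J = keep resected patients disease-free. Matrices
  are dated; the matrix in force at the piece's publication date
  applies ("closest preceding matrix").
- **w_custom** folds in optional modality multipliers, effect-size
  adjustments and per-piece overrides (default: constant 1).

A piece *qualifies* only if its outcome is in scope (overall survival in
the first release), it is significant after multiple-testing correction,
it did not fail on toxicity, its status counts, and no quality-control
flag is still to-do. When a top-tier review concludes the evidence for a
treatment in a context is insufficient, all prior pieces in that context
are *disregarded, never deleted*: they are flagged and take effect as
disqualified only in the next immutable data release, so within a
release the score slope is never negative. Every status change appends
exactly one audit entry.

## Worked example

```python
from cii import Query, compute_escore_series, scenario

fx = scenario("stepwise_accumulation")
series = compute_escore_series(
    Query(), fx.store, fx.hierarchy, fx.matrices["uniform"],
    fx.custom, fx.layout, fx.scoring, end_year=2014,
)
print(series.scores)
```

prints

```
{2000: 0.0, 2001: 1.0, 2002: 1.0, 2003: 2.0, 2004: 2.0, 2005: 3.0,
 2006: 3.0, 2007: 3.0, 2008: 4.0, 2009: 4.0, 2010: 5.0, 2011: 5.0,
 2012: 5.0, 2013: 6.0, 2014: 6.0}
```

— six significant RCTs published in six different years, each worth
evidence weight 1.0 under uniform value weights, so the cumulative
E-Score climbs one unit per evidence year: progress as a staircase of
stepwise innovation, not a single leap. The `examples/` directory walks
through the other capabilities: store building and tag queries,
value-scenario sensitivity, review overrides with audited releases, and
the synthetic-corpus pipeline.

There is also a thin CLI:

```
cii simulate --seed 7 --out tables/
cii score --tables tables/ --end-year 2016 --out series.csv
cii run --tables tables/ --out artifacts/
```

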