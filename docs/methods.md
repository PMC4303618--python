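# Methods

## Scope and purpose

`cii` measures *evidence accumulation*, not treatment effect. Its
E-Scores are relative trackers for comparing progress over time and
across areas under explicit stakeholder values; they are not absolute
quantities translatable into survival estimates, and the package offers
no clinical guidance.

## Data model

Three relational tables — references, treatments, pieces of evidence —
are linked by opaque string keys (in real use, reference keys are PubMed
identifiers; ingestion of live literature feeds is out of scope and all
test inputs come from the synthetic generator). A piece's date is always
its reference's publication date (ISO 8601). Subgroup tags are
exact-string and case-sensitive after whitespace normalization; a
controlled vocabulary ships in `cii/data/tags.txt` to prevent silent
drift. Disease states and therapeutic goals are fixed four-value enums,
configurable through the layout file.

Nothing is ever overwritten or deleted. Updates append a new version row
with a `supersedes` pointer and an audit note; status changes append a
new version *and* exactly one audit entry. Row counts are therefore
non-decreasing across any operation sequence, and every historical row
remains retrievable — the property that makes reversal statistics and
full accountability possible. CSV (RFC-4180 quoting) and JSON-lines are
the interchange formats, one file per table; an embedded database backend
could be slotted behind the same surface but flat files keep the store
transparent and diffable.

## Disaggregation

A study description lists arms (non-control arms only — the comparator
is text, because the comparison rather than the arm is the unit),
timepoints, subgroups (the empty tag-set is "entire population"),
analysis goals, and one result cell per combination. Disaggregation
emits |arms|×|timepoints|×|subgroups|×|goals| pieces minus cells marked
`not_reported`; a missing cell is an error naming the combination, which
catches curation gaps early. Piece ids are
`<ref_id>:<arm>.<tp>.<sg>.<goal>` — deterministic, idempotent and
human-auditable. Only pre-planned analyses should be entered; the
curator asserts this.

## Qualification and weighting

Defaults (editable in `cii/data/hierarchy.yaml` / `scoring.yaml`):

| parameter | default | why |
|---|---|---|
| RCT weight | 1.0 | individual trials carry the top numerical weight |
| meta-analysis / systematic review / observational | 0.5 | pooled reviews below RCTs numerically (anti-inflation), top tier functionally |
| retrospective / historical | 0.25 | weakest designs |
| group fraction | 1/k | a class-level result is split among its k members |
| outcomes in scope | overall survival | well-defined, broadly measured first outcome |
| require multiple-testing correction | true | uncorrected significance never counts |
| count_threshold | 0.0 | first qualifying piece counts immediately |
| milestone levels | [1.0, 3.0] | three evidence-strength shade tiers |

Only the *ordering* of the numerical weights is fixed by the method
(RCT strictly highest, meta-analysis strictly below); the exact values
are configuration defaults. Per-piece weight overrides are supported for
users who grade individual studies (e.g. with a GRADE-style assessment);
no assignment procedure is built in. Non-inferiority pieces qualify on
the same terms as superiority pieces; custom weights can down-weight
them if a stakeholder wishes.

A deliberate subtlety: a piece flagged `disqualified_pending` by a
review override **still qualifies** until the next release. The method's
defining constraint is that overrides never decrease published scores in
real time — the whole curve drops only in the following data release.
Making pending pieces non-qualifying would violate that constraint, so
the status check excludes only `disqualified` and `to_review`.

## Value Matrix

Ten squares A–J over the 16-cell (disease state × goal) product. Four
cells are anchored by the method's semantics (A: cure advanced, D: stop
progression advanced, H: stop progression regional, J: keep resected
disease-free) and locked by a validation rule; the curative column
{A, C, F, J} is the cure goal across the four states. The remaining
cells are provisional and editable in `cii/data/layout.yaml`. Square
labels confer no value judgment and the engine never orders squares by
label. Each piece maps to exactly one square; a treatment straddling
squares does so through multiple pieces.

Several dated matrices may be supplied; lookup is piecewise-constant and
right-continuous with breakpoints exactly at the effective dates. Pieces
dated before the earliest matrix use the earliest matrix, so a matrix
always applies. A piece's value weight uses the matrix in force at the
piece's *publication date*, not the evaluation year — the dating rule is
applied at the scoring of each piece. Treatment goal paths (multimodal
synergies) are annotation/visualization only; they do not alter scores,
though the custom-weight surface leaves room for a future path
multiplier.

## Scoring algorithm

Contributions are summed in deterministic (date, piece_id) order at
calendar-year granularity. With a positive `count_threshold`,
contributions for a (treatment, square) accrue in a pending pool until
the pool's cumulative *evidence* weight reaches the threshold; the whole
pool then counts in the crossing year and later pieces count
immediately. The default threshold 0 makes this a no-op. The series axis
starts one year before the earliest matched piece (a visible zero
baseline); an empty match yields an all-zero series. Stratified scoring
requires the partition tags to cover the matched pieces disjointly —
both overlap and non-coverage are rejected, because pointwise
additivity of strata is only defined for a true partition.

Every series carries a 16-hex config fingerprint (SHA-256 over the
canonicalized hierarchy, matrices, custom weights, layout and scoring
config) so that any artifact can be traced to the exact weight inputs
that produced it.

## Releases, overrides, audit

Only a top-functional-tier review (meta-analysis or systematic review)
with an `insufficient_support` conclusion may override. Its context is
(treatment, square, outcome); a tagged review restricts the match to
pieces carrying its tags. Matching active pieces dated on or before the
review become `disqualified_pending`. `create_release` flips pending to
disqualified, stamps the audit entries with the release id,
content-hashes the tables (order-independent SHA-256 over canonical
rows) and keeps a frozen deep-copy snapshot for scoring against
published releases. The status machine admits only
active → disqualified_pending → disqualified → to_review → active.

New qualifying evidence in an overridden context only *flags* the
disqualified pieces `to_review`; re-activation is an explicit curator
action, reflecting that re-assessment is a human step. Overrides do not
block future pieces from accruing. Release dates default to the latest
reference date in the store so that artifacts are deterministic
functions of the data.

## Synthetic corpora

The generator emulates the structural features the engine must handle:
mixed study types over a year range, Bernoulli significance and toxicity
failures, group evidence with 1/k splits, subgroup tags from a
vocabulary, a recurring "home context" per treatment (so overrides have
targets), and occasional later insufficient-support reviews. Default
conditions: 20 treatments, Poisson-mean 8 pieces each over 1995–2015,
60% significant, 5% toxicity failures, 10% group evidence, RCT-heavy
study mix, 10% override probability per treatment — a mid-sized curated
corpus of roughly 150–200 pieces. One RNG stream per table is spawned
from the master seed, so adding a table never perturbs the others and
identical (params, seed) yield byte-identical table files.

What the generator does **not** emulate: real literature growth curves,
realistic effect-size distributions, publication bias, correlated
subgroup structures, or curation noise. Passing tests therefore
demonstrate the engine's algebraic and procedural correctness on
structurally realistic inputs, not calibration against any real corpus.

Four deterministic scenario fixtures (≤ 50 pieces, golden-hash
stability-tested) encode the canonical qualitative behaviours: stepwise
accumulation, reversal by review, a targeted treatment broadening its
patient share, and curative-vs-uniform value sensitivity.

## Numerical choices

Scores are plain float64 sums in a fixed order; test comparisons use
1e-9 absolute tolerance (observed engine-vs-reference discrepancies are
at the 1e-15 level). Milestone tiers are inclusive at the boundary
(cumulative weight 1.0 reaches level 1.0). Matrix selection at an
effective date chooses the newly effective matrix. Ties in piece
ordering are broken by piece_id.

## Verification sizes

The property suite checks engine-vs-brute-force equivalence on 100
seeded corpora of at most 500 pieces each, monotonicity over randomized
corpora and configs, release semantics on the reversal fixture,
disaggregation counts on 50 randomized study descriptions, and full
determinism/round-trip checks; the acceptance script re-measures the
same quantities on 30 corpora per run. These sizes keep a full run in
seconds while exercising every code path; all of them scale linearly if
larger sweeps are wanted.

## Known limitations

- One square per piece; multi-square treatments arise only via multiple
  pieces.
- Effect-size custom weighting implements a single linear-in-benefit
  rule; richer elasticities must be supplied as per-piece overrides.
- The flag vocabulary is illustrative (`multiple_testing_checked`,
  `duplicate_review_done`, …); the engine only distinguishes to-do from
  resolved.
- Releases persist as metadata (id, date, hash, transitions) in the
  table directory; frozen snapshots live in memory and are reconstructed
  by re-scoring against the audit history rather than serialized.
- No alerting: new contradicting evidence surfaces only as `to_review`
  flags and reversal statistics.
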