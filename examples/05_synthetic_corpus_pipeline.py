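"""Seeded synthetic corpus through the full pipeline.

Generates a reproducible corpus, runs capture -> review -> scoring ->
value weighting, and prints the artifacts: an E-Score series CSV,
declarative Value Matrix plot data, and reversal statistics, all stamped
with a config fingerprint for reproducibility audits.
"""

import tempfile
from pathlib import Path

from cii import (
    CorpusParams,
    CustomWeights,
    PipelineConfig,
    ScoringConfig,
    default_hierarchy,
    default_layout,
    generate_corpus,
    run_pipeline,
)

corpus = generate_corpus(CorpusParams(n_treatments=10, seed=7))
print(
    f"generated {len(corpus.store.pieces)} pieces over "
    f"{len(corpus.store.treatments)} treatments "
    f"({len(corpus.override_review_ids)} pending override reviews)"
)

out = Path(tempfile.mkdtemp()) / "artifacts"
result = run_pipeline(
    PipelineConfig(
        store=corpus.store,
        hierarchy=default_hierarchy(),
        layout=default_layout(),
        matrices=corpus.matrices,
        custom=CustomWeights(),
        scoring=ScoringConfig(),
    ),
    out,
)
print(f"config fingerprint: {result['fingerprint']}")
print(f"final E-Score: {result['series'].final():.2f}")
print(f"{len(result['circles'])} circles on the value matrix")
for path in result["artifacts"]:
    print(" ", path)
# Re-running with the same seed and configs reproduces every artifact
# byte-for-byte; changing any weight changes the fingerprint.
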