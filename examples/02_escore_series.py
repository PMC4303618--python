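"""Cumulative E-Scores: stepwise evidence accumulation as a staircase.

Six significant trials in six different years, uniform value weights:
each trial adds its evidence weight (1.0 for an RCT) in its publication
year, so the cumulative series climbs one unit per evidence year.
"""

from cii import Query, compute_escore_series, scenario

fx = scenario("stepwise_accumulation")
series = compute_escore_series(
    Query(), fx.store, fx.hierarchy, fx.matrices["uniform"], fx.custom,
    fx.layout, fx.scoring, end_year=2014,
)

print("year  cumulative E-Score")
for year, score in series.scores.items():
    bar = "#" * int(score)
    print(f"{year}  {score:5.1f}  {bar}")
print(f"\nfinal E-Score: {series.final():.1f} from {series.n_pieces[2014]} pieces")
# The staircase shape is the point: progress is stepwise accumulation of
# qualifying evidence, not a single great leap.
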