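# Default evidence hierarchy.
# Numerical weights drive scoring: individual randomised trials carry the
# highest numerical weight; pooled reviews are weighted lower so that
# controversy-rich areas (many re-analyses of the same trials) are not
# inflated.  Functional tiers govern override rights: meta-analyses and
# systematic reviews share the top tier and may disqualify prior evidence.
numeric_weight:
  rct: 1.0
  meta_analysis: 0.5
  systematic_review: 0.5
  observational: 0.5
  retrospective: 0.25
  historical: 0.25
functional_tier:
  meta_analysis: 2
  systematic_review: 2
  rct: 1
  observational: 0
  retrospective: 0
  historical: 0
group_fraction_rule: one_over_k
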