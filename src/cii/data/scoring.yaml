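# Default scoring configuration.
# count_threshold 0: the first qualifying piece counts immediately.
# milestone_levels define three evidence-strength shade tiers (0/1/2).
outcomes_in_scope:
  - overall_survival
require_multiple_testing: true
count_threshold: 0.0
milestone_levels: [1.0, 3.0]
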