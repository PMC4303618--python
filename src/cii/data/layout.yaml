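# Default Value Matrix layout: ten squares A-J over the product of four
# disease states and four therapeutic goals.  The cells A (cure advanced
# disease), D (stop progression of advanced disease), H (stop progression
# of regional disease) and J (keep resected patients disease-free) are
# anchored and locked by validation; the curative column is {A, C, F, J}.
# All other cells are PROVISIONAL and may be edited.  Square labels are
# for classification only and confer no value judgment.
squares: [A, B, C, D, E, F, G, H, I, J]
mapping:
  advanced:
    become_disease_free: A
    stop_progression: D
    shrink_or_slow: B
    symptom_relief: G
  regional:
    become_disease_free: C
    stop_progression: H
    shrink_or_slow: E
    symptom_relief: G
  localized:
    become_disease_free: F
    stop_progression: I
    shrink_or_slow: I
    symptom_relief: I
  resected:
    become_disease_free: J
    stop_progression: J
    shrink_or_slow: J
    symptom_relief: J
curative_set: [A, C, F, J]
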