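# Controlled subgroup-tag vocabulary, one tag per line.
# Tag matching is exact-string and case-sensitive after whitespace
# normalization; extend this list rather than inventing variants.
breast
colon
endometrium
kidney
liver
lung
pancreas
prostate
melanoma
stomach
rectum
testes
her2-positive
egfr-mutant
kras-wildtype
anti-angiogenesis
postmenopausal
elderly
early-onset
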