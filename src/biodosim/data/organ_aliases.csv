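# Mapping from biodistribution organ labels to phantom organ names.
# Matching is case-insensitive and ignores surrounding whitespace and
# trailing periods; extend with --aliases for study-specific labels.
alias,organ
s.i.,small intestine
si,small intestine
small int,small intestine
l.i.,large intestine
li,large intestine
large int,large intestine
intestine,small intestine
kidney,kidneys
lung,lungs
femur,bone
bone marrow,bone
whole body,whole body
total body,whole body
wb,whole body
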