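# BLAST-style annotators: taxon name plus an E-value (lower is better)
name: name_evalue
read_id_col: 0
label_col: 1
score_col: 2
label_kind: name
score_direction: lower_better
ambiguity_marker: null
unresolved: fp
has_header: true
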