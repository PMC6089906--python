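# similarity classifiers that emit AMBIGUOUS(a;b;...) multi-taxon calls;
# members are collapsed to their lowest common ancestor, the read keeps its
# own similarity score
name: ambiguous_list
read_id_col: 0
label_col: 1
score_col: 2
label_kind: name
score_direction: higher_better
ambiguity_marker: AMBIGUOUS
ambiguity_separator: ";"
has_header: true
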