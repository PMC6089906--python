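# k-mer classifiers: integer taxid plus a confidence in [0,1], higher better
name: taxid_confidence
read_id_col: 0
label_col: 1
score_col: 2
label_kind: taxid
score_direction: higher_better
ambiguity_marker: null
has_header: true
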