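# every real read annotated correctly to full depth; shuffled reads untouched
p_correct:
  subspecies: 1.0
p_classify_shuffled: 0.0
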