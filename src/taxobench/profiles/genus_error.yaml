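# 90% correct to full depth, 5% swapped to a sibling genus, 5% unclassified;
# 1% of shuffled reads spuriously classified
p_correct:
  subspecies: 0.90
p_misclassify:
  genus: 0.05
p_classify_shuffled: 0.01
correct_score: [0.7, 1.0]
error_score: [0.1, 0.9]
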