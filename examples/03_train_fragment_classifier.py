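"""Train the stage-1 fragment classifier on a synthetic fragment library.

Ten fragment classes with a strong per-position consensus signal
(motif_strength 0.9) are generated, featurized, and classified by the
multimodal DBN-pretrained network at reduced layer widths.  A label-shuffled
control shows the same protocol finds nothing when there is nothing to find.
"""

from deepfragk.benchmarks import stage1_recovery

result = stage1_recovery(seed=0, n_shuffles=2)

print(f"held-out accuracy : {result['accuracy']:.3f} "
      f"(n={result['n_test']}, {result['epochs']} epochs)")
print(f"shuffled control  : {result['shuffled_accuracy']:.3f} "
      f"(chance = 0.100 for 10 classes)")
# accuracy near 1.0 means the three feature groups carry the class signal
# and the classifier recovers it; the control near 0.1 confirms the
# pipeline does not manufacture accuracy from structureless labels.
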