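"""Featurize one protein fragment and inspect its ten feature blocks.

A fragment (4-20 residues) is described by 1759 values in three groups:
sequence composition (77), physicochemical properties (82) and
PSSM-derived evolutionary information (1600).
"""

import numpy as np

from deepfragk import AminoAcidSequence, featurize_window, segment_sequence
from deepfragk.synthetic_data import synth_pssm

seq = AminoAcidSequence(id="demo", residues="MKVLAWDESTGH")
profile = synth_pssm(seq, noise=1.0, seed=0)   # stands in for a PSI-BLAST profile

window = segment_sequence(seq, profile, min_len=12, max_len=12)[0]
features = featurize_window(window)

print(f"fragment {window.sequence.id}: {window.sequence.residues}")
for block in features.blocks:
    head = np.array2string(block.values[:4], precision=3)
    print(f"  {block.name:>22s}  dim={block.dim:<4d} head={head}")
vec = features.concatenated()
print(f"total feature vector: {vec.shape[0]} values "
      f"(groups: {features.group_spans})")
# group frequencies are a distribution over the 10 side-chain classes;
# the evolutionary blocks summarize the 20x20 residue-pair structure of the PSSM
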