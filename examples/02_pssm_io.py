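"""Write and read a position-specific scoring matrix in PSI-BLAST ASCII form.

Synthetic profiles are BLOSUM62 rows plus rounded Gaussian noise, so they
use integer scores exactly like real `psiblast -out_ascii_pssm` output and
round-trip losslessly through the parser.
"""

import tempfile
from pathlib import Path

import numpy as np

from deepfragk import AminoAcidSequence, read_pssm_ascii, write_pssm_ascii
from deepfragk.synthetic_data import synth_pssm

seq = AminoAcidSequence(id="demo", residues="ACDEFGHIKL")
profile = synth_pssm(seq, noise=2.0, seed=42)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.pssm"
    write_pssm_ascii(profile, path)
    print(f"wrote {path.name}; first data line:")
    print("  " + path.read_text().splitlines()[3])
    back = read_pssm_ascii(path, seq_id="demo")

print(f"round trip exact: {np.array_equal(back.scores, profile.scores)}")
print(f"profile shape: {back.scores.shape} (one row per residue, "
      "20 log-odds columns in fixed order A R N D C Q E G H I L K M F P S T W Y V)")
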