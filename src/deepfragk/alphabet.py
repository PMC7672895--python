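"""Residue alphabet and the fixed PSSM column order.

Every matrix in the package uses one declared residue column order — the
PSI-BLAST header order ``A R N D C Q E G H I L K M F P S T W Y V`` — so
profiles read from differently-ordered files are re-mapped on input.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard residues, alphabetical; used for sequence sanitization.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed internal column order for all PSSM-shaped matrices (PSI-BLAST order).
PSSM_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

AA_SET = frozenset(STANDARD_AA)

#: residue letter -> column index in PSSM_COLUMN_ORDER
AA_TO_COL = {aa: i for i, aa in enumerate(PSSM_COLUMN_ORDER)}

_CODE_LUT = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_TO_COL.items():
    _CODE_LUT[ord(_aa)] = _i


def encode(residues: str) -> np.ndarray:
    """Map a sanitized sequence to integer codes in PSSM column order."""
    codes = _CODE_LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({c for c in residues if c not in AA_SET})
        raise ValueError(f"non-standard residues in sequence: {bad}")
    return codes.astype(np.int64)
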