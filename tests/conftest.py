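import numpy as np
import pytest

from deepfragk.io_formats import AminoAcidSequence, PSSMProfile
from deepfragk.synthetic_data import (SyntheticLibrarySpec,
                                      make_fragment_library, synth_pssm)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_library():
    """4 well-separated fragment classes, 8 samples each."""
    return make_fragment_library(
        SyntheticLibrarySpec(n_classes=4, samples_per_class=8,
                             motif_strength=0.9, seed=11))


@pytest.fixture
def random_fragment(rng):
    def make(length=None, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        L = int(length or r.integers(4, 21))
        from deepfragk.alphabet import PSSM_COLUMN_ORDER
        residues = "".join(PSSM_COLUMN_ORDER[c] for c in r.integers(0, 20, L))
        seq = AminoAcidSequence(id=f"frag{L}", residues=residues)
        profile = synth_pssm(seq, noise=1.0, seed=int(r.integers(0, 2**31)))
        return seq, profile
    return make


@pytest.fixture
def toy_profile():
    seq = AminoAcidSequence(id="toy", residues="ACD")
    scores = np.arange(60, dtype=float).reshape(3, 20) / 10.0 - 3.0
    return PSSMProfile(sequence=seq, scores=scores)
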