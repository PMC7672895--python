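import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deepfragk.alphabet import PSSM_COLUMN_ORDER
from deepfragk.fragment_features import (DEFAULT_PARTITION, DWT_SCALES,
                                         FLEXIBILITY, HYDROPHILICITY,
                                         HYDROPHOBICITY, MEAN_ASA,
                                         SIDE_CHAIN_MASS, _dwt_stats,
                                         dwt_features,
                                         functional_group_frequencies,
                                         group_transitions, physchem_group_features,
                                         property_profile, pseaac,
                                         residue_distribution, sequence_entropy,
                                         sequence_group_features)
from deepfragk.io_formats import AminoAcidSequence


def seq(residues: str) -> AminoAcidSequence:
    return AminoAcidSequence(id="t", residues=residues)


valid_fragment = st.text(alphabet=PSSM_COLUMN_ORDER, min_size=4, max_size=20)


class TestGroupFrequencies:
    def test_homopolymer_concentrates_in_one_group(self):
        vals = functional_group_frequencies(seq("AAAA")).values
        idx = DEFAULT_PARTITION.names.index("aliphatic")
        assert vals[idx] == 1.0 and vals.sum() == 1.0

    def test_two_group_split(self):
        vals = functional_group_frequencies(seq("GPGP")).values
        g = DEFAULT_PARTITION.names.index("glycine")
        p = DEFAULT_PARTITION.names.index("proline")
        assert vals[g] == 0.5 and vals[p] == 0.5
        assert vals.sum() == 1.0

    def test_hand_tally(self):
        # A C D E F G H I K L over the default side-chain partition
        vals = functional_group_frequencies(seq("ACDEFGHIKL")).values
        expect = {"glycine": 0.1, "aliphatic": 0.3, "cysteine": 0.1,
                  "aromatic": 0.1, "acidic": 0.2, "basic": 0.2}
        for name, freq in expect.items():
            assert vals[DEFAULT_PARTITION.names.index(name)] == pytest.approx(freq)
        assert vals.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(valid_fragment)
    def test_sums_to_one(self, residues):
        assert functional_group_frequencies(seq(residues)).values.sum() \
            == pytest.approx(1.0, abs=1e-12)


class TestEntropy:
    def test_single_symbol_is_zero(self):
        np.testing.assert_array_equal(sequence_entropy(seq("AAAA")).values,
                                      [0.0, 0.0])

    def test_uniform_four_types(self):
        assert sequence_entropy(seq("ACDE")).values[0] == pytest.approx(2.0)

    def test_dipeptide_entropy_hand_value(self):
        # ACAC: dipeptides AC, CA, AC -> p = (2/3, 1/3)
        expect = -(2 / 3) * np.log2(2 / 3) - (1 / 3) * np.log2(1 / 3)
        assert sequence_entropy(seq("ACAC")).values[1] \
            == pytest.approx(expect, abs=1e-10)
        assert expect == pytest.approx(0.9183, abs=1e-4)

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            sequence_entropy(seq("A"))


class TestResidueDistribution:
    def test_single_residue(self):
        vals = residue_distribution(seq("A")).values
        assert vals[PSSM_COLUMN_ORDER.index("A")] == 1.0
        assert vals.sum() == 1.0

    def test_mean_relative_positions(self):
        vals = residue_distribution(seq("ACA")).values
        assert vals[PSSM_COLUMN_ORDER.index("A")] \
            == pytest.approx((1 / 3 + 3 / 3) / 2)
        assert vals[PSSM_COLUMN_ORDER.index("C")] == pytest.approx(2 / 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(valid_fragment)
    def test_absent_residues_are_zero(self, residues):
        vals = residue_distribution(seq(residues)).values
        for i, aa in enumerate(PSSM_COLUMN_ORDER):
            if aa not in residues:
                assert vals[i] == 0.0


class TestGroupTransitions:
    def test_single_cross_transition(self):
        vals = group_transitions(seq("GP")).values
        assert vals.sum() == 1.0 and vals.max() == 1.0

    def test_homopolymer_has_none(self):
        assert group_transitions(seq("GGGG")).values.sum() == 0.0

    def test_enumerated_pairs(self):
        # G|P, P|G, G|A: {G,P} twice, {G, aliphatic} once, over 3 adjacencies
        vals = group_transitions(seq("GPGA")).values
        assert sorted(vals[vals > 0].tolist()) == pytest.approx([1 / 3, 2 / 3])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(valid_fragment)
    def test_sum_bounded_by_one(self, residues):
        vals = group_transitions(seq(residues)).values
        lut = DEFAULT_PARTITION.code_of()
        codes = [lut[PSSM_COLUMN_ORDER.index(c)] for c in residues]
        all_cross = all(a != b for a, b in zip(codes, codes[1:]))
        total = vals.sum()
        assert total <= 1.0 + 1e-12
        assert (total == pytest.approx(1.0)) == all_cross


def pseaac_oracle(residues, lam, w):
    """Straight-line evaluation of the type-1 composition formulas."""
    scales = []
    for sc in (HYDROPHOBICITY, HYDROPHILICITY, SIDE_CHAIN_MASS):
        arr = np.array([sc.values[aa] for aa in PSSM_COLUMN_ORDER])
        scales.append((arr - arr.mean()) / arr.std())
    L = len(residues)
    idx = [PSSM_COLUMN_ORDER.index(c) for c in residues]
    thetas = []
    for k in range(1, min(lam, L - 1) + 1):
        tot = 0.0
        for i in range(L - k):
            tot += np.mean([(s[idx[i]] - s[idx[i + k]]) ** 2 for s in scales])
        thetas.append(tot / (L - k))
    freqs = np.zeros(20)
    for i in idx:
        freqs[i] += 1 / L
    denom = freqs.sum() + w * sum(thetas)
    out = np.zeros(40)
    out[:20] = freqs / denom
    for k, th in enumerate(thetas):
        out[20 + k] = w * th / denom
    return out


class TestPseAAC:
    def test_homopolymer_has_zero_correlation(self):
        vals = pseaac(seq("AAAAA"), lam=4, w=0.05).values
        assert vals[PSSM_COLUMN_ORDER.index("A")] == pytest.approx(1.0)
        assert np.all(vals[20:] == 0.0)

    def test_padding_beyond_available_lags(self):
        vals = pseaac(seq("ACDE"), lam=19, w=0.05).values
        assert np.any(vals[20:23] > 0)
        assert np.all(vals[23:] == 0.0)

    def test_matches_independent_oracle(self):
        got = pseaac(seq("ACDEF"), lam=2, w=0.05).values
        np.testing.assert_allclose(got, pseaac_oracle("ACDEF", 2, 0.05),
                                   atol=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(valid_fragment, st.integers(min_value=1, max_value=19))
    def test_nonnegative_and_normalized_prefix(self, residues, lam):
        vals = pseaac(seq(residues), lam=lam, w=0.05).values
        assert np.all(vals >= 0)
        k = min(lam, len(residues) - 1)
        assert vals[:20 + k].sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            pseaac(seq("ACDE"), lam=0, w=0.05)
        with pytest.raises(ValueError):
            pseaac(seq("ACDE"), lam=2, w=0.0)


def haar_matrix_32():
    """Orthonormal 3-level Haar analysis operator built by direct recursion."""
    def one_level(n):
        H = np.zeros((n, n))
        for i in range(n // 2):
            H[i, 2 * i] = H[i, 2 * i + 1] = 1 / np.sqrt(2)
            H[n // 2 + i, 2 * i] = 1 / np.sqrt(2)
            H[n // 2 + i, 2 * i + 1] = -1 / np.sqrt(2)
        return H
    T = one_level(32)
    for size in (16, 8):
        block = np.eye(32)
        block[:size, :size] = one_level(size)
        T = block @ T
    return T  # rows: A3(4), D3(4), D2(8), D1(16)


class TestDWT:
    def test_constant_profile(self):
        vals = dwt_features(seq("AAAA")).values
        hydro = vals[:14]
        c = HYDROPHOBICITY.values["A"]
        # detail bands carry nothing: mean/sd/max of D3, D2, D1 all 0
        np.testing.assert_allclose(hydro[3:12], 0.0, atol=1e-12)
        assert hydro[12] == pytest.approx(32 * c * c)

    def test_impulse_matches_direct_haar_matrix(self):
        profile = np.zeros(32)
        profile[0] = 1.0
        coeffs = haar_matrix_32() @ profile
        bands = [coeffs[:4], coeffs[4:8], coeffs[8:16], coeffs[16:]]
        expect = []
        for band in bands:
            expect += [band.mean(), band.std(), band.max()]
        energy = float((coeffs ** 2).sum())
        p = coeffs[coeffs != 0] ** 2 / energy
        expect += [energy, float(-(p * np.log2(p)).sum())]
        np.testing.assert_allclose(_dwt_stats(profile), expect, atol=1e-10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(valid_fragment, st.sampled_from(range(3)))
    def test_parseval_on_random_fragments(self, residues, which):
        profile = property_profile(seq(residues), DWT_SCALES[which])
        pos = np.linspace(0, 1, len(profile))
        resampled = np.interp(np.linspace(0, 1, 32), pos, profile)
        energy = _dwt_stats(profile)[12]
        assert energy == pytest.approx((resampled ** 2).sum(), rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dwt_features(seq("ACD"))


class TestPropertyProfile:
    def test_lookup_of_embedded_scale(self):
        got = property_profile(seq("AR"), HYDROPHOBICITY)
        np.testing.assert_array_equal(got, [1.8, -4.5])

    def test_homopolymer_constant_and_length(self):
        for scale in (FLEXIBILITY, MEAN_ASA):
            prof = property_profile(seq("WWWWW"), scale)
            assert len(prof) == 5 and np.ptp(prof) == 0.0


class TestGroupConcatenations:
    def test_dimensions_and_order(self):
        blocks = sequence_group_features(seq("GPGP"))
        assert [b.name for b in blocks] == ["group_frequencies", "entropy",
                                            "residue_distribution",
                                            "group_transitions"]
        assert sum(b.dim for b in blocks) == 77
        phys = physchem_group_features(seq("GPGP"))
        assert [b.name for b in phys] == ["pseaac", "dwt"]
        assert sum(b.dim for b in phys) == 82

    def test_concatenation_equals_individual_ops(self):
        s = seq("GPGP")
        blocks = sequence_group_features(s)
        np.testing.assert_array_equal(
            blocks[0].values, functional_group_frequencies(s).values)
        np.testing.assert_array_equal(blocks[1].values,
                                      sequence_entropy(s).values)

    def test_homopolymer_joint_degeneracies(self):
        s = seq("AAAAAA")
        phys = physchem_group_features(s)
        assert np.all(phys[0].values[20:] == 0.0)          # no correlation
        assert np.all(np.abs(phys[1].values[3:12]) < 1e-12)  # no detail signal
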