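"""Encoders against hand-worked examples and naive counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sixma import (
    LabeledDataset,
    SequenceRecord,
    encode_binary,
    encode_enac,
    encode_kmer,
    encode_ncp,
    fit_pstnpds,
    reduce_strand,
    transform_pstnpds,
    trinucleotide_index,
)
from sixma.encoders import TRI_ORDER
from sixma.errors import (
    AlphabetError,
    FitError,
    LengthMismatchError,
    ParameterError,
)
from tests.conftest import random_dataset

# ---------------------------------------------------------------------------
# naive re-implementations (string slicing + counting), the independent oracle
# ---------------------------------------------------------------------------

BASES = "ACGT"
NCP = {"A": [1, 1, 1], "C": [0, 1, 0], "G": [1, 0, 0], "T": [0, 0, 1]}


def naive_binary(seq):
    return [1.0 if b == c else 0.0 for b in seq for c in BASES]


def naive_kmer(seq, k):
    from itertools import product

    windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    return [windows.count("".join(m)) / len(windows) for m in product(BASES, repeat=k)]


def naive_ncp(seq):
    return [v for b in seq for v in NCP[b]]


def naive_enac(seq, w):
    out = []
    for i in range(len(seq) - w + 1):
        win = seq[i : i + w]
        out.extend(win.count(c) / w for c in BASES)
    return out


def naive_reduce(seq):
    return "".join({"A": "A", "T": "A", "C": "C", "G": "C"}[b] for b in seq)


def naive_pstnpds(train_seqs, train_labels, seq):
    """Recount class frequencies from scratch and look up per-position z."""
    L = len(seq)
    pos = [s for s, l in zip(train_seqs, train_labels) if l == 1]
    neg = [s for s, l in zip(train_seqs, train_labels) if l == 0]
    phi = []
    for j in range(L - 2):
        tri = naive_reduce(seq[j : j + 3])
        fp = sum(naive_reduce(s[j : j + 3]) == tri for s in pos) / len(pos)
        fn = sum(naive_reduce(s[j : j + 3]) == tri for s in neg) / len(neg)
        phi.append(fp - fn)
    return phi


def ds_of(seqs, labels):
    return LabeledDataset(
        SequenceRecord(f"r{i}", s, l) for i, (s, l) in enumerate(zip(seqs, labels))
    )


# ---------------------------------------------------------------------------
# hand-worked examples
# ---------------------------------------------------------------------------

class TestExamples:
    def test_binary_concatenates_onehot_codes(self):
        X = encode_binary(ds_of(["ACGT"], [1]))
        assert X.values.tolist() == [
            [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1]
        ]
        assert X.feature_names[:4] == ["pos01_A", "pos01_C", "pos01_G", "pos01_T"]

    def test_binary_rows_sum_to_length(self, small_dataset):
        X = encode_binary(small_dataset)
        assert np.allclose(X.values.sum(axis=1), small_dataset.length)

    def test_kmer3_has_64_features(self, small_dataset):
        assert encode_kmer(small_dataset, k=3).n_features == 64

    def test_kmer_counts_overlapping_windows(self):
        # AACAA, k=2: windows AA,AC,CA,AA
        X = encode_kmer(ds_of(["AACAA"], [1]), k=2)
        by_name = dict(zip(X.feature_names, X.values[0]))
        assert by_name["AA"] == pytest.approx(0.5)
        assert by_name["AC"] == pytest.approx(0.25)
        assert by_name["CA"] == pytest.approx(0.25)
        assert sum(v for v in by_name.values()) == pytest.approx(1.0)

    def test_kmer_all_same_base(self):
        X = encode_kmer(ds_of(["AAAAAA"], [1]), k=3)
        assert X.values[0, X.feature_names.index("AAA")] == 1.0
        assert X.values[0].sum() == 1.0

    def test_ncp_codes(self):
        X = encode_ncp(ds_of(["CG"], [1]))
        assert X.values.tolist() == [[0, 1, 0, 1, 0, 0]]
        assert encode_ncp(ds_of(["A"], [1])).values.tolist() == [[1, 1, 1]]
        assert encode_ncp(ds_of(["T"], [1])).values.tolist() == [[0, 0, 1]]

    def test_enac_dimension_at_default_window(self, small_dataset):
        assert encode_enac(small_dataset, window=5).n_features == 148

    def test_enac_window_frequencies(self):
        X = encode_enac(ds_of(["AACGT"], [1]), window=5)
        assert X.values[0].tolist() == pytest.approx([0.4, 0.2, 0.2, 0.2])
        X2 = encode_enac(ds_of(["AAAAA"], [1]), window=5)
        assert X2.values[0].tolist() == [1, 0, 0, 0]

    def test_reduce_strand(self):
        assert reduce_strand("ATGC") == "AACC"
        assert reduce_strand("AAAA") == "AAAA"
        s = reduce_strand("ACGTTGCA")
        assert reduce_strand(s) == s  # idempotent

    def test_trinucleotide_index_bijection(self):
        assert trinucleotide_index("AAA") == 1
        assert trinucleotide_index("CCC") == 8
        assert sorted(trinucleotide_index(t) for t in TRI_ORDER) == list(range(1, 9))

    def test_trinucleotide_index_rejects_unreduced(self):
        with pytest.raises(AlphabetError):
            trinucleotide_index("ACG")


class TestPSTNPds:
    def test_toy_counting(self):
        """1 positive AAAA vs 1 negative CCCC: z is +1 on the AAA row and
        -1 on the CCC row at both positions."""
        model = fit_pstnpds(ds_of(["AAAA", "CCCC"], [1, 0]))
        expected = np.zeros((8, 2))
        expected[0, :] = 1.0   # AAA row
        expected[7, :] = -1.0  # CCC row
        assert np.array_equal(model.z, expected)
        X = transform_pstnpds(model, ds_of(["AAAA"], [1]))
        assert X.values.tolist() == [[1.0, 1.0]]

    def test_identical_classes_give_zero_z(self):
        seqs = ["ACGTA", "GGTCA", "ACGTA", "GGTCA"]
        model = fit_pstnpds(ds_of(seqs, [1, 1, 0, 0]))
        assert np.allclose(model.z, 0.0)

    def test_columns_sum_to_one(self, small_dataset):
        model = fit_pstnpds(small_dataset)
        assert np.allclose(model.f_pos.sum(axis=0), 1.0)
        assert np.allclose(model.f_neg.sum(axis=0), 1.0)
        assert np.all(np.abs(model.z) <= 1.0)

    def test_label_swap_negates_z(self, small_dataset):
        model = fit_pstnpds(small_dataset)
        flipped = ds_of(small_dataset.sequences, 1 - small_dataset.labels)
        assert np.allclose(fit_pstnpds(flipped).z, -model.z)

    def test_feature_count_is_L_minus_2(self, small_dataset):
        model = fit_pstnpds(small_dataset)
        assert transform_pstnpds(model, small_dataset).n_features == 39

    def test_single_class_training_rejected(self):
        with pytest.raises(FitError):
            fit_pstnpds(ds_of(["AAAA", "CCCC"], [1, 1]))

    def test_length_mismatch_rejected(self, small_dataset):
        model = fit_pstnpds(small_dataset)
        with pytest.raises(LengthMismatchError):
            transform_pstnpds(model, ds_of(["ACGT"], [1]))

    def test_transform_matches_recount_oracle(self):
        train = random_dataset(20, 20, 15, seed=3)
        probe = random_dataset(25, 25, 15, seed=4)
        model = fit_pstnpds(train)
        X = transform_pstnpds(model, probe)
        for r, rec in enumerate(probe):
            expected = naive_pstnpds(train.sequences, train.labels, rec.seq)
            assert np.allclose(X.values[r], expected, atol=1e-12)

    def test_json_round_trip(self, tmp_path, small_dataset):
        from sixma import PSTNPdsModel

        model = fit_pstnpds(small_dataset)
        path = tmp_path / "m.json"
        model.to_json(path)
        again = PSTNPdsModel.from_json(path)
        assert np.array_equal(again.z, model.z)
        assert again.tri_order == model.tri_order
        assert again.train_fingerprint == model.train_fingerprint


class TestOracleEquivalence:
    """All encoders agree with the naive slicing/counting oracles."""

    def test_all_encoders_match_naive_on_random_sequences(self):
        ds = random_dataset(50, 50, 21, seed=9)
        checks = [
            (encode_binary(ds).values, [naive_binary(s) for s in ds.sequences]),
            (encode_kmer(ds, k=2).values, [naive_kmer(s, 2) for s in ds.sequences]),
            (encode_ncp(ds).values, [naive_ncp(s) for s in ds.sequences]),
            (encode_enac(ds, window=5).values, [naive_enac(s, 5) for s in ds.sequences]),
        ]
        for got, want in checks:
            assert np.allclose(got, np.array(want), atol=1e-12)
        for s in ds.sequences:
            assert reduce_strand(s) == naive_reduce(s)


class TestDimensionLaw:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        L=st.integers(min_value=6, max_value=30),
        k=st.integers(min_value=1, max_value=3),
        w=st.integers(min_value=1, max_value=6),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_feature_counts(self, L, k, w, seed):
        ds = random_dataset(3, 3, L, seed=seed)
        assert encode_binary(ds).n_features == 4 * L
        assert encode_ncp(ds).n_features == 3 * L
        assert encode_kmer(ds, k).n_features == 4 ** k
        assert encode_enac(ds, w).n_features == (L - w + 1) * 4
        assert transform_pstnpds(fit_pstnpds(ds), ds).n_features == L - 2

    def test_normalization(self, small_dataset):
        Xk = encode_kmer(small_dataset, k=3)
        assert np.allclose(Xk.values.sum(axis=1), 1.0)
        Xe = encode_enac(small_dataset, window=5)
        blocks = Xe.values.reshape(len(small_dataset), -1, 4)
        assert np.allclose(blocks.sum(axis=2), 1.0)

    @pytest.mark.parametrize("bad_call", [
        lambda ds: encode_kmer(ds, k=100),
        lambda ds: encode_enac(ds, window=100),
        lambda ds: encode_kmer(ds, k=0),
    ])
    def test_out_of_range_parameters(self, small_dataset, bad_call):
        with pytest.raises(ParameterError):
            bad_call(small_dataset)
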