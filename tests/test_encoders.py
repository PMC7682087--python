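"""Encoders: one-hot bijectivity, AAindex lookup, CKSAAP vs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from malprec.encoders import (
    AAindexTable,
    CKSAAPConfig,
    N_ALPHA,
    cksaap_column_names,
    decode_onehot,
    encode_aaindex,
    encode_cksaap,
    encode_combined,
    encode_onehot,
    load_aaindex_table,
)
from malprec.windows import ALPHABET, PeptideWindow

WORKED_PEPTIDE = "VAERAALEKLDANQEYK"

window_strings = st.text(alphabet=ALPHABET, min_size=2, max_size=17)


def brute_force_cksaap(residues: str, config: CKSAAPConfig) -> np.ndarray:
    """Independent oracle: enumerate all (i, i+k+1) pairs into a dict."""
    blocks = []
    for k in config.k_list:
        tally: dict[str, float] = {a + b: 0.0 for a in ALPHABET for b in ALPHABET}
        n_pairs = 0
        for i in range(len(residues)):
            j = i + k + 1
            if j < len(residues):
                pair = residues[i] + residues[j]
            elif config.pad_beyond_window:
                pair = residues[i] + "X"
            else:
                continue
            tally[pair] += 1.0
            n_pairs += 1
        vec = np.array([tally[a + b] for a in ALPHABET for b in ALPHABET])
        if config.normalize and n_pairs:
            vec /= n_pairs
        blocks.append(vec)
    return np.concatenate(blocks)


class TestOneHot:
    def test_17mer_geometry(self):
        v = encode_onehot(WORKED_PEPTIDE)
        assert v.shape == (17 * 21,)
        assert v.sum() == 17
        assert set(np.unique(v)) == {0.0, 1.0}

    def test_a_block(self):
        v = encode_onehot("A")
        assert v[0] == 1 and v[1:].sum() == 0

    def test_x_block(self):
        v = encode_onehot("X")
        assert v[-1] == 1 and v[:-1].sum() == 0

    def test_rejects_bad_character(self):
        with pytest.raises(ValueError, match="position 1"):
            encode_onehot("AZA".replace("Z", "1"))

    @given(window_strings)
    @settings(max_examples=100, derandomize=True)
    def test_bijective(self, s):
        v = encode_onehot(s)
        assert v.reshape(-1, N_ALPHA).sum(axis=1).tolist() == [1.0] * len(s)
        assert decode_onehot(v) == s


class TestAAindex:
    def test_bundled_table_shape(self):
        t = load_aaindex_table()
        assert t.n_properties == 9
        assert t.values.shape == (9, 21)
        assert np.all(t.values[:, -1] == 0.0)  # X column zero by default

    def test_x_mean_policy(self):
        t = load_aaindex_table(x_policy="mean")
        assert np.allclose(t.values[:, -1], t.values[:, :-1].mean(axis=1))

    def test_17mer_length(self):
        assert encode_aaindex(WORKED_PEPTIDE).shape == (17 * 9,)

    def test_constant_window_repeats_residue_values(self):
        t = load_aaindex_table()
        v = encode_aaindex("G" * 17, t)
        g = t.values[:, ALPHABET.index("G")]
        assert np.allclose(v.reshape(17, 9), np.tile(g, (17, 1)))

    def test_all_x_window_is_zero(self):
        assert np.all(encode_aaindex("X" * 17) == 0.0)

    def test_swapping_positions_swaps_slices(self, rng):
        t = load_aaindex_table()
        s = "VAERAALEKLDANQEYW"
        swapped = list(s)
        swapped[2], swapped[10] = swapped[10], swapped[2]
        a = encode_aaindex(s, t).reshape(17, 9)
        b = encode_aaindex("".join(swapped), t).reshape(17, 9)
        assert np.allclose(a[2], b[10]) and np.allclose(a[10], b[2])
        mask = np.ones(17, bool)
        mask[[2, 10]] = False
        assert np.allclose(a[mask], b[mask])

    def test_table_validation(self):
        with pytest.raises(ValueError):
            AAindexTable(property_names=("p",), values=np.zeros((2, 21)))
        bad = np.zeros((1, 21))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            AAindexTable(property_names=("p",), values=bad)


class TestCKSAAP:
    def test_worked_example_nva(self):
        cfg = CKSAAPConfig(k_list=(0,))
        v = encode_cksaap(WORKED_PEPTIDE, cfg)
        names = cksaap_column_names(cfg)
        assert v[names.index("cksaap_k0_VA")] == 1.0

    def test_worked_example_padded_pair_count(self):
        v = encode_cksaap(WORKED_PEPTIDE, CKSAAPConfig(k_list=(0,)))
        assert v.sum() == 17  # includes the terminal KX pair
        names = cksaap_column_names(CKSAAPConfig(k_list=(0,)))
        assert v[names.index("cksaap_k0_KX")] == 1.0

    def test_default_vector_length(self):
        assert encode_cksaap(WORKED_PEPTIDE).shape == (441 * 4,)

    def test_unpadded_mode_has_l_minus_k_minus_1_pairs(self):
        for k in range(4):
            v = encode_cksaap(
                WORKED_PEPTIDE, CKSAAPConfig(k_list=(k,), pad_beyond_window=False)
            )
            assert v.sum() == 17 - k - 1

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            encode_cksaap("AK", CKSAAPConfig(k_list=(5,)))

    @given(window_strings, st.sets(st.integers(0, 3), min_size=1),
           st.booleans(), st.booleans())
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, s, ks, normalize, pad):
        ks = {k for k in ks if k <= len(s) - 1} or {0}
        cfg = CKSAAPConfig(k_list=tuple(ks), normalize=normalize,
                           pad_beyond_window=pad)
        assert np.allclose(encode_cksaap(s, cfg), brute_force_cksaap(s, cfg))

    @given(window_strings)
    @settings(max_examples=50, derandomize=True)
    def test_conservation(self, s):
        counts = encode_cksaap(s, CKSAAPConfig(k_list=(0, 1)))
        assert counts[:441].sum() == len(s) and counts[441:].sum() == len(s)
        freqs = encode_cksaap(s, CKSAAPConfig(k_list=(0, 1), normalize=True))
        assert np.isclose(freqs[:441].sum(), 1.0)
        assert np.isclose(freqs[441:].sum(), 1.0)

    def test_permutation_sensitivity(self):
        # same composition, different pair structure
        a, b = "VAERAALEKLDANQEYK", "AVREAALEKLDANQEYK"
        assert sorted(a) == sorted(b)
        va = encode_cksaap(a, CKSAAPConfig(k_list=(0,)))
        vb = encode_cksaap(b, CKSAAPConfig(k_list=(0,)))
        assert not np.allclose(va, vb)
        # compositional marginals (row sums over partners) agree except
        # at the pair ends touched by padding, which depend on the last
        # residue only -- identical here.
        assert np.allclose(va.reshape(21, 21).sum(axis=1),
                           vb.reshape(21, 21).sum(axis=1))


class TestCombined:
    def test_default_width_and_block_order(self, small_labeled_windows):
        fm = encode_combined(small_labeled_windows[:10])
        assert fm.values.shape == (10, 1764 + 357 + 153)
        assert list(fm.block_spans) == ["cksaap", "onehot", "aaindex"]
        assert fm.block_spans["cksaap"] == (0, 1764)
        assert fm.block_spans["aaindex"] == (2121, 2274)

    def test_single_block_subset(self, small_labeled_windows):
        fm = encode_combined(small_labeled_windows[:10], encoders=("onehot",))
        assert fm.values.shape == (10, 357)

    def test_empty_window_list_keeps_metadata(self):
        fm = encode_combined([])
        assert fm.values.shape == (0, 2274)
        assert len(fm.column_names) == 2274

    def test_mixed_lengths_rejected(self):
        w17 = PeptideWindow(residues="A" * 8 + "K" + "A" * 8)
        w15 = PeptideWindow(residues="A" * 7 + "K" + "A" * 7, n=7, eps=7)
        with pytest.raises(ValueError, match="mixed"):
            encode_combined([w17, w15])

    def test_rows_match_individual_encoders(self, small_labeled_windows):
        w = small_labeled_windows[0]
        fm = encode_combined([w])
        row = fm.values[0]
        assert np.allclose(row[:1764], encode_cksaap(w))
        assert np.allclose(row[1764:2121], encode_onehot(w))
        assert np.allclose(row[2121:], encode_aaindex(w))

    def test_csv_and_sidecar(self, tmp_path, small_labeled_windows):
        import json

        import pandas as pd

        fm = encode_combined(small_labeled_windows[:3], encoders=("onehot",))
        out = tmp_path / "f.csv"
        fm.to_csv(out)
        back = pd.read_csv(out)
        assert list(back.columns) == fm.column_names
        assert np.allclose(back.values, fm.values)
        cfg = fm.sidecar_config()
        assert json.dumps(cfg)  # serializable
        assert cfg["alphabet"] == ALPHABET
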