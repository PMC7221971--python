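import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphppi import features
from graphppi.alphabet import AA_INDEX, PHYSICOCHEMICAL_ORDER
from graphppi.features import (
    SubstitutionMatrix,
    dipeptide_composition,
    encode_adjacency,
    energy_profile,
    fuse,
    load_contact_matrix,
    window_energy,
)
from graphppi.sequence_io import ProteinRecord


def bipartite_energy_oracle(M):
    """Sum of |eigenvalues| of the full symmetric adjacency [[0,M],[M^T,0]]."""
    a, b = M.shape
    full = np.zeros((a + b, a + b))
    full[:a, a:] = M
    full[a:, :a] = M.T
    return np.abs(np.linalg.eigvalsh(full)).sum()


class TestEncodeAdjacency:
    def test_single_residue_one_hot(self, unit_matrix):
        M = encode_adjacency(ProteinRecord("p", "D"), unit_matrix)
        expected = np.zeros((20, 1))
        expected[0, 0] = 1.0
        np.testing.assert_array_equal(M, expected)

    def test_repeated_residue_identical_columns(self, unit_matrix):
        M = encode_adjacency(ProteinRecord("p", "DD"), unit_matrix)
        np.testing.assert_array_equal(M[:, 0], M[:, 1])
        assert M[0, 0] == 1.0 and M.sum() == 2.0

    def test_contact_column_lookup(self, contact_matrix):
        # D is first and K last in the physicochemical ordering
        M = encode_adjacency(ProteinRecord("p", "DK"), contact_matrix)
        np.testing.assert_array_equal(M[:, 0], contact_matrix.values[:, 0])
        np.testing.assert_array_equal(M[:, 1], contact_matrix.values[:, 19])

    def test_non_canonical_gives_zero_column(self, unit_matrix):
        M = encode_adjacency(ProteinRecord("p", "DXD"), unit_matrix)
        assert M[:, 1].sum() == 0.0 and M[:, 0].sum() == 1.0


class TestWindowEnergy:
    def test_zero_matrix(self):
        assert window_energy(np.zeros((20, 20))) == 0.0

    @pytest.mark.parametrize("a,b", [(3, 2), (1, 1), (20, 20), (5, 7)])
    def test_complete_bipartite_closed_form(self, a, b):
        M = np.zeros((20, 20))
        M[:a, :b] = 1.0
        assert window_energy(M) == pytest.approx(2 * np.sqrt(a * b), abs=1e-10)

    def test_one_hot_counts_closed_form(self, rng):
        # columns one-hot with per-row counts n_i -> energy = 2 sum sqrt(n_i)
        rows = rng.integers(0, 20, size=20)
        M = np.zeros((20, 20))
        M[rows, np.arange(20)] = 1.0
        counts = np.bincount(rows, minlength=20)
        assert window_energy(M) == pytest.approx(
            2 * np.sum(np.sqrt(counts)), abs=1e-10
        )

    def test_homopolymer_window(self, unit_matrix):
        M = encode_adjacency(ProteinRecord("p", "D" * 20), unit_matrix)
        assert window_energy(M) == pytest.approx(2 * np.sqrt(20), abs=1e-10)

    def test_matches_full_adjacency_eigensolver(self, rng):
        for _ in range(50):
            M = rng.normal(size=(20, 20))
            assert window_energy(M) == pytest.approx(
                bipartite_energy_oracle(M), abs=1e-8
            )

    def test_transpose_and_permutation_invariance(self, rng):
        M = rng.normal(size=(20, 20))
        e = window_energy(M)
        assert window_energy(M.T) == pytest.approx(e, abs=1e-8)
        pr, pc = rng.permutation(20), rng.permutation(20)
        assert window_energy(M[pr][:, pc]) == pytest.approx(e, abs=1e-8)

    @given(c=st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_absolute_homogeneity(self, c):
        rng = np.random.default_rng(99)
        M = rng.normal(size=(20, 20))
        assert window_energy(c * M) == pytest.approx(
            abs(c) * window_energy(M), rel=1e-9, abs=1e-9
        )

    def test_non_finite_rejected(self):
        M = np.zeros((20, 20))
        M[0, 0] = np.nan
        with pytest.raises(ValueError):
            window_energy(M)


class TestEnergyProfile:
    def test_homopolymer_219_all_windows_equal(self, unit_matrix):
        ep = energy_profile(ProteinRecord("p", "D" * 219), unit_matrix)
        np.testing.assert_allclose(ep, 2 * np.sqrt(20), atol=1e-10)
        assert ep.shape == (200,)

    def test_length_19_zero_padded(self, unit_matrix):
        ep = energy_profile(ProteinRecord("p", "D" * 19), unit_matrix)
        np.testing.assert_array_equal(ep, np.zeros(200))

    def test_length_21_two_windows(self, unit_matrix, rng):
        seq = "".join(
            PHYSICOCHEMICAL_ORDER[i] for i in rng.integers(0, 20, size=21)
        )
        ep = energy_profile(ProteinRecord("p", seq), unit_matrix)
        assert ep[0] > 0 and ep[1] > 0
        np.testing.assert_array_equal(ep[2:], np.zeros(198))

    def test_long_sequence_truncated_left_anchored(self, unit_matrix, rng):
        seq = "".join(
            PHYSICOCHEMICAL_ORDER[i] for i in rng.integers(0, 20, size=300)
        )
        ep = energy_profile(ProteinRecord("p", seq), unit_matrix)
        rec_prefix = ProteinRecord("p", seq[:219])
        np.testing.assert_allclose(ep, energy_profile(rec_prefix, unit_matrix), atol=1e-10)

    def test_windows_match_scalar_energy(self, unit_matrix, contact_matrix, rng):
        seq = "".join(
            PHYSICOCHEMICAL_ORDER[i] for i in rng.integers(0, 20, size=40)
        )
        rec = ProteinRecord("p", seq)
        for S in (unit_matrix, contact_matrix):
            ep = energy_profile(rec, S)
            M = encode_adjacency(rec, S)
            for k in range(40 - 19):
                assert ep[k] == pytest.approx(window_energy(M[:, k : k + 20]), abs=1e-9)


class TestDipeptide:
    def test_triple_a(self):
        dp = dipeptide_composition(ProteinRecord("p", "AAA"))
        idx = 20 * AA_INDEX["A"] + AA_INDEX["A"]
        assert dp[idx] == 1.0 and dp.sum() == 1.0

    def test_acac_frequencies(self):
        dp = dipeptide_composition(ProteinRecord("p", "ACAC"))
        assert dp[20 * AA_INDEX["A"] + AA_INDEX["C"]] == pytest.approx(2 / 3)
        assert dp[20 * AA_INDEX["C"] + AA_INDEX["A"]] == pytest.approx(1 / 3)
        assert dp.sum() == pytest.approx(1.0)

    @given(st.text(alphabet=PHYSICOCHEMICAL_ORDER, min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_with_rational_entries(self, seq):
        dp = dipeptide_composition(ProteinRecord("p", seq))
        assert dp.shape == (400,)
        assert dp.sum() == pytest.approx(1.0, abs=1e-12)
        # every entry is a count over L-1
        counts = dp * (len(seq) - 1)
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_single_residue_zero_vector(self):
        np.testing.assert_array_equal(
            dipeptide_composition(ProteinRecord("p", "A")), np.zeros(400)
        )


class TestFuse:
    def test_short_protein_energy_blocks_zero(self, unit_matrix, contact_matrix):
        v = fuse(ProteinRecord("p", "DK" * 9 + "D"), unit_matrix, contact_matrix)
        assert v.shape == (800,)
        np.testing.assert_array_equal(v[:400], np.zeros(400))
        assert v[400:].sum() == pytest.approx(1.0)

    def test_homopolymer_blocks(self, unit_matrix, contact_matrix):
        v = fuse(ProteinRecord("p", "D" * 219), unit_matrix, contact_matrix)
        np.testing.assert_allclose(v[:200], 2 * np.sqrt(20), atol=1e-10)
        assert v[400] == 1.0  # f_DD, first dipeptide slot

    def test_deterministic(self, unit_matrix, contact_matrix, rng):
        seq = "".join(PHYSICOCHEMICAL_ORDER[i] for i in rng.integers(0, 20, 80))
        rec = ProteinRecord("p", seq)
        np.testing.assert_array_equal(
            fuse(rec, unit_matrix, contact_matrix), fuse(rec, unit_matrix, contact_matrix)
        )


class TestContactMatrixIO:
    def test_fixture_loads_and_reexports(self, tmp_path, contact_matrix):
        # re-export in internal order, reload, compare
        import pandas as pd

        order = list(PHYSICOCHEMICAL_ORDER)
        df = pd.DataFrame(contact_matrix.values, index=order, columns=order)
        p = tmp_path / "cm.tsv"
        df.to_csv(p, sep="\t")
        again = load_contact_matrix(p)
        np.testing.assert_allclose(again.values, contact_matrix.values, atol=1e-12)

    def test_wrong_shape_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        rows = ["aa\t" + "\t".join(PHYSICOCHEMICAL_ORDER)]
        for aa in PHYSICOCHEMICAL_ORDER[:19]:
            rows.append(aa + "\t" + "\t".join(["0.0"] * 20))
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="20x20"):
            load_contact_matrix(p)

    def test_alphabetical_file_permuted_into_basis(self, tmp_path):
        # tagged matrix: entry = 100*i + j under ALPHABETICAL indexing
        alpha = sorted(PHYSICOCHEMICAL_ORDER)
        rows = ["aa\t" + "\t".join(alpha)]
        for i, aa in enumerate(alpha):
            rows.append(aa + "\t" + "\t".join(str(100 * i + j) for j in range(20)))
        p = tmp_path / "tag.tsv"
        p.write_text("\n".join(rows) + "\n")
        m = load_contact_matrix(p)
        for r, aa_r in enumerate(PHYSICOCHEMICAL_ORDER):
            for c, aa_c in enumerate(PHYSICOCHEMICAL_ORDER):
                assert m.values[r, c] == 100 * alpha.index(aa_r) + alpha.index(aa_c)


def test_unit_matrix_is_identity(unit_matrix):
    np.testing.assert_array_equal(unit_matrix.values, np.eye(20))


def test_substitution_matrix_shape_validated():
    with pytest.raises(ValueError):
        SubstitutionMatrix("bad", np.zeros((19, 20)))


def test_feature_table_layout(small_dataset):
    table = features.feature_table(dict(list(small_dataset.proteins.items())[:3]))
    assert table.shape == (3, 800)
    assert list(table.columns[:2]) == ["pge_001", "pge_002"]
    assert table.columns[400] == "dp_DD"
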