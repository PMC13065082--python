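"""Featurization: exact reference values, geometry, and oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgrhost.features import (
    DEFAULT_CORNERS,
    CornerAssignment,
    GenomeSequence,
    build_feature_tensor,
    cgr_trajectory,
    count_kmers,
    kmer_average_positions,
    kmer_cell_index,
    minmax_normalize,
)

from conftest import (
    WORKED_COUNTS,
    WORKED_K,
    WORKED_MEAN_POSITIONS,
    WORKED_TRAJECTORY,
    oracle_positions,
    random_dna,
)

dna = st.text(alphabet="ACGT", min_size=3, max_size=200)


class TestWorkedExample:
    """Every printed value of the hand computation, bit-exact."""

    def test_trajectory(self, worked_seq):
        traj = cgr_trajectory(worked_seq)
        assert list(traj.points) == WORKED_TRAJECTORY

    def test_counts(self, worked_seq):
        table = count_kmers(worked_seq, WORKED_K)
        assert dict(table.counts) == WORKED_COUNTS
        assert table.total() == len(worked_seq) - WORKED_K + 1

    def test_mean_positions(self, worked_seq):
        pos = kmer_average_positions(worked_seq, WORKED_K)
        for word, (mx, my) in WORKED_MEAN_POSITIONS.items():
            assert pos.mean_x[word] == mx, word
            assert pos.mean_y[word] == my, word

    def test_tensor_places_values_in_cells(self, worked_seq):
        t = build_feature_tensor(worked_seq, WORKED_K, normalize=False)
        for word, count in WORKED_COUNTS.items():
            r, c = kmer_cell_index(word)
            assert t.f1[r, c] == count
            mx, my = WORKED_MEAN_POSITIONS[word]
            assert t.f2[r, c] == mx
            assert t.f3[r, c] == my

    def test_normalized_tensor_max_count_cell_is_one(self, worked_seq):
        t = minmax_normalize(build_feature_tensor(worked_seq, WORKED_K, normalize=False))
        r, c = kmer_cell_index("GT")
        assert t.f1[r, c] == 1.0  # count 2 against min 0, max 2


class TestTrajectory:
    def test_single_a(self):
        traj = cgr_trajectory(GenomeSequence("s", "A"))
        assert traj.points == ((0.25, 0.25),)

    def test_tttt_converges_to_t_corner(self):
        # (1,0) corner: iterate the midpoint map by hand four times
        traj = cgr_trajectory(GenomeSequence("s", "TTTT"))
        assert traj.points[-1] == (0.96875, 0.03125)

    def test_ambiguity_emits_no_point(self):
        plain = cgr_trajectory(GenomeSequence("s", "ACGT"))
        salted = cgr_trajectory(GenomeSequence("s", "ACNGT"))
        assert salted.points == plain.points

    @given(dna)
    @settings(max_examples=50, derandomize=True)
    def test_points_inside_open_unit_square(self, residues):
        traj = cgr_trajectory(GenomeSequence("s", residues))
        pts = np.array(traj.points)
        assert (pts > 0).all() and (pts < 1).all()

    @given(dna)
    @settings(max_examples=25, derandomize=True)
    def test_each_point_is_midpoint_to_corner(self, residues):
        traj = cgr_trajectory(GenomeSequence("s", residues))
        prev = np.array(traj.start)
        for ch, pt in zip(residues, traj.points):
            corner = np.array(DEFAULT_CORNERS.corner(ch))
            assert np.array_equal(np.asarray(pt), 0.5 * (prev + corner))
            prev = np.asarray(pt)


class TestCounts:
    @pytest.mark.parametrize(
        "residues, k, expected_nonzero",
        [
            ("AAAA", 1, {"A": 4}),
            ("ACGTACGT", 3, {"ACG": 2, "CGT": 2, "GTA": 1, "TAC": 1}),
        ],
    )
    def test_hand_enumerated(self, residues, k, expected_nonzero):
        table = count_kmers(GenomeSequence("s", residues), k)
        assert {w: c for w, c in table.counts.items() if c} == expected_nonzero
        assert table.total() == len(residues) - k + 1

    def test_ambiguous_windows_excluded(self):
        # ACGNA, k=2: windows AC, CG valid; GN, NA invalid
        table = count_kmers(GenomeSequence("s", "ACGNA"), 2)
        assert table.total() == 2

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="length"):
            count_kmers(GenomeSequence("s", "AC"), 3)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            count_kmers(GenomeSequence("s", "ACGT"), 0)

    @given(dna, st.integers(min_value=1, max_value=4))
    @settings(max_examples=50, derandomize=True)
    def test_conservation(self, residues, k):
        # ambiguity-free: counts sum to L - k + 1
        if len(residues) < k:
            return
        table = count_kmers(GenomeSequence("s", residues), k)
        assert table.total() == len(residues) - k + 1


class TestCellIndex:
    @pytest.mark.parametrize(
        "word, cell",
        [("CC", (0, 0)), ("TT", (3, 3)), ("GG", (0, 3)), ("AA", (3, 0))],
    )
    def test_known_cells(self, word, cell):
        assert kmer_cell_index(word) == cell

    def test_rejects_invalid_characters(self):
        with pytest.raises(ValueError):
            kmer_cell_index("AN", 2)

    @given(dna, st.integers(min_value=1, max_value=5))
    @settings(max_examples=40, derandomize=True)
    def test_mean_positions_lie_in_their_cell(self, residues, k):
        if len(residues) < k:
            return
        seq = GenomeSequence("s", residues)
        pos = kmer_average_positions(seq, k)
        counts = count_kmers(seq, k).counts
        side = 2**k
        for word, n in counts.items():
            if n == 0:
                assert pos.mean_x[word] == 0.0 and pos.mean_y[word] == 0.0
                continue
            r, c = kmer_cell_index(word, k)
            x, y = pos.mean_x[word], pos.mean_y[word]
            assert c / side < x < (c + 1) / side
            assert (side - 1 - r) / side < y < (side - r) / side


class TestOracleEquivalence:
    """Streaming scan vs brute-force prefix-materializing oracle."""

    def test_random_sequences_bit_for_bit(self):
        rng = np.random.default_rng(2024)
        for trial in range(100):
            k = int(rng.integers(1, 4))
            length = int(rng.integers(k, 201))
            residues = random_dna(rng, length, ambiguity=0.05 if trial % 3 == 0 else 0.0)
            seq_counts, seq_mx, seq_my = oracle_positions(residues, k)
            seq = GenomeSequence("s", residues)
            if sum(seq_counts.values()) == 0:
                continue
            table = count_kmers(seq, k)
            pos = kmer_average_positions(seq, k)
            for word in table.counts:
                assert table.counts[word] == seq_counts.get(word, 0)
                assert pos.mean_x[word] == seq_mx.get(word, 0.0)
                assert pos.mean_y[word] == seq_my.get(word, 0.0)


class TestTensor:
    def test_two_letter_sequence_single_cell(self):
        t = build_feature_tensor(GenomeSequence("s", "AC"), 2, normalize=False)
        r, c = kmer_cell_index("AC")
        assert t.f1[r, c] == 1
        # two midpoint steps from (0.5, 0.5): A then C
        assert (t.f2[r, c], t.f3[r, c]) == (0.125, 0.625)
        assert t.f1.sum() == 1

    def test_k7_grid_side_128(self):
        rng = np.random.default_rng(0)
        seq = GenomeSequence("s", random_dna(rng, 500))
        t = build_feature_tensor(seq, 7, normalize=False)
        assert t.data.shape == (3, 128, 128)

    @given(dna, st.integers(min_value=1, max_value=4))
    @settings(max_examples=40, derandomize=True)
    def test_zero_coupling(self, residues, k):
        # F2/F3 zero exactly where F1 is zero (absent word)
        if len(residues) < k:
            return
        t = build_feature_tensor(GenomeSequence("s", residues), k, normalize=False)
        absent = t.f1 == 0
        assert (t.f2[absent] == 0).all() and (t.f3[absent] == 0).all()
        present = ~absent
        assert (t.f2[present] > 0).all() and (t.f3[present] > 0).all()

    def test_corner_relabeling_reflects_coordinates(self):
        # Swapping the x/y role of every corner is a symmetry of the square
        # fixing the start point, so it transposes the grid and swaps the
        # mean-x and mean-y channels; counts are merely permuted.
        swapped = CornerAssignment(
            A=(0, 0), C=(1, 0), G=(1, 1), T=(0, 1)
        )  # mirror of the default across the diagonal y = x
        rng = np.random.default_rng(5)
        seq = GenomeSequence("s", random_dna(rng, 300))
        base = build_feature_tensor(seq, 3, normalize=False)
        refl = build_feature_tensor(seq, 3, corners=swapped, normalize=False)
        for word in ["ACG", "TTT", "GAT", "CCA"]:
            r1, c1 = kmer_cell_index(word, 3, DEFAULT_CORNERS)
            r2, c2 = kmer_cell_index(word, 3, swapped)
            assert base.f1[r1, c1] == refl.f1[r2, c2]
            assert base.f2[r1, c1] == refl.f3[r2, c2]
            assert base.f3[r1, c1] == refl.f2[r2, c2]
        assert sorted(base.f1.ravel()) == sorted(refl.f1.ravel())


class TestNormalization:
    def test_linear_rescale(self):
        seq = GenomeSequence("s", "ACGTACGTAAC")
        t = build_feature_tensor(seq, 2, normalize=False)
        n = minmax_normalize(t)
        for c in range(3):
            lo, hi = t.data[c].min(), t.data[c].max()
            assert np.array_equal(n.data[c], (t.data[c] - lo) / (hi - lo))
            assert n.data[c].min() == 0.0 and n.data[c].max() == 1.0

    def test_constant_channel_maps_to_zero(self):
        from cgrhost.features import FeatureTensor

        data = np.zeros((3, 2, 2))
        data[0] = 5.0  # constant
        data[1] = [[0, 1], [2, 3]]
        t = FeatureTensor(k=1, data=data, normalized=False)
        n = minmax_normalize(t)
        assert (n.data[0] == 0).all()
        assert n.data[1].tolist() == [[0, 1 / 3], [2 / 3, 1]]

    def test_double_normalization_rejected(self):
        seq = GenomeSequence("s", "ACGTAC")
        t = build_feature_tensor(seq, 2)
        with pytest.raises(ValueError):
            minmax_normalize(t)


class TestCornerAssignment:
    def test_non_bijective_rejected(self):
        with pytest.raises(ValueError):
            CornerAssignment(A=(0, 0), C=(0, 0), G=(1, 1), T=(1, 0))

    def test_lowercase_sequences_uppercased(self):
        t1 = build_feature_tensor(GenomeSequence("s", "acgtac"), 2, normalize=False)
        t2 = build_feature_tensor(GenomeSequence("s", "ACGTAC"), 2, normalize=False)
        assert np.array_equal(t1.data, t2.data)
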