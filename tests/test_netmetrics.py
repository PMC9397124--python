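"""Participation coefficient, within-module z, community medians, nodal extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painflow import (
    CommunityPartition,
    community_medians,
    extract_nodes,
    participation_coefficient,
    within_module_z,
)


def _partition(assignment):
    return CommunityPartition(
        node_labels=[f"n{i}" for i in range(len(assignment))],
        communities=np.asarray(assignment, dtype=object),
    )


def _random_symmetric(rng, n):
    W = rng.normal(size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


def pc_double_loop_oracle(W, partition):
    """Independent per-community strength summation, two explicit loops."""
    labels = partition.community_labels
    n = W.shape[0]
    pc = np.zeros(n)
    for i in range(n):
        k_is = {lab: 0.0 for lab in labels}
        for j in range(n):
            if i != j and np.isfinite(W[i, j]) and W[i, j] > 0:
                k_is[partition.communities[j]] += W[i, j]
        k = sum(k_is.values())
        if k > 0:
            pc[i] = 1.0 - sum((v / k) ** 2 for v in k_is.values())
    return pc


class TestParticipationCoefficient:
    def test_single_community_strength_gives_zero(self):
        part = _partition(["A", "A", "B", "B"])
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 2.0  # node 0's positive strength all within A
        W[0, 2] = W[2, 0] = -1.0  # negative edge must be discarded
        pc = participation_coefficient(W, part)
        assert pc[0] == pytest.approx(0.0, abs=1e-15)

    def test_uniform_spread_over_seven_communities(self):
        labels = list("ABCDEFG")
        # node 0 in A, one partner node in each of the 7 communities
        part = _partition(["A"] + labels)
        W = np.zeros((8, 8))
        for j in range(1, 8):
            W[0, j] = W[j, 0] = 1.0
        pc = participation_coefficient(W, part)
        assert pc[0] == pytest.approx(6.0 / 7.0, abs=1e-15)

    def test_matches_double_loop_oracle(self, rng):
        part = _partition([["A", "B", "C", "D"][i % 4] for i in range(20)])
        W = _random_symmetric(rng, 20)
        np.testing.assert_allclose(
            participation_coefficient(W, part), pc_double_loop_oracle(W, part),
            atol=1e-12,
        )

    def test_isolated_node_gets_zero(self):
        part = _partition(["A", "A", "B"])
        W = np.zeros((3, 3))
        W[1, 2] = W[2, 1] = 1.0
        assert participation_coefficient(W, part)[0] == 0.0

    def test_bounds_and_asymmetry_rejection(self, rng):
        part = _partition([["A", "B", "C"][i % 3] for i in range(12)])
        for _ in range(5):
            W = _random_symmetric(rng, 12)
            pc = participation_coefficient(W, part)
            assert (pc >= 0).all() and (pc <= 1 - 1 / 3 + 1e-12).all()
        W = _random_symmetric(rng, 12)
        W[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            participation_coefficient(W, part)

    def test_community_relabelling_invariance(self, rng):
        assignment = [["A", "B", "C"][i % 3] for i in range(9)]
        renamed = [{"A": "Z", "B": "Y", "C": "X"}[a] for a in assignment]
        W = _random_symmetric(rng, 9)
        np.testing.assert_allclose(
            participation_coefficient(W, _partition(assignment)),
            participation_coefficient(W, _partition(renamed)),
            atol=1e-14,
        )

    def test_concentration_lowers_pc(self):
        # moving strength from an even two-community split into one community
        part = _partition(["A", "A", "B", "B"])
        even = np.zeros((4, 4))
        even[0, 1] = even[1, 0] = 1.0
        even[0, 2] = even[2, 0] = 1.0
        conc = even.copy()
        conc[0, 1] = conc[1, 0] = 1.9
        conc[0, 2] = conc[2, 0] = 0.1
        assert (
            participation_coefficient(conc, part)[0]
            < participation_coefficient(even, part)[0]
        )


class TestWithinModuleZ:
    def test_three_node_community_closed_form(self):
        # within-community strengths {1, 2, 3} -> z = (k - 2) / popstd({1,2,3})
        part = _partition(["A", "A", "A", "B", "B"])
        W = np.zeros((5, 5))
        # strengths inside A: node0 = 0+1 = 1, node1 = 0+2 = 2, node2 = 1+2 = 3
        W[0, 2] = W[2, 0] = 1.0
        W[1, 2] = W[2, 1] = 2.0
        W[2, 3] = W[3, 2] = 4.0  # crosses into B: must not count
        W[3, 4] = W[4, 3] = 1.0
        z = within_module_z(W, part)
        sd = np.sqrt(2.0 / 3.0)  # population SD of {1, 2, 3}
        np.testing.assert_allclose(z[:3], [-1 / sd, 0.0, 1 / sd], atol=1e-12)
        np.testing.assert_allclose(z[:3], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_identical_within_strengths_give_zero(self):
        part = _partition(["A", "A", "A", "B"])
        W = np.full((4, 4), 2.0)
        np.fill_diagonal(W, 0.0)
        np.testing.assert_array_equal(within_module_z(W, part)[:3], 0.0)

    def test_community_mean_zero_at_every_tr(self, rng):
        part = _partition([["A", "B", "C"][i % 3] for i in range(15)])
        W = rng.normal(size=(20, 15, 15))
        W = (W + W.transpose(0, 2, 1)) / 2
        z = within_module_z(W, part)
        for lab in part.community_labels:
            members = part.communities == lab
            np.testing.assert_allclose(z[:, members].mean(axis=1), 0.0, atol=1e-8)

    def test_singleton_community_zero_not_fatal(self, rng):
        part = _partition(["A", "A", "B"])
        W = _random_symmetric(rng, 3)
        z = within_module_z(W, part)
        assert z[2] == 0.0

    def test_signed_mode_keeps_negative_edges(self):
        part = _partition(["A", "A", "A", "B"])
        W = np.zeros((4, 4))
        W[:3, :3] = [[0.0, -1.0, 1.0], [-1.0, 0.0, 0.5], [1.0, 0.5, 0.0]]
        z_pos = within_module_z(W, part, signed=False)
        z_signed = within_module_z(W, part, signed=True)
        assert not np.allclose(z_pos, z_signed)


class TestCommunityMedians:
    def test_single_node_community_median_is_value(self):
        part = _partition(["A", "B", "B"])
        vals = np.array([[0.3], [0.1], [0.9]])
        med, labels = community_medians(vals, part)
        assert med[labels.index("A"), 0] == pytest.approx(0.3)

    def test_odd_count_median(self):
        part = _partition(["A", "A", "A", "B"])
        med, _ = community_medians(np.array([[0.1], [0.5], [0.9], [0.0]]), part)
        assert med[0, 0] == pytest.approx(0.5)

    def test_matches_sort_and_pick_oracle(self, rng):
        part = _partition([["A", "B"][i % 2] for i in range(11)])
        vals = rng.normal(size=(11, 7))
        med, labels = community_medians(vals, part)
        for j, lab in enumerate(labels):
            block = vals[part.communities == lab]
            for t in range(7):
                s = np.sort(block[:, t])
                expected = (
                    s[len(s) // 2]
                    if len(s) % 2
                    else (s[len(s) // 2 - 1] + s[len(s) // 2]) / 2
                )
                assert med[j, t] == pytest.approx(expected, abs=1e-12)

    def test_undefined_values_ignored(self):
        part = _partition(["A", "A", "A", "B"])
        vals = np.array([[0.2], [np.nan], [0.6], [0.0]])
        med, _ = community_medians(vals, part)
        assert med[0, 0] == pytest.approx(0.4)


class TestExtractNodes:
    def test_six_requested_labels_give_six_series(self, rng):
        labels = [f"n{i}" for i in range(10)]
        vals = rng.normal(size=(10, 5))
        out, got = extract_nodes(vals, labels, labels[:6])
        assert out.shape == (6, 5) and got == labels[:6]

    def test_empty_request_is_empty_not_error(self, rng):
        out, got = extract_nodes(rng.normal(size=(3, 4)), ["a", "b", "c"], [])
        assert out.shape == (0, 4) and got == []

    def test_duplicate_label_collapses_with_warning(self, rng):
        with pytest.warns(UserWarning, match="duplicate"):
            out, got = extract_nodes(
                rng.normal(size=(3, 4)), ["a", "b", "c"], ["a", "a"]
            )
        assert got == ["a"] and out.shape == (1, 4)

    def test_unknown_label_lists_valid_ones(self, rng):
        with pytest.raises(ValueError, match="valid labels"):
            extract_nodes(rng.normal(size=(2, 2)), ["a", "b"], ["zz"])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_property_pc_bounds_and_z_mean_zero(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 16))
    n_comm = int(rng.integers(2, 5))
    part = _partition([f"C{i % n_comm}" for i in range(n)])
    W = rng.normal(size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    pc = participation_coefficient(W, part)
    assert (pc >= 0).all()
    assert (pc <= 1 - 1 / len(part.community_labels) + 1e-12).all()
    z = within_module_z(W, part)
    for lab in part.community_labels:
        assert abs(z[part.communities == lab].mean()) < 1e-8
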