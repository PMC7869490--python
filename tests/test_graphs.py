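"""Contact maps, edge schemes, adjacency normalization, structure contacts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactsol.features import NodeFeatureMatrix
from contactsol.graphs import (
    ContactMap,
    EdgeScheme,
    build_contact_graph,
    contact_map_from_structure,
    evaluate_contact_prediction,
    normalize_adjacency,
    parse_contact_map,
    read_ca_coordinates,
    top_pairs,
)
from conftest import random_symmetric_map


def features_for(L):
    return NodeFeatureMatrix(np.zeros((L, 3)), ("AAPHY7",))


class TestContactMap:
    def test_rejects_asymmetric(self):
        P = np.array([[0, 0.5], [0.4, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            ContactMap(P)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="0, 1"):
            ContactMap(np.full((2, 2), 1.5))

    def test_diagonal_forced_to_zero(self):
        cm = ContactMap(np.eye(3))
        assert np.all(np.diag(cm.P) == 0)


class TestEdgeSchemes:
    def test_alpha_zero_is_chain_only(self, rng):
        P = random_symmetric_map(rng, 5)
        g = build_contact_graph(ContactMap(P), features_for(5),
                                EdgeScheme(mode="topk", alpha=0.0))
        idx = np.arange(5)
        sep = np.abs(idx[:, None] - idx[None, :])
        expected = ((sep >= 1) & (sep <= 2)).astype(float)
        assert np.array_equal(g.A, expected)

    def test_full_mode_keeps_probabilities_and_forces_neighbors(self):
        # |i-j| <= 2 pairs are unconditionally weight 1 even when the
        # predicted probability is lower; beyond that the probability is kept
        P = np.zeros((4, 4))
        P[0, 3] = P[3, 0] = 0.4
        P[0, 2] = P[2, 0] = 0.1
        g = build_contact_graph(ContactMap(P), features_for(4), EdgeScheme(mode="full"))
        assert g.A[0, 3] == 0.4
        assert g.A[0, 2] == 1.0
        assert g.A[0, 1] == g.A[1, 2] == g.A[2, 3] == 1.0
        assert np.all(np.diag(g.A) == 0)

    @pytest.mark.parametrize("L,alpha", [(6, 1.0), (20, 2.0), (50, 3.5), (15, 0.4)])
    def test_topk_matches_brute_force_sort(self, rng, L, alpha):
        P = random_symmetric_map(rng, L)
        g = build_contact_graph(ContactMap(P), features_for(L),
                                EdgeScheme(mode="topk", alpha=alpha))
        # independent oracle: exhaustive sort over all eligible pairs
        eligible = [(P[i, j], i, j) for i in range(L) for j in range(i + 1, L)
                    if j - i > 2]
        eligible.sort(key=lambda t: (-t[0], t[1], t[2]))
        budget = int(np.floor(alpha * L))
        kept = {(i, j) for _, i, j in eligible[:budget]}
        got = {(i, j) for i in range(L) for j in range(i + 1, L)
               if j - i > 2 and g.A[i, j] > 0}
        assert got == kept
        for i, j in kept:
            assert g.A[i, j] == P[i, j]  # continuous weighting

    def test_discrete_weighting_sets_unit_edges(self, rng):
        L = 12
        P = random_symmetric_map(rng, L)
        g = build_contact_graph(ContactMap(P), features_for(L),
                                EdgeScheme(mode="topk", alpha=1.0,
                                           weighting="discrete"))
        off = g.A[np.triu_indices(L, 3)]
        assert set(np.unique(off)) <= {0.0, 1.0}
        assert np.sum(off == 1.0) == L  # floor(1*L) kept pairs

    def test_edge_count_monotone_and_saturating(self, rng):
        L = 20
        P = random_symmetric_map(rng, L)
        counts = []
        for alpha in [0, 1, 2, 4, 7, 100]:
            g = build_contact_graph(ContactMap(P), features_for(L),
                                    EdgeScheme(mode="topk", alpha=alpha))
            counts.append(int(np.sum(g.A[np.triu_indices(L, 1)] > 0)))
        assert counts == sorted(counts)
        assert counts[-1] == L * (L - 1) // 2  # saturated: fully connected

    def test_permutation_equivariance_off_chain(self, rng):
        # The chain-neighbor rule depends on sequence position, so full
        # equivariance holds for permutations applied after construction
        # (graph isomorphism); at pairs that are non-neighbors both before
        # and after relabeling, construction itself commutes with the
        # permutation.
        L = 15
        P = random_symmetric_map(rng, L)
        X = NodeFeatureMatrix(rng.normal(size=(L, 4)), ("AAPHY7",))
        scheme = EdgeScheme(mode="full")
        A = build_contact_graph(ContactMap(P), X, scheme).A
        perm = rng.permutation(L)
        P_perm = P[np.ix_(perm, perm)]
        X_perm = NodeFeatureMatrix(X.X[perm], ("AAPHY7",))
        A_perm = build_contact_graph(ContactMap(P_perm), X_perm, scheme).A
        A_relabelled = A[np.ix_(perm, perm)]
        for a in range(L):
            for b in range(L):
                i, j = perm[a], perm[b]
                if abs(i - j) > 2 and abs(a - b) > 2:
                    assert A_perm[a, b] == A_relabelled[a, b]

    def test_length_mismatch_rejected(self, rng):
        P = random_symmetric_map(rng, 5)
        with pytest.raises(ValueError, match="residues"):
            build_contact_graph(ContactMap(P), features_for(4), EdgeScheme())


class TestNormalizeAdjacency:
    def test_empty_graph_gives_identity(self):
        assert np.allclose(normalize_adjacency(np.zeros((3, 3))), np.eye(3))

    def test_hand_computed_two_nodes(self):
        A = np.array([[0, 0.5], [0.5, 0]])
        expected = np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]])
        assert np.allclose(normalize_adjacency(A), expected)

    @given(L=st.integers(2, 50), seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_rows_sum_to_one_property(self, L, seed):
        A = random_symmetric_map(np.random.default_rng(seed), L)
        A_hat = normalize_adjacency(A)
        assert np.allclose(A_hat.sum(axis=1), 1.0, atol=1e-9)
        assert A_hat.min() >= 0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            normalize_adjacency(np.array([[0, -1.0], [-1.0, 0]]))


class TestStructureContacts:
    def test_hand_computed_chain(self):
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        cm = contact_map_from_structure(coords, cutoff=7.5)
        # d(1,3) = 7.6 >= 7.5: strict inequality excludes it
        assert cm.P[0, 1] == cm.P[1, 2] == 1
        assert cm.P[0, 2] == 0

    def test_far_apart_no_contacts(self):
        cm = contact_map_from_structure(np.array([[0, 0, 0], [10, 0, 0]]))
        assert np.all(cm.P == 0)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            contact_map_from_structure(np.array([[0, 0, 0.0]]))

    def test_contact_count_matches_brute_force(self, spec):
        from contactsol.synthetic import generate_conformation
        coords = generate_conformation(40, spec, seed=3)
        cm = contact_map_from_structure(coords, cutoff=7.5)
        n_pairs = 0
        for i in range(40):
            for j in range(i + 1, 40):
                if np.linalg.norm(coords[i] - coords[j]) < 7.5:
                    n_pairs += 1
        assert int(cm.P[np.triu_indices(40, 1)].sum()) == n_pairs


class TestContactEvaluation:
    def test_perfect_prediction(self):
        actual = contact_map_from_structure(
            np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]))
        pairs = [(0, 1), (1, 2)]
        assert evaluate_contact_prediction(pairs, actual) == (1.0, 1.0)

    def test_half_right(self):
        P = np.zeros((5, 5))
        for i, j in [(0, 2), (1, 4)]:
            P[i, j] = P[j, i] = 1
        precision, recall = evaluate_contact_prediction(
            [(0, 2), (0, 3)], ContactMap(P))
        assert precision == 0.5 and recall == 0.5

    def test_empty_prediction_warns(self):
        P = np.zeros((3, 3))
        P[0, 2] = P[2, 0] = 1
        with pytest.warns(UserWarning, match="empty"):
            precision, recall = evaluate_contact_prediction([], ContactMap(P))
        assert precision == 0.0


class TestReaders:
    def test_dense_round_trip(self, rng):
        P = np.round(random_symmetric_map(rng, 6), 6)
        text = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in P)
        assert np.allclose(parse_contact_map(text).P, P, atol=1e-9)

    def test_triplet_round_trip(self, protein):
        cm = parse_contact_map(protein.file_texts["contacts"],
                               length=protein.length)
        assert np.allclose(cm.P, protein.predicted_map.P, atol=1e-6)

    def test_casp_rr_records_with_header(self):
        text = (
            "PFRMAT RR\nTARGET T0999\nMODEL 1\n"
            "1 5 0 8 0.93\n2 6 0 8 0.40\nEND\n"
        )
        cm = parse_contact_map(text, length=6)
        assert cm.P[0, 4] == 0.93 and cm.P[4, 0] == 0.93
        assert cm.P[1, 5] == 0.40

    def test_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            parse_contact_map("1 9 0.5\n", length=5)

    def test_pdb_ca_trace_first_model_single_chain(self):
        def atom(serial, name, chain, resi, x):
            return (f"ATOM  {serial:5d}  {name:<3s} ALA {chain}{resi:4d}    "
                    f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
        pdb = "\n".join([
            "MODEL     1",
            atom(1, "N", "A", 1, 0.0),
            atom(2, "CA", "A", 1, 1.0),
            atom(3, "CA", "A", 2, 4.8),
            atom(4, "CA", "B", 1, 99.0),
            "ENDMDL",
            "MODEL     2",
            atom(5, "CA", "A", 1, 50.0),
            "ENDMDL",
            "END",
        ])
        coords = read_ca_coordinates(pdb)  # first chain, first model
        assert coords.shape == (2, 3)
        assert coords[:, 0].tolist() == [1.0, 4.8]
        coords_b = read_ca_coordinates(pdb, chain="B")
        assert coords_b[:, 0].tolist() == [99.0]
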