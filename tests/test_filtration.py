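"""Graph filtration: MST, barcode, single linkage, slope — against oracles."""

import numpy as np
import pytest

from conftest import (
    all_spanning_trees_min_weight,
    barcode_by_edge_sweep,
    is_ultrametric,
    minimax_exhaustive_paths,
    minimax_floyd_warshall,
    random_distance_matrix,
)
from topoconn import (
    Barcode,
    DistanceMatrix,
    barcode,
    barcode_slope,
    minimum_spanning_tree,
    single_linkage,
)


class TestWorkedExample:
    """The 4-node network with distances 0.1 .. 0.9 (hand-checkable)."""

    def test_mst_edges(self, four_node_dm):
        mst = minimum_spanning_tree(four_node_dm)
        assert mst == [(0, 1, 0.1), (1, 2, 0.3), (2, 3, 0.4)]
        # exhaustive enumeration over all 3-edge subsets agrees on weight
        assert sum(w for *_, w in mst) == pytest.approx(
            all_spanning_trees_min_weight(four_node_dm)
        )

    def test_barcode_events(self, four_node_dm):
        bc = barcode(four_node_dm)
        assert bc.merge_events == ((0.1, 3), (0.3, 2), (0.4, 1))
        assert bc.n_components(0.0) == 4
        assert bc.n_components(0.35) == 2
        assert bc.n_components(1.0) == 1

    def test_single_linkage_matrix(self, four_node_dm):
        _, slm = single_linkage(four_node_dm)
        expected = np.array(
            [
                [0.0, 0.1, 0.3, 0.4],
                [0.1, 0.0, 0.3, 0.4],
                [0.3, 0.3, 0.0, 0.4],
                [0.4, 0.4, 0.4, 0.0],
            ]
        )
        np.testing.assert_array_equal(slm.values, expected)
        np.testing.assert_array_equal(
            slm.values, minimax_exhaustive_paths(four_node_dm)
        )

    def test_dendrogram_heights_match_barcode(self, four_node_dm):
        dendro, _ = single_linkage(four_node_dm)
        heights = [h for *_, h in dendro.merges]
        assert heights == [0.1, 0.3, 0.4]
        newick = dendro.to_newick()
        assert newick.endswith(";") and all(
            lab in newick for lab in "ABCD"
        )

    def test_slope_closed_form(self, four_node_dm):
        # OLS on (0.1,3),(0.3,2),(0.4,1): slope = -0.3/(7/150) = -45/7
        res = barcode_slope(barcode(four_node_dm), n_range=(1, 3))
        assert res.slope == pytest.approx(-45 / 7, rel=1e-12)
        assert res.n_points_used == 3


class TestSmallCases:
    def test_two_nodes(self):
        dm = DistanceMatrix(
            values=np.array([[0.0, 0.6], [0.6, 0.0]]), roi_labels=("A", "B")
        )
        assert minimum_spanning_tree(dm) == [(0, 1, 0.6)]
        _, slm = single_linkage(dm)
        np.testing.assert_array_equal(slm.values, dm.values)

    def test_all_equal_distances(self):
        p, d = 5, 0.42
        vals = np.full((p, p), d)
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(values=vals, roi_labels=tuple("ABCDE"))
        mst = minimum_spanning_tree(dm)
        assert sum(w for *_, w in mst) == pytest.approx((p - 1) * d)
        bc = barcode(dm)
        assert bc.n_components(d - 1e-9) == p
        assert bc.n_components(d) == 1

    def test_ultrametric_input_is_fixed_point(self):
        rng = np.random.default_rng(7)
        dm = random_distance_matrix(rng, 6)
        _, slm = single_linkage(dm)
        ultra = DistanceMatrix(values=slm.values, roi_labels=dm.roi_labels)
        _, slm2 = single_linkage(ultra)
        np.testing.assert_array_equal(slm2.values, slm.values)


@pytest.mark.parametrize("p", [3, 5, 8])
def test_barcode_and_slm_match_oracles(p):
    """MST route == all-edge union-find sweep and minimax DP, exactly."""
    rng = np.random.default_rng(100 + p)
    for _ in range(50):
        dm = random_distance_matrix(rng, p)
        bc = barcode(dm)
        assert list(bc.merge_events) == barcode_by_edge_sweep(dm)
        _, slm = single_linkage(dm)
        np.testing.assert_array_equal(slm.values, minimax_floyd_warshall(dm))


def test_slm_matches_exhaustive_path_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(10):
        dm = random_distance_matrix(rng, 6)
        _, slm = single_linkage(dm)
        np.testing.assert_array_equal(slm.values, minimax_exhaustive_paths(dm))


def test_slm_matches_scipy_single_linkage():
    """Cross-check against scipy's cophenetic distances (independent code)."""
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(21)
    for p in (5, 10, 20):
        dm = random_distance_matrix(rng, p)
        _, slm = single_linkage(dm)
        z = linkage(squareform(dm.values), method="single")
        np.testing.assert_allclose(
            squareform(slm.values), cophenet(z), atol=1e-12
        )


def test_slm_properties_on_random_inputs():
    """Ultrametricity, SLM <= input, equality iff input ultrametric."""
    rng = np.random.default_rng(33)
    for _ in range(50):
        p = int(rng.integers(3, 9))
        dm = random_distance_matrix(rng, p)
        _, slm = single_linkage(dm)
        assert is_ultrametric(slm.values)
        assert np.all(slm.values <= dm.values + 1e-12)
        equal = np.array_equal(slm.values, dm.values)
        assert equal == is_ultrametric(dm.values)


def test_tie_handling_is_permutation_equivariant():
    """With many tied weights, SLM/barcode depend only on the weighted graph."""
    rng = np.random.default_rng(55)
    for _ in range(20):
        p = 7
        dm = random_distance_matrix(rng, p, ties=True)
        perm = rng.permutation(p)
        dm_p = DistanceMatrix(
            values=dm.values[np.ix_(perm, perm)],
            roi_labels=tuple(dm.roi_labels[i] for i in perm),
        )
        assert list(barcode(dm).merge_events) == list(barcode(dm_p).merge_events)
        _, slm = single_linkage(dm)
        _, slm_p = single_linkage(dm_p)
        np.testing.assert_array_equal(
            slm_p.values, slm.values[np.ix_(perm, perm)]
        )


class TestBarcodeSlope:
    def test_exact_line_recovered(self):
        # events on N = 70 - 100 eps within the window
        events = tuple(
            ((70 - n) / 100.0, n) for n in range(69, 0, -1)
        )
        bc = Barcode(n_nodes=70, merge_events=events)
        res = barcode_slope(bc, n_range=(11, 66))
        assert res.slope == pytest.approx(-100.0, rel=1e-9)
        assert res.intercept == pytest.approx(70.0, rel=1e-9)
        assert res.n_points_used == 56

    def test_grid_sampling_on_exact_line(self):
        events = tuple(((70 - n) / 100.0, n) for n in range(69, 0, -1))
        bc = Barcode(n_nodes=70, merge_events=events)
        res = barcode_slope(bc, n_range=(11, 66), grid=200)
        # a right-continuous step function sampled densely stays near the line
        assert res.slope == pytest.approx(-100.0, rel=0.05)

    def test_single_in_window_event_errors(self, four_node_dm):
        bc = barcode(four_node_dm)
        with pytest.raises(ValueError, match="at least 2"):
            barcode_slope(bc, n_range=(3, 4))

    def test_zero_epsilon_variance_errors(self):
        bc = Barcode(n_nodes=4, merge_events=((0.5, 3), (0.5, 2), (0.5, 1)))
        with pytest.raises(ValueError, match="zero variance"):
            barcode_slope(bc, n_range=(1, 3))

    def test_bad_window_rejected(self, four_node_dm):
        with pytest.raises(ValueError, match="low"):
            barcode_slope(barcode(four_node_dm), n_range=(3, 3))

    def test_slope_negative_on_random_barcodes(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            dm = random_distance_matrix(rng, 12)
            res = barcode_slope(barcode(dm), n_range=(2, 11))
            assert res.slope < 0
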