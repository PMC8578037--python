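"""Association matrices and density thresholding."""

import numpy as np
import pytest

from subscn import (
    association_matrix,
    binarize_at_density,
    build_sweep,
    default_density_grid,
    minimum_connected_density,
)
from subscn.network import AssociationMatrix, NetworkError


def _assoc_from_matrix(r):
    r = np.asarray(r, float)
    return AssociationMatrix(r, [f"n{i}" for i in range(len(r))])


class TestAssociationMatrix:
    def test_duplicated_rois_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (30, 3))
        x = np.column_stack([x, x[:, 0]])  # node 3 duplicates node 0
        assoc = association_matrix(x)
        assert assoc.r[0, 3] == pytest.approx(1.0)

    def test_independent_noise_stays_weak(self):
        rng = np.random.default_rng(1)
        assoc = association_matrix(rng.normal(0, 1, (1000, 10)))
        off = np.abs(assoc.r[np.triu_indices(10, 1)])
        assert off.max() < 0.15

    def test_matches_textbook_formula(self):
        # hand-entered 6-participant x 5-ROI table; oracle is the explicit
        # sum-based Pearson formula
        x = np.array(
            [[4.0, 7.1, 1.2, 9.0, 3.3],
             [5.5, 6.2, 2.1, 8.1, 2.9],
             [6.1, 5.0, 3.3, 7.7, 4.4],
             [4.9, 6.8, 2.8, 8.8, 3.1],
             [5.2, 5.9, 1.9, 9.4, 3.8],
             [6.6, 4.8, 3.1, 7.2, 2.6]]
        )
        assoc = association_matrix(x)
        n = x.shape[0]
        for i in range(5):
            for j in range(i + 1, 5):
                sx, sy = x[:, i], x[:, j]
                num = (sx * sy).sum() - sx.sum() * sy.sum() / n
                den = np.sqrt(
                    ((sx**2).sum() - sx.sum() ** 2 / n)
                    * ((sy**2).sum() - sy.sum() ** 2 / n)
                )
                assert assoc.r[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_roi_named(self):
        x = np.ones((10, 3))
        x[:, 0] = np.arange(10)
        x[:, 2] = np.arange(10) ** 2
        with pytest.raises(NetworkError, match="node1"):
            association_matrix(x)

    def test_asymmetric_matrix_rejected(self):
        r = np.zeros((3, 3))
        r[0, 1] = 0.5
        with pytest.raises(NetworkError, match="symmetric"):
            _assoc_from_matrix(r)


class TestBinarize:
    def test_full_density_gives_complete_graph(self):
        rng = np.random.default_rng(2)
        assoc = association_matrix(rng.normal(0, 1, (20, 12)))
        net = binarize_at_density(assoc, 1.0)
        assert net.n_edges == 12 * 11 // 2

    def test_top_half_of_four_nodes_by_brute_force(self):
        r = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.1, (0, 3): 0.5,
                (1, 2): 0.7, (1, 3): -0.2, (2, 3): 0.3}
        for (i, j), v in vals.items():
            r[i, j] = r[j, i] = v
        net = binarize_at_density(_assoc_from_matrix(r), 0.5)
        expected = sorted(vals, key=vals.get, reverse=True)[:3]
        got = {(i, j) for i in range(4) for j in range(i + 1, 4)
               if net.adjacency[i, j]}
        assert got == set(expected)

    def test_edge_sets_nest_across_densities(self):
        rng = np.random.default_rng(3)
        assoc = association_matrix(rng.normal(0, 1, (40, 15)))
        prev = None
        for d in (0.1, 0.2, 0.35, 0.6, 0.9):
            a = binarize_at_density(assoc, d).adjacency
            if prev is not None:
                assert np.all(prev <= a)
            prev = a

    def test_achieved_density_within_one_pair(self):
        rng = np.random.default_rng(4)
        assoc = association_matrix(rng.normal(0, 1, (40, 15)))
        m = 15 * 14 / 2
        for d in (0.17, 0.3, 0.45):
            net = binarize_at_density(assoc, d)
            assert abs(net.density - d) <= 1 / m

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        assoc = association_matrix(rng.normal(0, 1, (40, 10)))
        warped = _assoc_from_matrix(np.tanh(3.0 * assoc.r))
        for d in (0.2, 0.5):
            a = binarize_at_density(assoc, d).adjacency
            b = binarize_at_density(warped, d).adjacency
            np.testing.assert_array_equal(a, b)

    def test_absolute_ranking_keeps_strong_negatives(self):
        r = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.1, (0, 3): 0.5,
                (1, 2): 0.7, (1, 3): -0.95, (2, 3): 0.3}
        for (i, j), v in vals.items():
            r[i, j] = r[j, i] = v
        assoc = _assoc_from_matrix(r)
        signed = binarize_at_density(assoc, 0.5).adjacency
        absolute = binarize_at_density(assoc, 0.5, rank_by="absolute").adjacency
        assert signed[1, 3] == 0      # strong negative excluded by signed ranking
        assert absolute[1, 3] == 1    # included when ranking by |r|

    def test_zero_edge_density_rejected(self):
        rng = np.random.default_rng(6)
        assoc = association_matrix(rng.normal(0, 1, (20, 10)))
        with pytest.raises(NetworkError):
            binarize_at_density(assoc, 0.001)


class TestMinimumConnectedDensity:
    def test_isolated_node_joins_last(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (200, 8))
        shared = rng.normal(0, 1, 200)
        x[:, :7] += 2.0 * shared[:, None]      # 7 tightly covarying nodes
        assoc = association_matrix(x)
        assert minimum_connected_density(assoc) > 0.2

    def test_grid_refinement_monotone(self):
        rng = np.random.default_rng(8)
        assoc = association_matrix(rng.normal(0, 1, (60, 12)))
        coarse = minimum_connected_density(assoc, grid_step=0.01)
        fine = minimum_connected_density(assoc, grid_step=0.001)
        assert coarse >= fine
        assert coarse - fine < 0.01

    def test_paperlike_control_connects_in_analyzed_range(self):
        """Seven-module control cohorts reach one component by the bottom
        of the analyzed density range (median over seeds)."""
        from subscn import generate_cohort, paperlike_spec, residualize

        dmins = []
        for s in range(3):
            spec = paperlike_spec(seed=s)
            _, table = generate_cohort(spec)
            res = residualize(table.select_groups(["HC"]), "pooled_all")
            dmins.append(minimum_connected_density(association_matrix(res, "HC")))
        assert np.median(dmins) <= 0.17 + 1e-9


class TestBuildSweep:
    def test_default_grid_is_fifteen_densities(self):
        grid = default_density_grid()
        assert len(grid) == 15
        np.testing.assert_allclose(grid, 0.17 + 0.02 * np.arange(15))

    def test_single_density_sweep(self):
        rng = np.random.default_rng(9)
        assoc = association_matrix(rng.normal(0, 1, (40, 10)))
        sweep = build_sweep(assoc, d_min=0.3, d_max=0.3)
        assert len(sweep) == 1

    def test_sweep_nestedness(self, tiny_residuals):
        assoc = association_matrix(tiny_residuals, "HC")
        sweep = build_sweep(assoc)
        for a, b in zip(sweep.networks[:-1], sweep.networks[1:]):
            assert np.all(a.adjacency <= b.adjacency)

    def test_disconnected_densities_flagged_not_fatal(self):
        rng = np.random.default_rng(10)
        assoc = association_matrix(rng.normal(0, 1, (20, 20)))
        sweep = build_sweep(assoc, d_min=0.05, d_max=0.15, step=0.05)
        assert isinstance(sweep.flagged, list)
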