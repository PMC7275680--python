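import numpy as np
import pytest

from fenclone.io_formats import PlotCoordinates
from fenclone.mem_spatial import (MEMBasis, SpatialWeights, adjusted_r2,
                                  candidate_weights, detrend,
                                  euclidean_distances, mem_basis, moran_i,
                                  select_swm, significant_mems)


def coords_from(pts):
    return [PlotCoordinates(f"{i:02d}", float(x), float(y))
            for i, (x, y) in enumerate(pts)]


@pytest.fixture(scope="module")
def grid16():
    """A slightly jittered 4x4 grid of 16 plots."""
    rng = np.random.default_rng(5)
    pts = [(10.0 * i + rng.uniform(-1, 1), 10.0 * j + rng.uniform(-1, 1))
           for i in range(4) for j in range(4)]
    return coords_from(pts)


class TestDistances:
    def test_right_triangle(self):
        d = euclidean_distances(coords_from([(0, 0), (3, 0), (3, 4)]))
        off = sorted(d[np.triu_indices(3, 1)])
        assert off == pytest.approx([3.0, 4.0, 5.0])

    def test_isometry_invariance(self):
        pts = np.random.default_rng(0).uniform(0, 10, (8, 2))
        d1 = euclidean_distances(coords_from(pts))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        d2 = euclidean_distances(coords_from(pts @ R.T + [100, -40]))
        assert np.allclose(d1, d2)

    def test_matches_pairwise_recomputation(self):
        pts = np.random.default_rng(1).uniform(0, 50, (10, 2))
        d = euclidean_distances(coords_from(pts))
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(
                    np.hypot(*(pts[i] - pts[j])), abs=1e-12)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distances(coords_from([(0, 0), (0, 0), (1, 1)]))


class TestCandidateGrid:
    def test_default_grid_size_for_16_plots(self, grid16):
        d = euclidean_distances(grid16)
        cands = candidate_weights(d)
        assert len(cands) == 10 * 3 + 8  # threshold sweep x 3 weightings + kNN

    def test_all_candidates_valid(self, grid16):
        d = euclidean_distances(grid16)
        for c in candidate_weights(d):
            assert np.allclose(c.W, c.W.T)
            assert np.all(np.diag(c.W) == 0)
            assert np.all(c.W >= 0)

    def test_threshold_graphs_connected(self, grid16):
        d = euclidean_distances(grid16)
        for c in candidate_weights(d, knn=False):
            assert c.connected


class TestMEMBasis:
    def test_eigenvectors_zero_mean_orthonormal(self, grid16):
        d = euclidean_distances(grid16)
        for cand in candidate_weights(d)[:5]:
            basis = mem_basis(cand)
            assert np.all(np.abs(basis.vectors.mean(axis=0)) < 1e-10)
            gram = basis.vectors.T @ basis.vectors
            assert np.allclose(gram, np.eye(basis.n_mems), atol=1e-8)

    def test_moran_eigenvalue_identity(self, grid16):
        """Moran's I of each MEM equals (n / sum W) * its eigenvalue."""
        d = euclidean_distances(grid16)
        cand = candidate_weights(d)[0]
        basis = mem_basis(cand)
        scale = len(grid16) / cand.W.sum()
        for k in range(basis.n_mems):
            assert moran_i(basis.vectors[:, k], cand) == pytest.approx(
                scale * basis.values[k], abs=1e-8)

    def test_ring_graph_matches_dense_eigendecomposition(self):
        n = 4
        W = np.zeros((n, n))
        for i in range(n):
            W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
        sw = SpatialWeights(W, "ring4")
        basis = mem_basis(sw)
        H = np.eye(n) - np.ones((n, n)) / n
        ref = np.sort(np.linalg.eigvalsh(H @ W @ H))[::-1]
        ref = ref[np.abs(ref) > 1e-9 * np.abs(ref).max()]
        assert np.allclose(np.sort(basis.values), np.sort(ref), atol=1e-10)
        # centering removes the ring's constant eigenvector (lambda = +2);
        # what survives is the alternating checkerboard mode at -2
        assert np.allclose(basis.values, [-2.0], atol=1e-10)
        assert np.allclose(np.abs(basis.vectors[:, 0]), 0.5, atol=1e-10)

    def test_binary_mems_invariant_to_coordinate_scaling(self, grid16):
        d = euclidean_distances(grid16)
        b1 = mem_basis(candidate_weights(d, knn=False)[0])
        b2 = mem_basis(candidate_weights(3.7 * d, knn=False)[0])
        assert np.allclose(b1.vectors, b2.vectors, atol=1e-10)

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ValueError):
            SpatialWeights(np.zeros((4, 4)), "empty")


class TestMoranI:
    def test_permutation_null_expectation(self, grid16):
        d = euclidean_distances(grid16)
        cand = candidate_weights(d)[0]
        rng = np.random.default_rng(2)
        x = rng.standard_normal(16)
        vals = [moran_i(rng.permutation(x), cand) for _ in range(3000)]
        assert np.mean(vals) == pytest.approx(-1 / 15, abs=0.01)

    def test_checkerboard_negative(self):
        # 4-ring with alternating values: perfect negative autocorrelation
        W = np.zeros((4, 4))
        for i in range(4):
            W[i, (i + 1) % 4] = W[(i + 1) % 4, i] = 1.0
        assert moran_i(np.array([1.0, -1.0, 1.0, -1.0]),
                       SpatialWeights(W, "ring")) < 0

    def test_constant_vector_rejected(self, grid16):
        d = euclidean_distances(grid16)
        with pytest.raises(ValueError):
            moran_i(np.ones(16), candidate_weights(d)[0])


class TestSWMSelection:
    def test_adjusted_r2_arithmetic(self):
        assert adjusted_r2(0.5, 16, 1) == pytest.approx(0.4643, abs=1e-4)

    def test_single_candidate_returned(self, grid16):
        d = euclidean_distances(grid16)
        cand = candidate_weights(d, knn=False)[:1]
        rng = np.random.default_rng(0)
        chosen, basis, diag = select_swm(rng.standard_normal((16, 2)), cand)
        assert chosen is cand[0]
        assert diag[0]["chosen"]

    def test_planted_signal_recovers_its_candidate(self, grid16):
        d = euclidean_distances(grid16)
        cands = candidate_weights(d)
        target = cands[3]
        v1 = mem_basis(target).positive().vectors[:, 0]
        rng = np.random.default_rng(1)
        y = v1 + 0.01 * rng.standard_normal(16)
        chosen, _, _ = select_swm(y[:, None], cands)
        # the target SWM's own first MEM must be (near-)perfectly explained
        basis = mem_basis(chosen)
        from fenclone.mem_spatial import _ols_r2
        assert _ols_r2(y, basis.positive().vectors) > 0.98


class TestForwardSelection:
    def test_planted_mem_selected(self, grid16):
        d = euclidean_distances(grid16)
        basis = mem_basis(candidate_weights(d, knn=False)[0])
        pos = np.flatnonzero(basis.values > 0)
        k = pos[1]
        rng = np.random.default_rng(4)
        y = 3.0 * basis.vectors[:, k] + 0.05 * rng.standard_normal(16)
        sel, pvals = significant_mems(y, basis, nperm=199, seed=9)
        assert k in sel
        assert pvals[k] <= 0.05

    def test_alpha_zero_selects_nothing(self, grid16):
        d = euclidean_distances(grid16)
        basis = mem_basis(candidate_weights(d, knn=False)[0])
        y = np.random.default_rng(0).standard_normal(16)
        sel, _ = significant_mems(y, basis, alpha=0.0, nperm=99, seed=1)
        assert sel == []

    def test_white_noise_mostly_unselected(self, grid16):
        """Under the null the first permutation test rejects at ~alpha, so
        the selection is empty in the large majority of replicates."""
        d = euclidean_distances(grid16)
        basis = mem_basis(candidate_weights(d, knn=False)[0])
        rng = np.random.default_rng(6)
        empty = sum(
            significant_mems(rng.standard_normal(16), basis, nperm=99,
                             seed=int(rng.integers(2 ** 31)))[0] == []
            for _ in range(20)
        )
        # ranking by marginal R^2 before testing inflates the nominal 5%
        # somewhat; demand a clear majority rather than 1 - alpha
        assert empty >= 12


class TestDetrend:
    def test_empty_selection_is_passthrough(self):
        y = np.arange(5.0)
        basis = mem_basis(SpatialWeights(1.0 - np.eye(5), "complete"))
        res = detrend(y, basis, [])
        assert np.array_equal(res.residuals, y)

    def test_exact_fit_leaves_zero_residuals(self, grid16):
        d = euclidean_distances(grid16)
        basis = mem_basis(candidate_weights(d, knn=False)[0])
        y = 2.0 + 1.5 * basis.vectors[:, 0]
        res = detrend(y, basis, [0])
        assert np.all(np.abs(res.residuals) < 1e-10)
        assert res.r2 == pytest.approx(1.0)

    def test_residuals_orthogonal_to_selected(self, grid16):
        d = euclidean_distances(grid16)
        basis = mem_basis(candidate_weights(d, knn=False)[0])
        rng = np.random.default_rng(8)
        y = rng.standard_normal(16)
        res = detrend(y, basis, [0, 2, 3])
        for k in (0, 2, 3):
            assert abs(res.residuals @ basis.vectors[:, k]) < 1e-8

    def test_detrending_reduces_moran_i(self, grid16):
        """Removing selected MEMs lowers |Moran's I| of a spatially
        autocorrelated field."""
        d = euclidean_distances(grid16)
        cand = candidate_weights(d, knn=False)[0]
        basis = mem_basis(cand)
        rng = np.random.default_rng(10)
        reduced = selected = 0
        for _ in range(20):
            y = (2.0 * basis.vectors[:, 0] + 1.0 * basis.vectors[:, 1]
                 + 0.3 * rng.standard_normal(16))
            sel, _ = significant_mems(y, basis, nperm=99,
                                      seed=int(rng.integers(2 ** 31)))
            if not sel:
                continue
            selected += 1
            res = detrend(y, basis, sel)
            if abs(moran_i(res.residuals, cand)) <= abs(moran_i(y, cand)):
                reduced += 1
        assert selected >= 15          # the planted signal is found
        assert reduced == selected     # and detrending never increases |I|
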