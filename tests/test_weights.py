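import numpy as np
import pytest

import gwcrash as gw
from gwcrash import GWCrashError, KernelSpec


class TestContiguity:
    def test_queen_2x2_grid_each_unit_has_three_neighbours(self):
        units = gw.generate_lattice(2, 1.0, seed=0)
        wm = gw.contiguity_weights(units, "queen")
        assert list(wm.cardinalities()) == [3, 3, 3, 3]

    def test_rook_2x2_grid_excludes_corner_pairs(self):
        units = gw.generate_lattice(2, 1.0, seed=0)
        wm = gw.contiguity_weights(units, "rook")
        assert list(wm.cardinalities()) == [2, 2, 2, 2]
        # diagonal pairs (0,3) and (1,2) touch only at a corner
        W = wm.W.toarray()
        assert W[0, 3] == 0 and W[1, 2] == 0

    def test_symmetric_before_standardization(self, lattice5):
        wm = gw.contiguity_weights(lattice5, "queen")
        assert (wm.W != wm.W.T).nnz == 0

    def test_missing_geometry_raises_with_unit_ids(self, lattice5):
        units = gw.SpatialUnitTable(data=lattice5.data.copy())
        with pytest.raises(GWCrashError, match="geometry"):
            gw.contiguity_weights(units, "queen")

    def test_island_warns_and_leaves_empty_row(self):
        import pandas as pd
        from shapely.geometry import box

        df = pd.DataFrame({"x": [0.0, 10.0], "y": [0.0, 0.0]},
                          index=pd.Index(["a", "b"], name="unit_id"))
        geoms = [box(-0.5, -0.5, 0.5, 0.5), box(9.5, -0.5, 10.5, 0.5)]
        units = gw.SpatialUnitTable(data=df, geometry=geoms)
        with pytest.warns(UserWarning, match="island"):
            wm = gw.contiguity_weights(units, "queen")
        assert wm.W.nnz == 0


class TestRowStandardize:
    def test_rows_sum_to_one_and_idempotent(self, lattice5):
        wm = gw.row_standardize(gw.contiguity_weights(lattice5, "rook"))
        sums = np.asarray(wm.W.sum(axis=1)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-12)
        again = gw.row_standardize(wm)
        assert np.allclose((again.W - wm.W).toarray(), 0.0, atol=1e-15)

    def test_binary_row_becomes_thirds(self):
        import pandas as pd
        from scipy import sparse

        W = sparse.csr_matrix(
            np.array([[0, 1, 0, 1], [1, 0, 0, 0], [0, 0, 0, 1], [1, 1, 1, 0]], float)
        )
        wm = gw.WeightMatrix(ids=pd.Index(list("abcd")), W=W)
        std = gw.row_standardize(wm)
        assert np.allclose(std.W.toarray()[3], [1 / 3, 1 / 3, 1 / 3, 0])

    def test_empty_row_stays_zero_without_nan(self):
        import pandas as pd
        from scipy import sparse

        W = sparse.csr_matrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], float))
        std = gw.row_standardize(gw.WeightMatrix(ids=pd.Index(list("abc")), W=W))
        out = std.W.toarray()
        assert np.all(np.isfinite(out)) and np.all(out[2] == 0)


class TestEdgeListIO:
    def test_round_trip_through_csv(self, tmp_path, lattice5):
        wm = gw.row_standardize(gw.contiguity_weights(lattice5, "queen"))
        path = tmp_path / "w.csv"
        wm.to_csv(path)
        back = gw.WeightMatrix.from_csv(path, ids=wm.ids, style=wm.style)
        assert np.allclose((back.W - wm.W).toarray(), 0.0, atol=1e-12)


class TestKernels:
    def test_bisquare_formula_endpoints_and_midpoint(self):
        # one focal at 0 plus units at d = b/2 and d = b for N_k = 3
        import pandas as pd

        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]},
                          index=pd.Index(list("abc"), name="unit_id"))
        units = gw.SpatialUnitTable(data=df)
        w = gw.kernel_weight_vector(units, 0, KernelSpec("adaptive_bisquare", 3))
        assert w[0] == 1.0  # d = 0
        assert w[1] == pytest.approx((1 - 0.25) ** 2)  # d = b/2 -> 0.5625
        assert w[2] == 0.0  # d = b (tie at the radius)

    def test_gaussian_kernel_value_and_focal_weight(self, lattice5):
        w = gw.kernel_weight_vector(lattice5, 0, KernelSpec("fixed_gaussian", 2.0))
        assert w[0] == 1.0
        d = np.linalg.norm(lattice5.coords - lattice5.coords[0], axis=1)
        assert np.allclose(w, np.exp(-0.5 * (d / 2.0) ** 2))

    @pytest.mark.parametrize(
        "spec",
        [KernelSpec("adaptive_bisquare", 10), KernelSpec("fixed_gaussian", 1.5)],
    )
    def test_weights_monotone_nonincreasing_in_distance(self, lattice5, spec):
        w = gw.kernel_weight_vector(lattice5, 12, spec)
        d = np.linalg.norm(lattice5.coords - lattice5.coords[12], axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(w[order]) <= 1e-12)

    def test_adaptive_full_bandwidth_covers_all_but_radius_ties(self, lattice5):
        n = lattice5.n
        w = gw.kernel_weight_vector(lattice5, 0, KernelSpec("adaptive_bisquare", n))
        d = np.linalg.norm(lattice5.coords - lattice5.coords[0], axis=1)
        b = np.max(d)
        assert np.all(w[d < b] > 0) and np.all(w[d >= b] == 0)

    def test_adaptive_nonzero_count_for_generic_coordinates(self):
        # distinct pairwise distances: exactly the N_k - 1 units strictly
        # inside the radius keep positive weight (the N_k-th defines b)
        import pandas as pd

        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(40, 2))
        df = pd.DataFrame(pts, columns=["x", "y"],
                          index=pd.Index([f"u{i}" for i in range(40)]))
        units = gw.SpatialUnitTable(data=df)
        for nk in (6, 12, 25):
            w = gw.kernel_weight_vector(units, 7, KernelSpec("adaptive_bisquare", nk))
            assert np.count_nonzero(w) == nk - 1

    def test_adaptive_radius_ties_all_get_zero_weight(self, lattice5):
        # focal at the lattice centre with N_k = 8: four units tie at the
        # bandwidth radius sqrt(2) and are all excluded, deterministically
        w = gw.kernel_weight_vector(lattice5, 12, KernelSpec("adaptive_bisquare", 8))
        d = np.linalg.norm(lattice5.coords - lattice5.coords[12], axis=1)
        assert np.all(w[np.isclose(d, np.sqrt(2))] == 0)
        assert np.count_nonzero(w) == 5  # self + the four at distance 1

    def test_bandwidth_larger_than_n_rejected(self, lattice5):
        with pytest.raises(GWCrashError, match="exceeds"):
            gw.kernel_weight_vector(
                lattice5, 0, KernelSpec("adaptive_bisquare", lattice5.n + 1)
            )

    def test_coincident_units_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"x": [0.0, 0.0, 1.0], "y": [0.0, 0.0, 0.0]},
                          index=pd.Index(list("abc"), name="unit_id"))
        units = gw.SpatialUnitTable(data=df)
        with pytest.raises(GWCrashError, match="coincident"):
            gw.kernel_weight_vector(units, 0, KernelSpec("adaptive_bisquare", 2))

    def test_uniform_debug_kernel_is_all_ones(self, lattice5):
        w = gw.kernel_weight_vector(lattice5, 3, KernelSpec("uniform", 1))
        assert np.all(w == 1.0)
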