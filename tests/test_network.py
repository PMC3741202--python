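import numpy as np
import pandas as pd
import pytest
from scipy.optimize import root

from occunet.network import (
    DispersalKernel,
    boost_once,
    boost_to_fixed_point,
    build_network,
    classify_quadrants,
    deletion_influence,
    kernel_value,
    nni,
)
from occunet.synthetic import default_landscape

from conftest import pair_network, random_network


def algebraic_fixed_point(coords, p0, cutoff=1000.0):
    """Independent fixed-point solution for small networks: solve the
    stationarity equations directly with a nonlinear root finder."""
    coords = np.asarray(coords, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    n = len(p0)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    D = np.where((d < cutoff) & ~np.eye(n, dtype=bool), 1.0 - d / cutoff, 0.0)

    def residual(p):
        out = np.empty(n)
        for i in range(n):
            prod = 1.0
            for j in range(n):
                if D[i, j] > 0:
                    prod *= 1.0 - p0[i] * p[j] * D[i, j]
            out[i] = p[i] - (1.0 - (1.0 - p0[i]) * prod)
        return out

    sol = root(residual, p0)
    assert np.max(np.abs(residual(sol.x))) < 1e-10
    return sol.x


class TestKernel:
    def test_linear_zero_at_cutoff(self):
        assert kernel_value(DispersalKernel(), 1000.0) == 0.0

    def test_linear_one_at_origin(self):
        assert kernel_value(DispersalKernel(), 0.0) == 1.0

    def test_linear_midpoint(self):
        assert kernel_value(DispersalKernel(), 500.0) == 0.5

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_value(DispersalKernel(), -1.0)

    def test_beta_kernel_properties(self):
        k = DispersalKernel(family="beta", cutoff=1000.0, params=(2.0, 2.0))
        assert kernel_value(k, 500.0) == pytest.approx(1.0)  # mode of beta(2,2)
        assert kernel_value(k, 1000.0) == 0.0
        assert kernel_value(k, 0.0) == 0.0
        d = np.linspace(0, 1500, 200)
        w = kernel_value(k, d)
        assert ((0.0 <= w) & (w <= 1.0)).all()

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            DispersalKernel(family="gaussian")


class TestBuildNetwork:
    def test_beyond_cutoff_no_edges(self):
        net = pair_network(d=2000.0)
        assert net.edge_weight.size == 0
        res = boost_to_fixed_point(net)
        np.testing.assert_allclose(res.p_total, net.p_intrinsic)

    def test_midrange_pair_single_symmetric_edge(self):
        net = pair_network(d=500.0)
        assert net.edge_weight.size == 2  # one undirected edge, both directions
        np.testing.assert_allclose(net.edge_weight, 0.5)

    def test_grid_matches_all_pairs_oracle(self):
        xs, ys = np.meshgrid(np.arange(6) * 400.0, np.arange(6) * 400.0)
        patches = pd.DataFrame(
            {
                "patch_id": [f"P{i}" for i in range(36)],
                "x": xs.ravel(),
                "y": ys.ravel(),
                "watershed": "W",
            }
        )
        net = build_network(patches, np.full(36, 0.5))
        got = {(int(s), int(t)) for s, t in zip(net.edge_src, net.edge_dst)}
        coords = patches[["x", "y"]].to_numpy()
        expected = set()
        for i in range(36):
            for j in range(36):
                if i != j and np.linalg.norm(coords[i] - coords[j]) < 1000.0:
                    expected.add((i, j))
        assert got == expected

    def test_missing_probability_rejected(self):
        patches = pd.DataFrame(
            {"patch_id": ["a"], "x": [0.0], "y": [0.0], "watershed": ["W"]}
        )
        with pytest.raises(ValueError, match="missing"):
            build_network(patches, [np.nan])


class TestBoost:
    def test_isolated_patch_unchanged(self):
        net = pair_network(p1=0.6, p2=0.3, d=5000.0)
        np.testing.assert_allclose(boost_once(net, net.p_intrinsic), [0.6, 0.3])

    def test_pair_first_sweep_hand_values(self):
        # D = 0.5, so 1 - 0.6*0.8*0.5 = 0.76 and 1 - 0.6*0.8*0.5 = 0.76:
        # p1' = 1 - 0.4*0.76 = 0.696, p2' = 1 - 0.2*0.76 = 0.848
        net = pair_network(p1=0.6, p2=0.8, d=500.0)
        np.testing.assert_allclose(
            boost_once(net, net.p_intrinsic), [0.696, 0.848], atol=1e-12
        )

    def test_sweep_never_decreases(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            net = random_network(rng)
            p = net.p_intrinsic
            for _ in range(5):
                p_next = boost_once(net, p)
                assert (p_next >= p - 1e-12).all()
                assert (p_next >= net.p_intrinsic - 1e-12).all()
                p = p_next

    def test_out_of_range_probabilities_rejected(self):
        net = pair_network()
        with pytest.raises(ValueError):
            boost_once(net, [0.5, 1.5])

    def test_pair_fixed_point_algebra(self):
        # linearize: p1 = 0.6 + 0.12 p2, p2 = 0.8 + 0.08 p1
        net = pair_network(p1=0.6, p2=0.8, d=500.0)
        res = boost_to_fixed_point(net, tol=1e-12)
        p1 = 0.696 / (1 - 0.0096)
        p2 = 0.8 + 0.08 * p1
        assert res.converged
        np.testing.assert_allclose(res.p_total, [p1, p2], atol=1e-8)

    @pytest.mark.parametrize("n,seed", [(2, 1), (3, 2), (4, 3), (4, 4)])
    def test_small_networks_match_root_finder(self, n, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 1500, size=(n, 2))
        p0 = rng.uniform(0.05, 0.95, n)
        patches = pd.DataFrame(
            {
                "patch_id": [f"P{i}" for i in range(n)],
                "x": coords[:, 0],
                "y": coords[:, 1],
                "watershed": "W",
            }
        )
        net = build_network(patches, p0)
        res = boost_to_fixed_point(net, tol=1e-13, max_iter=500)
        expected = algebraic_fixed_point(coords, p0)
        np.testing.assert_allclose(res.p_total, expected, atol=1e-8)

    def test_all_isolated_converges_immediately(self):
        patches = pd.DataFrame(
            {
                "patch_id": ["a", "b", "c"],
                "x": [0.0, 5000.0, 10_000.0],
                "y": [0.0, 0.0, 0.0],
                "watershed": "W",
            }
        )
        net = build_network(patches, [0.2, 0.5, 0.9])
        res = boost_to_fixed_point(net)
        assert res.converged and res.n_iterations == 1
        np.testing.assert_allclose(res.p_total, net.p_intrinsic)
        np.testing.assert_allclose(res.nni, 0.0)

    def test_landscape_scale_convergence(self):
        """A full-size clustered landscape converges in a few dozen
        synchronous sweeps at the default tolerance."""
        t = default_landscape(seed=3)
        rng = np.random.default_rng(3)
        net = build_network(t, rng.uniform(0.05, 0.95, len(t)))
        res = boost_to_fixed_point(net, tol=1e-6)
        assert res.converged
        assert res.n_iterations <= 30

    def test_order_invariance(self):
        """Permuting patch rows permutes the fixed point identically."""
        rng = np.random.default_rng(9)
        perm = rng.permutation(15)
        df = pd.DataFrame(
            {
                "patch_id": [f"P{i}" for i in range(15)],
                "x": rng.uniform(0, 3000, 15),
                "y": rng.uniform(0, 3000, 15),
                "watershed": "W",
            }
        )
        p = rng.uniform(0.01, 0.99, 15)
        base = boost_to_fixed_point(build_network(df, p), tol=1e-12)
        shuffled = df.iloc[perm].reset_index(drop=True)
        res_perm = boost_to_fixed_point(build_network(shuffled, p[perm]), tol=1e-12)
        np.testing.assert_allclose(res_perm.p_total, base.p_total[perm], atol=1e-10)


class TestNNI:
    def test_worked_example(self):
        assert nni(0.60, 0.80) == pytest.approx(0.50)

    def test_no_improvement_is_zero(self):
        assert nni(0.35, 0.35) == 0.0

    def test_saturated_boost_is_one(self):
        assert nni(0.4, 1.0) == pytest.approx(1.0)

    def test_no_headroom_defined_as_zero(self):
        assert nni(1.0, 1.0) == 0.0

    def test_bounds_on_random_networks(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            res = boost_to_fixed_point(random_network(rng))
            assert ((res.nni >= 0.0) & (res.nni <= 1.0)).all()


class TestDeletionInfluence:
    def test_isolated_patch_zero_influence(self):
        net = pair_network(d=5000.0)
        infl = deletion_influence(net)
        np.testing.assert_allclose(infl.g, 0.0)

    def test_pair_deletion_algebra(self):
        net = pair_network(p1=0.6, p2=0.8, d=500.0)
        p1 = 0.696 / (1 - 0.0096)
        p2 = 0.8 + 0.08 * p1
        infl = deletion_influence(net)
        assert infl.exp_breed_total == pytest.approx(p1 + p2, abs=1e-8)
        # removing B leaves A at its intrinsic 0.6; ExpBreed_B = 0.6 + 0.8
        assert infl.exp_breed_without[1] == pytest.approx(1.4, abs=1e-8)
        assert infl.g[1] == pytest.approx((p1 + p2) - 1.4, abs=1e-8)

    def test_star_hub_dominates_leaves(self):
        angles = np.linspace(0, 2 * np.pi, 4, endpoint=False)
        patches = pd.DataFrame(
            {
                "patch_id": ["hub"] + [f"leaf{i}" for i in range(4)],
                "x": np.r_[0.0, 900 * np.cos(angles)],
                "y": np.r_[0.0, 900 * np.sin(angles)],
                "watershed": "W",
            }
        )
        net = build_network(patches, np.full(5, 0.5))
        # leaves are ~1273-1800 m apart: only hub-leaf edges exist
        assert net.edge_weight.size == 8
        infl = deletion_influence(net)
        assert (infl.g[0] > infl.g[1:]).all()

    def test_influence_nonnegative_random_networks(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            infl = deletion_influence(random_network(rng))
            assert (infl.g >= 0.0).all()

    def test_robustness_variants_run_unchanged(self):
        """5x dispersal cutoff and the beta kernel run through the same
        code path and keep every invariant."""
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "patch_id": [f"P{i}" for i in range(25)],
                "x": rng.uniform(0, 6000, 25),
                "y": rng.uniform(0, 6000, 25),
                "watershed": "W",
            }
        )
        p = rng.uniform(0.05, 0.95, 25)
        for kernel in (
            DispersalKernel(cutoff=5000.0),
            DispersalKernel(family="beta", cutoff=1000.0),
        ):
            net = build_network(df, p, kernel)
            res = boost_to_fixed_point(net)
            assert res.converged
            assert (res.p_total >= p - 1e-12).all()
            infl = deletion_influence(net)
            assert (infl.g >= 0.0).all()


class TestQuadrants:
    def test_connected_hotspot(self):
        assert classify_quadrants([0.60], [0.60], 0.53, 0.5)[0] == 2

    def test_thresholds_are_strict(self):
        assert classify_quadrants([0.53], [0.50], 0.53, 0.5)[0] == 4

    def test_network_dependent(self):
        assert classify_quadrants([0.10], [0.90], 0.53, 0.5)[0] == 1

    def test_isolated_good_patch(self):
        assert classify_quadrants([0.90], [0.10], 0.53, 0.5)[0] == 3

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_quadrants([0.5], [0.5], 1.2)
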