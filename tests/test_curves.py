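import numpy as np
import pytest

import bmhnet as B
from bmhnet.exceptions import ConfigurationError


class TestBettiCurve:
    def test_worked_example_curve_vectors(self, example1, example_grid):
        assert B.betti_curve(example1, 0, example_grid).values.tolist() == \
            [5, 2, 1, 1, 1, 1]
        assert B.betti_curve(example1, 1, example_grid).values.tolist() == \
            [0, 0, 1, 2, 2, 1]

    def test_single_node_space_is_all_ones(self):
        space = B.QuasimetricSpace(d=np.zeros((1, 1)), is_closed=True)
        grid = B.ThresholdGrid(0.0, 1.0, 7)
        assert B.betti_curve(space, 0, grid).values.tolist() == [1] * 7

    def test_incremental_equals_naive_recomputation(self):
        space = B.random_quasimetric(7, seed=21)
        grid = B.ThresholdGrid(0.0, 1.2, 9)
        for n in (0, 1):
            curve = B.betti_curve(space, n, grid)
            naive = [B.betti_number(space, n, float(l)) for l in grid.points]
            assert curve.values.tolist() == naive

    def test_node_relabelling_leaves_curve_unchanged(self):
        space = B.random_quasimetric(6, seed=5)
        perm = np.random.default_rng(0).permutation(6)
        permuted = B.QuasimetricSpace(d=space.d[np.ix_(perm, perm)], is_closed=True)
        grid = B.ThresholdGrid(0.0, 1.0, 8)
        for n in (0, 1):
            assert np.array_equal(
                B.betti_curve(space, n, grid).values,
                B.betti_curve(permuted, n, grid).values,
            )


class TestGrids:
    def test_default_grid_endpoints_and_spacing(self):
        g0, g1 = B.default_grids(2)
        assert g0.points.tolist() == [0.0, 1.0]
        assert g1.points.tolist() == [0.0, 2.0]
        g0, g1 = B.default_grids(256)
        assert len(g0.points) == 256
        assert g0.points[1] == pytest.approx(1 / 255)
        assert g1.points[1] == pytest.approx(2 / 255)
        _, g1 = B.default_grids(5)
        assert g1.points.tolist() == [0.0, 0.5, 1.0, 1.5, 2.0]

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            B.ThresholdGrid(0.0, 1.0, 1)
        with pytest.raises(ConfigurationError):
            B.ThresholdGrid(1.0, 0.0, 4)


@pytest.fixture(scope="module")
def tiny_connectome(tiny_partition):
    cohort = B.make_cohort(
        B.CohortSpec(n_subjects=(1, 1), partition=tiny_partition, seed=42)
    )
    return B.build_connectome(cohort.subjects[0])


class TestSubnetworkFeatures:
    def test_bundle_dimensions(self, tiny_connectome, tiny_partition):
        T = 8
        bundle = B.subnetwork_features(tiny_connectome, tiny_partition, T=T)
        assert bundle.x_betti.shape == (18 * T,)
        assert bundle.beta0_joint.shape == (9 * T,)
        assert bundle.x_connectome.shape == (27 * 26,)
        assert len(bundle.curves) == 18

    def test_deterministic_bundles(self, tiny_connectome, tiny_partition):
        b1 = B.subnetwork_features(tiny_connectome, tiny_partition, T=6)
        b2 = B.subnetwork_features(tiny_connectome, tiny_partition, T=6)
        assert np.array_equal(b1.x_betti, b2.x_betti)
        assert np.array_equal(b1.x_connectome, b2.x_connectome)

    def test_region_order_independence_of_curves(self, tiny_connectome, tiny_partition):
        rng = np.random.default_rng(1)
        perm = rng.permutation(tiny_connectome.n_regions)
        shuffled = B.DirectedConnectome(
            rho=tiny_connectome.rho[np.ix_(perm, perm)],
            tau=tiny_connectome.tau,
            region_ids=[tiny_connectome.region_ids[i] for i in perm],
        )
        b1 = B.subnetwork_features(tiny_connectome, tiny_partition, T=6)
        b2 = B.subnetwork_features(shuffled, tiny_partition, T=6)
        assert np.array_equal(b1.x_betti, b2.x_betti)

    def test_unassigned_region_named_in_error(self, tiny_connectome):
        mapping = B.default_partition(3).mapping.copy()
        mapping["R999"] = mapping.pop("R013")  # R013 left unassigned
        partial = B.SubnetworkPartition(mapping=mapping)
        with pytest.raises(ConfigurationError, match="R013"):
            B.subnetwork_features(tiny_connectome, partial, T=4)

    def test_thin_subnetwork_rejected(self):
        mapping = B.default_partition(3).mapping.copy()
        mapping["R000"] = "CEREN"  # BGN down to 2 regions
        with pytest.raises(ConfigurationError, match="BGN"):
            B.SubnetworkPartition(mapping=mapping)

    def test_two_class_cohort_curves_differ(self, tiny_partition):
        """Group-mean curves of coupling-sparse vs coupling-dense classes
        separate at some threshold in at least one subnetwork."""
        cohort = B.make_cohort(
            B.CohortSpec(n_subjects=(4, 4), partition=tiny_partition, seed=9)
        )
        conns = [B.build_connectome(ts) for ts in cohort.subjects]
        _, Xb = B.extract_features(conns, tiny_partition, T=16)
        mean0 = Xb[cohort.labels == 0].mean(axis=0)
        mean1 = Xb[cohort.labels == 1].mean(axis=0)
        assert np.max(np.abs(mean0 - mean1)) > 0.5


class TestSerialization:
    def test_long_csv_roundtrip(self, tmp_path, example1, example_grid):
        curves = [
            B.betti_curve(example1, 0, example_grid, subnetwork="DMN"),
            B.betti_curve(example1, 1, example_grid, subnetwork="DMN"),
        ]
        df = B.curves_to_frame(curves, subject="toy")
        p = tmp_path / "curves.csv"
        df.to_csv(p, index=False)
        import pandas as pd

        back = B.frame_to_curves(pd.read_csv(p))
        assert len(back) == 2
        for orig, rec in zip(curves, back):
            assert np.array_equal(orig.values, rec.values)
            assert np.allclose(orig.grid.points, rec.grid.points)
            assert rec.subnetwork == "DMN"

    def test_bundle_json_roundtrip(self, tmp_path, tiny_connectome, tiny_partition):
        bundle = B.subnetwork_features(tiny_connectome, tiny_partition, T=4)
        p = tmp_path / "bundle.json"
        bundle.to_json(p)
        back = B.FeatureBundle.from_json(p)
        assert np.array_equal(back.x_betti, bundle.x_betti)
        assert np.allclose(back.x_connectome, bundle.x_connectome)

    def test_partition_csv_roundtrip(self, tmp_path, tiny_partition):
        p = tmp_path / "partition.csv"
        tiny_partition.write_csv(p)
        back = B.SubnetworkPartition.read_csv(p)
        assert back.mapping == tiny_partition.mapping
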