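"""Fisher-z connectivity and proportional thresholding."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fnirsnet.connectivity import (
    AdjacencyMatrix,
    ConnectivityMatrix,
    density_of,
    fisher_z,
    proportional_threshold,
    task_block_correlation,
)
from fnirsnet.core import BlockAnnotation, HbTimeSeries


def _series(oxy: np.ndarray, valid=None) -> HbTimeSeries:
    n = oxy.shape[1]
    return HbTimeSeries(
        subject_id="t",
        sampling_rate=10.0,
        oxy=oxy,
        deoxy=np.zeros_like(oxy),
        blocks=(
            BlockAnnotation("pre_scan", 0, n // 2),
            BlockAnnotation("task", n // 2, n),
        ),
        valid_channels=valid,
    )


def _conn_from_matrix(z: np.ndarray, valid=None) -> ConnectivityMatrix:
    z = np.asarray(z, dtype=float)
    np.fill_diagonal(z, np.nan)
    if valid is None:
        valid = np.ones(z.shape[0], dtype=bool)
    return ConnectivityMatrix(values=z, valid_channels=valid, block_used="task")


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_matches_atanh_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-6)
        assert fisher_z(0.5) == pytest.approx(0.5493061443, abs=1e-6)

    @given(r=st.floats(-0.999, 0.999))
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @given(st.tuples(st.floats(-0.99, 0.99), st.floats(-0.99, 0.99)))
    def test_strictly_increasing(self, pair):
        a, b = sorted(pair)
        if a < b:
            assert fisher_z(a) < fisher_z(b)

    def test_unit_correlation_clipped_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z) and z > 10


class TestTaskBlockCorrelation:
    def test_identical_traces_give_clipped_max_z(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        oxy = np.vstack([x, x, rng.standard_normal(200)])
        conn = task_block_correlation(_series(oxy))
        assert conn.values[0, 1] > 10  # r = 1 clipped, still strongest
        assert np.isfinite(conn.values[0, 1])

    def test_uncorrelated_near_zero_and_symmetric(self):
        rng = np.random.default_rng(1)
        conn = task_block_correlation(_series(rng.standard_normal((5, 4000))))
        vals = conn.values
        np.testing.assert_allclose(vals, vals.T, equal_nan=True)
        iu = np.triu_indices(5, 1)
        assert np.nanmax(np.abs(vals[iu])) < 0.3

    def test_exact_r_half(self):
        # construct two traces with sample correlation exactly 0.5 in-block
        x = np.array([1.0, -1.0, 1.0, -1.0] * 25)
        y = np.array([1.0, -1.0, -1.0, 1.0] * 25)
        oxy = np.vstack([x, 0.5 * x + (np.sqrt(3) / 2) * y])
        conn = task_block_correlation(_series(np.hstack([oxy, oxy])), "task")
        assert conn.values[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-10)

    def test_invalid_channel_marked_missing(self):
        rng = np.random.default_rng(2)
        oxy = rng.standard_normal((4, 400))
        valid = np.array([True, False, True, True])
        conn = task_block_correlation(_series(oxy, valid))
        assert np.isnan(conn.values[1, :]).all()
        assert np.isnan(conn.values[:, 1]).all()

    def test_zero_variance_trace_missing_with_warning(self):
        rng = np.random.default_rng(3)
        oxy = rng.standard_normal((3, 400))
        oxy[2] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            conn = task_block_correlation(_series(oxy))
        assert np.isnan(conn.values[2, 0])
        assert np.isfinite(conn.values[0, 1])

    def test_missing_block_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(KeyError, match="post_control"):
            task_block_correlation(_series(rng.standard_normal((3, 400))), "post_control")


class TestProportionalThreshold:
    def test_full_montage_edge_quota(self):
        # 116 channels, all pairs available: round(0.15 * 6670) -> 1001 edges
        rng = np.random.default_rng(5)
        z = rng.standard_normal((116, 116))
        z = (z + z.T) / 2
        adj = proportional_threshold(_conn_from_matrix(z), 0.15)
        assert adj.edge_count == 1001
        assert round(density_of(adj), 2) == 0.15

    def test_four_node_ranks_selected_exactly(self):
        # pairwise z ranks known; density 0.5 of 6 pairs keeps the top 3
        z = np.zeros((4, 4))
        pairs = {(0, 1): 0.9, (0, 2): 0.1, (0, 3): 0.8, (1, 2): -0.5, (1, 3): 0.3, (2, 3): 0.7}
        for (i, j), v in pairs.items():
            z[i, j] = z[j, i] = v
        adj = proportional_threshold(_conn_from_matrix(z), 0.5)
        kept = {(i, j) for i, j in zip(*np.triu_indices(4, 1)) if adj.a[i, j]}
        assert kept == {(0, 1), (0, 3), (2, 3)}

    def test_negative_z_never_selected_in_signed_mode(self):
        z = np.full((4, 4), -0.9)
        pairs = {(0, 1): 0.05}
        for (i, j), v in pairs.items():
            z[i, j] = z[j, i] = v
        adj = proportional_threshold(_conn_from_matrix(z), 0.2)  # quota 1 edge
        assert adj.a[0, 1] == 1 and adj.edge_count == 1

    def test_absolute_mode_ranks_by_magnitude(self):
        z = np.zeros((4, 4))
        z[0, 1] = z[1, 0] = -0.95
        z[2, 3] = z[3, 2] = 0.5
        adj = proportional_threshold(_conn_from_matrix(z), 0.2, absolute=True)
        assert adj.a[0, 1] == 1 and adj.edge_count == 1

    def test_rank_invariance_under_increasing_transform(self):
        rng = np.random.default_rng(6)
        z = rng.uniform(-1, 1, (12, 12))
        z = (z + z.T) / 2
        a1 = proportional_threshold(_conn_from_matrix(z.copy()), 0.3)
        a2 = proportional_threshold(_conn_from_matrix(np.sinh(2 * z)), 0.3)
        np.testing.assert_array_equal(a1.a, a2.a)

    def test_invalid_channels_shrink_pair_set(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((10, 10))
        z = (z + z.T) / 2
        valid = np.ones(10, dtype=bool)
        valid[[2, 5]] = False
        adj = proportional_threshold(_conn_from_matrix(z, valid), 0.25)
        assert adj.edge_count == round(0.25 * (8 * 7 / 2))
        assert adj.a[2, :].sum() == 0 and adj.a[5, :].sum() == 0

    def test_tie_at_cutoff_broken_by_index(self):
        z = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (0, 3)]:
            z[i, j] = z[j, i] = 0.5
        adj = proportional_threshold(_conn_from_matrix(z), 1 / 3)  # quota 2 of 6
        assert adj.a[0, 1] == 1 and adj.a[0, 2] == 1 and adj.a[0, 3] == 0

    def test_zero_quota_rejected(self):
        z = np.eye(4)
        with pytest.raises(ValueError, match="zero"):
            proportional_threshold(_conn_from_matrix(z), 0.01)

    def test_output_always_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            z = rng.standard_normal((20, 20))
            z = (z + z.T) / 2
            adj = proportional_threshold(_conn_from_matrix(z), 0.2)
            np.testing.assert_array_equal(adj.a, adj.a.T)
            assert np.diag(adj.a).sum() == 0


class TestDensity:
    def test_complete_graph(self):
        a = 1 - np.eye(4, dtype=int)
        adj = AdjacencyMatrix(a=a, valid_channels=np.ones(4, dtype=bool))
        assert density_of(adj) == 1.0

    def test_empty_graph(self):
        adj = AdjacencyMatrix(a=np.zeros((5, 5), dtype=int),
                              valid_channels=np.ones(5, dtype=bool))
        assert density_of(adj) == 0.0

    def test_single_valid_node_rejected(self):
        adj = AdjacencyMatrix(a=np.zeros((3, 3), dtype=int),
                              valid_channels=np.array([True, False, False]))
        with pytest.raises(ValueError):
            density_of(adj)

    def test_pipeline_densities_hit_target(self, fitted_results):
        for d in fitted_results.achieved_densities():
            assert round(d, 2) == 0.15
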