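from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evsmlm.models import FluorophoreModel, LocalizationTable, NoiseModel, RoiGeometry
from evsmlm.synthetic import emit_localizations
from evsmlm.vorocluster import compute_voronoi_densities, merge_blinks, segment_clusters

from .conftest import canonical_partition, distance_oracle_labels, grid_truth


def _locs(xy, frames=None, channel="ch0"):
    xy = np.asarray(xy, float)
    return LocalizationTable(
        pd.DataFrame(
            {
                "x_nm": xy[:, 0],
                "y_nm": xy[:, 1],
                "frame": frames if frames is not None else np.arange(1, len(xy) + 1),
                "intensity": 1000.0,
                "channel": channel,
            }
        )
    )


FLUOR = FluorophoreModel("p", alpha=10.0, max_dark_time_frames=10)


class TestMergeBlinks:
    def test_close_pair_within_dark_time_merges(self):
        t = merge_blinks(_locs([[0, 0], [5, 0]], frames=[1, 2]), FLUOR, merge_radius_nm=50)
        assert len(t) == 1
        np.testing.assert_allclose(t.xy[0], [2.5, 0.0])

    def test_frame_gap_beyond_dark_time_keeps_both(self):
        t = merge_blinks(_locs([[0, 0], [5, 0]], frames=[1, 50]), FLUOR, merge_radius_nm=50)
        assert len(t) == 2

    def test_transitive_chain_merges_to_one(self):
        # A-B-C pairwise within radius on adjacent frames: union-find closure
        t = merge_blinks(
            _locs([[0, 0], [40, 0], [80, 0]], frames=[1, 2, 3]), FLUOR, merge_radius_nm=50
        )
        assert len(t) == 1

    def test_distant_points_unmerged(self):
        t = merge_blinks(_locs([[0, 0], [500, 0]], frames=[1, 2]), FLUOR, merge_radius_nm=50)
        assert len(t) == 2

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            merge_blinks(_locs([[0, 0]]), FLUOR, merge_radius_nm=0)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1000, allow_nan=False),
                st.floats(0, 1000, allow_nan=False),
                st.integers(1, 100),
            ),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_union_find_oracle(self, rows):
        """Merged groups must match brute-force transitive closure."""
        xy = np.array([(x, y) for x, y, _ in rows])
        frames = np.array([f for _, _, f in rows])
        merged = merge_blinks(_locs(xy, frames=frames), FLUOR, merge_radius_nm=50)

        n = len(xy)
        adj = np.zeros((n, n), bool)
        for i in range(n):
            for j in range(n):
                d = np.hypot(*(xy[i] - xy[j]))
                adj[i, j] = d <= 50 and abs(int(frames[i]) - int(frames[j])) <= 10
        reach = adj.copy()
        for k in range(n):  # Floyd-Warshall closure
            reach |= reach[:, [k]] & reach[[k], :]
        n_groups = len({tuple(r) for r in reach})
        assert len(merged) == n_groups
        assert len(merged) <= n


class TestVoronoiDensities:
    def test_corner_square_equal_densities(self):
        roi = RoiGeometry(width_nm=10_000, height_nm=10_000)
        c = 5_000.0
        pts = [[c - 100, c - 100], [c + 100, c - 100], [c - 100, c + 100], [c + 100, c + 100]]
        f = compute_voronoi_densities(_locs(pts), roi)
        assert f.valid.all()
        np.testing.assert_allclose(f.density, f.density[0], rtol=1e-9)

    def test_tessellation_conservation(self, roi_small):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10_000, (2_000, 2))
        f = compute_voronoi_densities(_locs(pts), roi_small)
        np.testing.assert_allclose(f.cell_area.sum(), roi_small.area_nm2, rtol=1e-9)

    def test_uniform_density_harmonic_mean_is_n_over_area(self, roi_small):
        # clipped cells tile the ROI, so the harmonic mean of densities is
        # exactly n / area (the plain mean exceeds it by Jensen's inequality)
        rng = np.random.default_rng(1)
        n = 10_000
        pts = rng.uniform(0, 10_000, (n, 2))
        f = compute_voronoi_densities(_locs(pts), roi_small)
        harmonic = n / (1.0 / f.density).sum()
        np.testing.assert_allclose(harmonic, n / roi_small.area_nm2, rtol=1e-9)
        # and the typical (median) density is on that scale
        assert 0.5 < np.median(f.density) / (n / roi_small.area_nm2) < 2.0

    def test_collinear_input_all_invalid(self, roi_small):
        pts = np.column_stack([np.linspace(100, 900, 10), np.full(10, 500.0)])
        f = compute_voronoi_densities(_locs(pts), roi_small)
        assert not f.valid.any()
        a = segment_clusters(_locs(pts), f, roi_small)
        assert a.n_clusters == 0
        assert (a.labels == -1).all()

    def test_too_few_points_invalid(self, roi_small):
        f = compute_voronoi_densities(_locs([[1, 1], [2, 2], [3, 1]]), roi_small)
        assert not f.valid.any()

    def test_duplicate_points_share_cell(self, roi_small):
        pts = [[100, 100], [100, 100], [900, 900], [500, 100], [100, 900]]
        f = compute_voronoi_densities(_locs(pts), roi_small)
        assert f.valid.all()
        assert f.density[0] == f.density[1]
        # duplicated coordinates count once toward the tessellation area
        np.testing.assert_allclose(
            f.cell_area[[0, 2, 3, 4]].sum(), roi_small.area_nm2, rtol=1e-9
        )


def _blob(rng, center, n=60, spread=25.0):
    return rng.normal(center, spread, (n, 2))


class TestSegmentClusters:
    def test_two_blobs_on_sparse_background(self, roi_small):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [
                _blob(rng, [3_000, 5_000]),
                _blob(rng, [7_000, 5_000]),
                rng.uniform(0, 10_000, (40, 2)),
            ]
        )
        locs = _locs(pts)
        f = compute_voronoi_densities(locs, roi_small)
        a = segment_clusters(locs, f, roi_small)
        assert a.n_clusters == 2
        # the two blobs are fully recovered and not mixed
        lab0 = set(a.labels[:60]) - {-1}
        lab1 = set(a.labels[60:120]) - {-1}
        assert len(lab0) == 1 and len(lab1) == 1 and lab0 != lab1

    def test_infinite_threshold_yields_no_clusters(self, roi_small):
        rng = np.random.default_rng(3)
        locs = _locs(rng.uniform(0, 10_000, (500, 2)))
        f = compute_voronoi_densities(locs, roi_small)
        a = segment_clusters(locs, f, roi_small, threshold_factor=np.inf)
        assert a.n_clusters == 0

    def test_single_blob_single_cluster_contains_all(self, roi_small):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-25, 25, (80, 2)) + [5_000, 5_000]  # all within 50 nm box
        locs = _locs(pts)
        f = compute_voronoi_densities(locs, roi_small)
        a = segment_clusters(locs, f, roi_small)
        assert a.n_clusters == 1
        assert (a.labels == 0).all()

    def test_permutation_invariance(self, roi_small):
        rng = np.random.default_rng(5)
        pts = np.vstack(
            [_blob(rng, [3_000, 3_000]), _blob(rng, [7_000, 7_000]), rng.uniform(0, 10_000, (50, 2))]
        )
        locs = _locs(pts)
        a = segment_clusters(locs, compute_voronoi_densities(locs, roi_small), roi_small)
        perm = rng.permutation(len(pts))
        locs_p = _locs(pts[perm])
        b = segment_clusters(locs_p, compute_voronoi_densities(locs_p, roi_small), roi_small)
        # memberships identical up to label permutation: compare partitions
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        assert canonical_partition(a.labels) == canonical_partition(b.labels[inv])

    @pytest.mark.parametrize("factors", [(0.5, 1.0), (1.0, 2.0), (2.0, 8.0)])
    def test_threshold_monotonicity(self, roi_small, factors):
        rng = np.random.default_rng(6)
        pts = np.vstack([_blob(rng, [4_000, 4_000]), rng.uniform(0, 10_000, (400, 2))])
        locs = _locs(pts)
        f = compute_voronoi_densities(locs, roi_small)
        lo, hi = factors

        def n_core(factor):
            mean_d = len(pts) / roi_small.area_nm2
            return int((f.density >= factor * mean_d).sum())

        assert n_core(hi) <= n_core(lo)

    def test_oracle_equivalence_separated_particles(self, roi_default):
        """Well-separated particles, zero background: memberships equal the
        brute-force distance-threshold connected-components oracle."""
        fluor = FluorophoreModel("p", alpha=10.0, loc_precision_sigma_nm=10.0)
        for seed in (0, 1):
            truth = grid_truth(roi_default, seed=seed, n_side=5)
            locs = emit_localizations(truth, fluor, NoiseModel(0.0), roi_default, seed=seed + 100)
            f = compute_voronoi_densities(locs, roi_default)
            a = segment_clusters(locs, f, roi_default)
            oracle = distance_oracle_labels(locs.xy, 100.0)
            assert canonical_partition(a.labels) == canonical_partition(oracle)

    def test_core_only_mode_restricts_membership(self, roi_small):
        rng = np.random.default_rng(8)
        pts = np.vstack([_blob(rng, [5_000, 5_000], n=100), rng.uniform(0, 10_000, (100, 2))])
        locs = _locs(pts)
        f = compute_voronoi_densities(locs, roi_small)
        attach = segment_clusters(locs, f, roi_small, connectivity="core-attach")
        strict = segment_clusters(locs, f, roi_small, connectivity="core-only")
        assert (strict.labels >= 0).sum() <= (attach.labels >= 0).sum()

    def test_unknown_connectivity_rejected(self, roi_small):
        rng = np.random.default_rng(9)
        locs = _locs(rng.uniform(0, 10_000, (10, 2)))
        f = compute_voronoi_densities(locs, roi_small)
        with pytest.raises(ValueError):
            segment_clusters(locs, f, roi_small, connectivity="ball")
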