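import numpy as np
import pytest

from whiskertrack.centerline import CenterlinePoints
from whiskertrack.cluster import (
    ClusterConfig,
    WhiskerCluster,
    cluster_dbscan,
    cluster_steger,
    extract_whiskers,
    filter_fur,
    filter_snout_attached,
    orient_clusters,
    resolve_base_overlap,
    stitch_clusters,
)
from whiskertrack.parameterize import SnoutLine

from oracles import dbscan_partition, mutual_neighbor_partition

SNOUT = SnoutLine((0.0, 100.0), (200.0, 100.0))


def points_from_xy(xy, directions=None):
    xy = np.asarray(xy, float)
    if directions is None:
        directions = np.zeros(len(xy))
    return CenterlinePoints(
        xy[:, 0],
        xy[:, 1],
        directions,
        np.ones(len(xy)),
        np.round(xy[:, 1]).astype(int),
        np.round(xy[:, 0]).astype(int),
    )


def chain(x0, y0, angle, n, spacing=1.0):
    t = np.arange(n) * spacing
    return np.column_stack([x0 + t * np.cos(angle), y0 + t * np.sin(angle)])


class TestDBSCAN:
    def test_single_chain_is_one_cluster(self):
        pts = points_from_xy(chain(10, 50, 0.3, 30))
        clusters = cluster_dbscan(pts, eps=2.0, min_pts=3)
        assert len(clusters) == 1
        assert len(clusters[0]) == 30

    def test_parallel_chains_stay_separate(self):
        a = chain(10, 40, 0.0, 25)
        b = chain(10, 50, 0.0, 25)
        clusters = cluster_dbscan(points_from_xy(np.vstack([a, b])), 2.0, 3)
        assert len(clusters) == 2

    def test_sparse_scatter_is_noise(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 300, size=(40, 2))  # ~4e-4 pts/px^2, eps=2
        clusters = cluster_dbscan(points_from_xy(xy), 2.0, 3)
        oracle_clusters, oracle_noise = dbscan_partition(xy, 2.0, 3)
        assert len(clusters) == len(oracle_clusters) == 0
        assert len(oracle_noise) == 40

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_partition(self, seed):
        rng = np.random.default_rng(seed)
        blobs = [
            rng.normal(center, 1.2, size=(rng.integers(5, 30), 2))
            for center in ((20, 20), (60, 30), (40, 70))
        ]
        xy = np.vstack(blobs + [rng.uniform(0, 90, size=(25, 2))])
        clusters = cluster_dbscan(points_from_xy(xy), 2.5, 3)
        oracle_clusters, oracle_noise = dbscan_partition(xy, 2.5, 3)
        # compare the partitions restricted to core points
        def key(xyset):
            return frozenset(map(tuple, np.round(sorted(map(tuple, xyset)), 6)))

        oracle_sets = {key(xy[list(c)]) for c in oracle_clusters}
        core_union = set().union(*oracle_clusters) if oracle_clusters else set()
        mine = set()
        for c in clusters:
            members = {
                i
                for i in core_union
                if any(np.allclose(xy[i], p) for p in c.xy)
            }
            mine.add(key(xy[list(members)]))
        assert mine == oracle_sets


class TestSteger:
    def test_collinear_chain_clusters_as_one(self):
        xy = chain(5, 50, 0.4, 30)
        pts = points_from_xy(xy, np.full(30, 0.4))
        clusters = cluster_steger(pts)
        assert len(clusters) == 1

    def test_two_pixel_gap_is_bridged(self):
        xy = chain(5, 50, 0.0, 30)
        xy = np.delete(xy, 15, axis=0)  # missing point -> 2 px gap
        pts = points_from_xy(xy, np.zeros(len(xy)))
        clusters = cluster_steger(pts)
        assert len(clusters) == 1

    def test_x_crossing_separated_by_direction(self):
        """Crossing chains never mix; the interrupted chain may fragment at
        the junction and is reassembled by stitching."""
        a = chain(30, 95, np.deg2rad(-45), 60)  # up-right
        b = chain(80, 95, np.deg2rad(-135), 60)  # up-left
        xy = np.vstack([a, b])
        dirs = np.array(
            [np.arctan2(-1, 1) % np.pi] * 60 + [np.arctan2(-1, -1) % np.pi] * 60
        )
        pix = np.round(xy).astype(int)
        _, keep = np.unique(pix, axis=0, return_index=True)
        keep = np.sort(keep)
        pts = points_from_xy(xy[keep], dirs[keep])
        clusters = cluster_steger(pts)
        labels = (np.arange(len(xy)) >= 60)[keep]  # chain membership
        for c in clusters:
            member = [
                labels[np.argmin(np.linalg.norm(pts.xy - p, axis=1))]
                for p in c.xy
            ]
            assert len(set(member)) == 1  # direction purity
        stitched = stitch_clusters(clusters, ClusterConfig(), SNOUT)
        assert len(stitched) == 2
        assert sum(len(c) for c in stitched) == len(pts)
        assert min(len(c) for c in stitched) >= 0.4 * len(pts)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_mutual_graph(self, seed):
        rng = np.random.default_rng(seed)
        pieces = []
        for _ in range(4):
            x0, y0 = rng.uniform(5, 60, 2)
            ang = rng.uniform(0, np.pi)
            pieces.append((chain(x0, y0, ang, rng.integers(5, 20)), ang))
        xy = np.vstack([p for p, _ in pieces])
        dirs = np.concatenate([np.full(len(p), a) for p, a in pieces])
        # deduplicate pixels (detection guarantees one point per pixel)
        pix = np.round(xy).astype(int)
        _, keep = np.unique(pix, axis=0, return_index=True)
        keep = np.sort(keep)
        pts = points_from_xy(xy[keep], dirs[keep])
        mine = {
            frozenset(map(tuple, np.round(c.xy, 6))) for c in cluster_steger(pts)
        }
        oracle = mutual_neighbor_partition(pts, np.deg2rad(45.0))
        oracle_sets = {
            frozenset(map(tuple, np.round(pts.xy[list(c)], 6))) for c in oracle
        }
        assert mine == oracle_sets

    def test_point_conservation(self):
        rng = np.random.default_rng(9)
        xy = np.unique(np.round(rng.uniform(0, 50, size=(60, 2))), axis=0)
        pts = points_from_xy(xy, rng.uniform(0, np.pi, len(xy)))
        clusters = cluster_steger(pts)
        total = sum(len(c) for c in clusters)
        assert total == len(pts)
        seen = np.vstack([c.xy for c in clusters])
        assert {tuple(p) for p in seen} == {tuple(p) for p in xy}


class TestStitch:
    CFG = ClusterConfig()

    def _cluster(self, xy):
        xy = np.asarray(xy, float)
        return WhiskerCluster(xy, np.zeros(len(xy)), np.ones(len(xy)))

    def test_collinear_fragments_merge(self):
        ang = np.deg2rad(75)
        lower = chain(50, 99, -ang + np.pi, 0)  # placeholder, build explicitly
        a = np.column_stack([50 + np.arange(30) * np.cos(ang) * -1,
                             99 - np.arange(30) * np.sin(ang)])
        gap_start = a[-1] + 8 * np.array([-np.cos(ang), -np.sin(ang)])
        b = np.column_stack([gap_start[0] - np.arange(25) * np.cos(ang),
                             gap_start[1] - np.arange(25) * np.sin(ang)])
        out = stitch_clusters([self._cluster(a), self._cluster(b)], self.CFG, SNOUT)
        assert len(out) == 1
        assert len(out[0]) == 55

    def test_single_cluster_unchanged(self):
        a = self._cluster(chain(20, 95, np.deg2rad(-80), 40))
        out = stitch_clusters([a], self.CFG, SNOUT)
        assert len(out) == 1
        assert len(out[0]) == 40

    def test_offset_fragment_not_merged(self):
        """Of three fragments, only the collinear pair merges; the brute
        force point-to-line check agrees."""
        ang = np.deg2rad(100)
        d = np.array([np.cos(ang), -np.sin(ang)])
        a = np.array([30.0, 99.0]) + np.outer(np.arange(30), d)
        b = a[-1] + 6 * d + np.outer(np.arange(20), d)
        c = a[-1] + 6 * d + np.array([12.0, 0.0]) + np.outer(np.arange(20), d)
        clusters = [self._cluster(p) for p in (a, b, c)]
        out = stitch_clusters(clusters, self.CFG, SNOUT)
        assert sorted(len(o) for o in out) == [20, 50]
        # brute-force: perpendicular distance of each base to a's tip line
        tip_dir = d / np.linalg.norm(d)
        for frag, expect_close in ((b, True), (c, False)):
            v = frag[0] - a[-1]
            perp = np.linalg.norm(v - (v @ tip_dir) * tip_dir)
            assert (perp <= self.CFG.stitch_max_dist) == expect_close

    def test_order_independent_partition(self):
        ang = np.deg2rad(80)
        d = np.array([np.cos(ang), -np.sin(ang)])
        a = np.array([40.0, 99.0]) + np.outer(np.arange(30), d)
        b = a[-1] + 5 * d + np.outer(np.arange(25), d)
        e = np.array([120.0, 99.0]) + np.outer(np.arange(35), d)
        clusters = [self._cluster(p) for p in (a, b, e)]
        outs = []
        for order in ((0, 1, 2), (2, 1, 0), (1, 2, 0)):
            out = stitch_clusters([clusters[i] for i in order], self.CFG, SNOUT)
            outs.append(
                sorted((frozenset(map(tuple, o.xy)) for o in out), key=sorted)
            )
        assert outs[0] == outs[1] == outs[2]


class TestBaseOverlap:
    def _cluster(self, xy):
        xy = np.asarray(xy, float)
        return WhiskerCluster(xy, np.zeros(len(xy)), np.ones(len(xy)))

    def test_attached_clusters_untouched(self):
        a = self._cluster(chain(30, 98, np.deg2rad(-75), 50))
        out = resolve_base_overlap([a], SNOUT)
        assert len(out) == 1 and not out[0].copied.any()

    def test_shared_base_duplicated(self):
        # whisker A reaches the snout; whisker B overlaps A's base and
        # diverges 40 px up
        ang_a = np.deg2rad(-80)
        a = np.array([60.0, 99.0]) + np.outer(
            np.arange(80), [np.cos(ang_a), np.sin(ang_a)]
        )
        split = a[40]
        ang_b = np.deg2rad(-55)
        b = split + np.outer(np.arange(1, 50), [np.cos(ang_b), np.sin(ang_b)])
        out = resolve_base_overlap(
            [self._cluster(a), self._cluster(b)], SNOUT
        )
        dists = [abs(SNOUT.signed_distance(c.base_point[None])[0]) for c in out]
        assert max(dists) <= 10.0
        copied = [c.copied.sum() for c in out]
        assert sorted(copied)[0] == 0 and sorted(copied)[1] > 0

    def test_floating_cluster_left_alone(self):
        b = self._cluster(chain(150, 40, np.deg2rad(30), 45))
        a = self._cluster(chain(20, 98, np.deg2rad(-75), 50))
        out = resolve_base_overlap([a, b], SNOUT)
        assert not any(c.copied.any() for c in out)


class TestFilters:
    def _cluster(self, xy):
        xy = np.asarray(xy, float)
        return WhiskerCluster(xy, np.zeros(len(xy)), np.ones(len(xy)))

    def test_threshold_zero_keeps_everything(self):
        cl = [self._cluster(chain(0, 0, 0.3, 12))]
        assert filter_fur(cl, 0.0) == cl

    def test_long_clusters_survive(self):
        cl = [self._cluster(chain(0, 0, 0.3, 60))]
        assert filter_fur(cl, 40.0) == cl

    def test_fur_speckles_removed_whiskers_kept(self):
        whiskers = [self._cluster(chain(10 * i, 90, np.deg2rad(-70), 85))
                    for i in (2, 6, 10)]
        fur = [self._cluster(chain(5 + 7 * i, 95, 0.9, 9)) for i in range(6)]
        out = filter_fur(whiskers + fur, 40.0)
        assert len(out) == 3
        assert all(c.length_px >= 80 for c in out)

    def test_snout_attachment_filter(self):
        near = self._cluster(chain(10, 97, np.deg2rad(-80), 50))
        far = self._cluster(chain(100, 50, np.deg2rad(-80), 50))
        out = filter_snout_attached([near, far], SNOUT, 10.0)
        assert len(out) == 1


class TestOnScene:
    def test_one_cluster_per_whisker(self, furry_scene):
        from whiskertrack.preprocess import Preprocessor, SilhouetteConfig
        from whiskertrack.centerline import (
            compute_derivatives,
            detect_centerline_points,
        )

        frames, truth, cfg = furry_scene
        pre = Preprocessor(
            silhouette=SilhouetteConfig(open_radius=3),
            snout=cfg.snout,
            side_margin=8.0,
        ).fit(frames)
        ccfg = ClusterConfig()
        good = 0
        checked = range(0, len(frames), 10)
        for fi in checked:
            derivs = compute_derivatives(pre(frames[fi]), 1.5)
            pts = detect_centerline_points(derivs, 4.0)
            clusters = extract_whiskers(pts, ccfg, cfg.snout, attach_margin=8.0)
            long_enough = [c for c in clusters if c.length_px >= 60]
            if len(long_enough) == truth.n_whiskers:
                good += 1
        assert good >= 0.9 * len(checked)
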