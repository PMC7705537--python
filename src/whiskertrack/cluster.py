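"""Grouping centerline points into one cluster per whisker.

Two selectable initial clustering algorithms (the choice depends on the
recording quality):

* ``dbscan`` -- density-based clustering on point positions; robust when the
  detected centerline is interrupted or rough.
* ``steger`` -- a local mutual-neighbour rule that exploits the per-point
  tangent direction: each point proposes at most one neighbour along its
  +tangent and one along its -tangent, searching the 8-neighbourhood plus
  the ring one pixel further (so a single missing point does not break a
  chain); an edge exists only when both points propose each other.  Works
  best on smooth, uninterrupted centerlines and separates crossing whiskers
  by direction continuity.

Initial clusters are then merged by collinearity ("stitching"): a line is
fitted to the tip section of a cluster and extended tip-ward; among clusters
whose base point falls close to that line, the one closest to the tip is
merged.  Whiskers that fully overlap near their base are resolved by copying
the visible basal segment into the detached cluster, and fur is removed by a
minimum-length criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import DBSCAN

from .centerline import CenterlinePoints
from .parameterize import SnoutLine

__all__ = [
    "WhiskerCluster",
    "ClusterConfig",
    "cluster_dbscan",
    "cluster_steger",
    "orient_clusters",
    "stitch_clusters",
    "resolve_base_overlap",
    "filter_fur",
    "filter_snout_attached",
    "extract_whiskers",
]


@dataclass
class WhiskerCluster:
    """An ordered set of centerline points hypothesised to be one whisker.

    Points run base (snout end) to tip once oriented.  ``copied`` marks
    points duplicated from another cluster by base-overlap resolution.
    """

    xy: np.ndarray  # (n, 2) sub-pixel image coordinates
    direction: np.ndarray  # (n,) tangent angles
    strength: np.ndarray  # (n,)
    copied: np.ndarray = None  # (n,) bool

    def __post_init__(self):
        self.xy = np.asarray(self.xy, float)
        self.direction = np.asarray(self.direction, float)
        self.strength = np.asarray(self.strength, float)
        if self.copied is None:
            self.copied = np.zeros(len(self.xy), bool)

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def base_point(self) -> np.ndarray:
        return self.xy[0]

    @property
    def tip_point(self) -> np.ndarray:
        return self.xy[-1]

    @property
    def length_px(self) -> float:
        if len(self.xy) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.xy, axis=0), axis=1)))

    def reversed(self) -> "WhiskerCluster":
        return WhiskerCluster(
            self.xy[::-1].copy(),
            self.direction[::-1].copy(),
            self.strength[::-1].copy(),
            self.copied[::-1].copy(),
        )

    def arclength(self) -> np.ndarray:
        """Cumulative along-curve coordinate of each point."""
        if len(self.xy) < 2:
            return np.zeros(len(self.xy))
        steps = np.linalg.norm(np.diff(self.xy, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class ClusterConfig:
    method: str = "steger"  # or "dbscan"
    dbscan_eps: float = 2.5
    dbscan_min_pts: int = 3
    steger_angle_tol: float = np.deg2rad(30.0)
    stitch_fit_len: float = 20.0
    stitch_max_dist: float = 3.0
    stitch_max_gap: float = 30.0
    # a candidate fragment must continue in roughly the same direction;
    # keeps crossing whiskers from being stitched onto each other
    stitch_angle_tol: float = np.deg2rad(30.0)
    min_whisker_len: float = 40.0
    snout_attach_dist: float = 10.0

    def __post_init__(self):
        for name in (
            "dbscan_eps",
            "stitch_fit_len",
            "stitch_max_dist",
            "stitch_max_gap",
            "snout_attach_dist",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.method not in ("dbscan", "steger"):
            raise ValueError(f"unknown clustering method {self.method!r}")


def _principal_order(xy: np.ndarray) -> np.ndarray:
    """Indices ordering points by projection on their principal axis."""
    if len(xy) <= 2:
        return np.arange(len(xy))
    centered = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if v[np.argmax(np.abs(v))] < 0:  # deterministic sign
        v = -v
    return np.argsort(centered @ v, kind="stable")


def _make_cluster(points: CenterlinePoints, idx: np.ndarray) -> WhiskerCluster:
    return WhiskerCluster(
        points.xy[idx], points.direction[idx], points.strength[idx]
    )


def cluster_dbscan(
    points: CenterlinePoints, eps: float = 2.5, min_pts: int = 3
) -> list[WhiskerCluster]:
    """Density-based clustering on (x, y); noise points are discarded and
    each cluster is ordered along its principal axis."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if len(points) == 0:
        return []
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(points.xy).labels_
    clusters = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        idx = np.nonzero(labels == lab)[0]
        order = _principal_order(points.xy[idx])
        clusters.append(_make_cluster(points, idx[order]))
    return clusters


def _mutual_edges(points: CenterlinePoints, angle_tol: float) -> np.ndarray:
    """(m, 2) index pairs that mutually propose each other as neighbours."""
    n = len(points)
    rows, cols = points.rows, points.cols
    r0, c0 = rows.min(), cols.min()
    h = rows.max() - r0 + 1
    w = cols.max() - c0 + 1
    idx_map = np.full((h + 4, w + 4), -1, int)
    idx_map[rows - r0 + 2, cols - c0 + 2] = np.arange(n)
    offsets = [
        (dr, dc)
        for dr in range(-2, 3)
        for dc in range(-2, 3)
        if (dr, dc) != (0, 0)
    ]
    tx, ty = np.cos(points.direction), np.sin(points.direction)
    cos_tol = np.cos(angle_tol)
    best_plus = np.full(n, -1, int)
    best_minus = np.full(n, -1, int)
    dist_plus = np.full(n, np.inf)
    dist_minus = np.full(n, np.inf)
    base_r = rows - r0 + 2
    base_c = cols - c0 + 2
    for dr, dc in offsets:
        nb = idx_map[base_r + dr, base_c + dc]
        ok = nb >= 0
        if not ok.any():
            continue
        i = np.nonzero(ok)[0]
        j = nb[i]
        dx = points.x[j] - points.x[i]
        dy = points.y[j] - points.y[i]
        dist = np.hypot(dx, dy)
        with np.errstate(invalid="ignore", divide="ignore"):
            proj = (dx * tx[i] + dy * ty[i]) / np.where(dist > 0, dist, np.inf)
        plus = proj >= cos_tol
        minus = proj <= -cos_tol
        for sel, best, dbest in ((plus, best_plus, dist_plus), (minus, best_minus, dist_minus)):
            ii, jj, dd = i[sel], j[sel], dist[sel]
            better = dd < dbest[ii]
            best[ii[better]] = jj[better]
            dbest[ii[better]] = dd[better]
    # mutuality: i proposes j (either direction) and j proposes i
    cand_i = np.concatenate([np.arange(n), np.arange(n)])
    cand_j = np.concatenate([best_plus, best_minus])
    keep = cand_j >= 0
    cand_i, cand_j = cand_i[keep], cand_j[keep]
    proposes = set(zip(cand_i.tolist(), cand_j.tolist()))
    edges = [
        (i, j)
        for i, j in proposes
        if i < j and ((j, i) in proposes)
    ]
    return np.asarray(sorted(edges), int).reshape(-1, 2)


def _order_component(comp: np.ndarray, adjacency: dict[int, list[int]]) -> list[int]:
    """Walk a degree<=2 component from an endpoint (path) or its smallest
    index (cycle)."""
    endpoints = [v for v in comp if len(adjacency[v]) <= 1]
    start = min(endpoints) if endpoints else int(min(comp))
    order = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [v for v in adjacency[cur] if v not in seen]
        if not nxt:
            break
        cur = min(nxt)
        order.append(cur)
        seen.add(cur)
    return order


def cluster_steger(
    points: CenterlinePoints, angle_tol: float = np.deg2rad(30.0)
) -> list[WhiskerCluster]:
    """Mutual-neighbour clustering guided by local tangent directions."""
    n = len(points)
    if n == 0:
        return []
    edges = _mutual_edges(points, angle_tol)
    if len(edges):
        adj = coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)
    adjacency: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in edges:
        adjacency[int(i)].append(int(j))
        adjacency[int(j)].append(int(i))
    clusters = []
    for lab in range(n_comp):
        comp = np.nonzero(labels == lab)[0]
        order = _order_component(comp, adjacency)
        clusters.append(_make_cluster(points, np.asarray(order, int)))
    # singletons are kept here; length filters drop them later
    return clusters


def orient_clusters(
    clusters: list[WhiskerCluster], snout: SnoutLine
) -> list[WhiskerCluster]:
    """Flip clusters so the endpoint nearer the snout line comes first."""
    out = []
    for c in clusters:
        d = np.abs(snout.signed_distance(np.vstack([c.base_point, c.tip_point])))
        out.append(c.reversed() if d[1] < d[0] else c)
    return out


def _tip_section(c: WhiskerCluster, fit_len: float) -> np.ndarray:
    s = c.arclength()
    total = s[-1]
    return c.xy[s >= total - fit_len]


def _fit_line(pts: np.ndarray):
    """(centroid, unit direction) least-squares line through points."""
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    return centroid, vt[0]


def stitch_clusters(
    clusters: list[WhiskerCluster],
    cfg: ClusterConfig,
    snout: SnoutLine,
) -> list[WhiskerCluster]:
    """Merge collinear cluster fragments until no merge applies.

    For every cluster long enough to linearise, a line through its tip
    section is extended tip-ward; clusters whose base point lies within
    ``stitch_max_dist`` of the line and within ``stitch_max_gap`` along it
    are candidates, and the one whose base is closest to the tip is merged
    (ties: lowest index).  Merging strictly reduces the cluster count, so
    the iteration terminates.
    """
    work = orient_clusters(clusters, snout)

    def tip_line(c: WhiskerCluster):
        """(tip point, tip-ward unit direction) or None if too small."""
        if len(c) < 3:
            return None
        if c.length_px >= cfg.stitch_fit_len:
            sec = _tip_section(c, cfg.stitch_fit_len)
            if len(sec) < 2:
                return None
            _, d = _fit_line(sec)
        else:
            # too short to linearise a tip section: use the detector's
            # per-point tangents (circular mean over the half-turn domain)
            two = 2.0 * c.direction
            mean_ang = 0.5 * np.arctan2(
                np.mean(np.sin(two)), np.mean(np.cos(two))
            )
            d = np.array([np.cos(mean_ang), np.sin(mean_ang)])
        if np.dot(c.tip_point - c.base_point, d) < 0:
            d = -d
        return c.tip_point, d

    def overall_dir(c: WhiskerCluster):
        v = c.tip_point - c.base_point
        n = np.linalg.norm(v)
        return v / n if n >= 2.0 else None  # too small to orient

    lines = [tip_line(c) for c in work]
    bases = np.array([c.base_point for c in work]).reshape(-1, 2)
    dirs = [overall_dir(c) for c in work]
    cos_tol = np.cos(cfg.stitch_angle_tol)
    merged = True
    while merged:
        merged = False
        for ai in range(len(work)):
            if lines[ai] is None:
                continue
            tip, d = lines[ai]
            v = bases - tip
            along = v @ d
            perp = np.linalg.norm(v - np.outer(along, d), axis=1)
            aligned = np.array(
                [
                    dirs[bi] is None or float(dirs[bi] @ d) >= cos_tol
                    for bi in range(len(work))
                ]
            )
            cand = (
                (along >= -2.0)
                & (along <= cfg.stitch_max_gap)
                & (perp <= cfg.stitch_max_dist)
                & aligned
            )
            cand[ai] = False
            if not cand.any():
                continue
            euclid = np.linalg.norm(v, axis=1)
            order = sorted(np.nonzero(cand)[0], key=lambda k: (euclid[k], k))
            bi = int(order[0])
            a, b = work[ai], work[bi]
            work[ai] = WhiskerCluster(
                np.vstack([a.xy, b.xy]),
                np.concatenate([a.direction, b.direction]),
                np.concatenate([a.strength, b.strength]),
                np.concatenate([a.copied, b.copied]),
            )
            lines[ai] = tip_line(work[ai])
            dirs[ai] = overall_dir(work[ai])
            del work[bi]
            del lines[bi]
            del dirs[bi]
            bases = np.delete(bases, bi, axis=0)
            keep_ai = ai if ai < bi else ai - 1
            bases[keep_ai] = work[keep_ai].base_point
            dirs[keep_ai] = overall_dir(work[keep_ai])
            merged = True
            break
    return work


def resolve_base_overlap(
    clusters: list[WhiskerCluster],
    snout: SnoutLine,
    cfg: ClusterConfig | None = None,
) -> list[WhiskerCluster]:
    """Give snout contact back to whiskers whose base is hidden below
    another whisker.

    A cluster starting well above the snout line whose extrapolated basal
    direction passes close to a snout-connected cluster's basal segment
    receives a copy of that segment (flagged), so both whiskers reach the
    snout and can be parameterised.
    """
    cfg = cfg or ClusterConfig()
    work = orient_clusters(clusters, snout)
    base_dists = [abs(float(snout.signed_distance(c.base_point[None])[0])) for c in work]
    out = list(work)
    for ci, c in enumerate(work):
        bd = base_dists[ci]
        # only whisker-scale clusters qualify: a stray speck must not adopt
        # a copy of a real whisker's basal segment
        if bd <= cfg.snout_attach_dist or c.length_px < cfg.min_whisker_len:
            continue
        s = c.arclength()
        basal = c.xy[s <= cfg.stitch_fit_len]
        if len(basal) < 2:
            continue
        centroid, d = _fit_line(basal)
        # orient toward the snout (decreasing distance to the line)
        if np.dot(d, snout.normal) > 0:
            d = -d
        base = c.base_point
        best = None  # (min perp distance, donor index)
        for di, donor in enumerate(work):
            if di == ci or base_dists[di] > cfg.snout_attach_dist:
                continue
            seg = donor.xy[np.abs(snout.signed_distance(donor.xy)) <= bd + 3.0]
            if len(seg) == 0:
                continue
            rel = seg - base
            along = rel @ d
            ok = along > -1.0
            if not ok.any():
                continue
            perp = np.linalg.norm(rel[ok] - np.outer(along[ok], d), axis=1)
            m = float(perp.min())
            if m <= cfg.stitch_max_dist and (best is None or (m, di) < best):
                best = (m, di)
        if best is not None:
            donor = work[best[1]]
            sel = np.abs(snout.signed_distance(donor.xy)) <= bd
            if not sel.any():
                continue
            out[ci] = WhiskerCluster(
                np.vstack([donor.xy[sel], c.xy]),
                np.concatenate([donor.direction[sel], c.direction]),
                np.concatenate([donor.strength[sel], c.strength]),
                np.concatenate([np.ones(int(sel.sum()), bool), c.copied]),
            )
    return out


def filter_fur(
    clusters: list[WhiskerCluster], min_whisker_len: float
) -> list[WhiskerCluster]:
    """Drop clusters shorter than the fur/whisker length criterion."""
    return [c for c in clusters if c.length_px >= min_whisker_len]


def filter_snout_attached(
    clusters: list[WhiskerCluster], snout: SnoutLine, attach_dist: float = 10.0
) -> list[WhiskerCluster]:
    """Keep clusters whose base point lies near the snout line."""
    oriented = orient_clusters(clusters, snout)
    return [
        c
        for c in oriented
        if abs(float(snout.signed_distance(c.base_point[None])[0])) <= attach_dist
    ]


def extract_whiskers(
    points: CenterlinePoints,
    cfg: ClusterConfig,
    snout: SnoutLine,
    attach_margin: float = 0.0,
) -> list[WhiskerCluster]:
    """Full clustering stage: initial clustering, stitching, base-overlap
    resolution, fur and attachment filtering."""
    if cfg.method == "dbscan":
        clusters = cluster_dbscan(points, cfg.dbscan_eps, cfg.dbscan_min_pts)
    else:
        clusters = cluster_steger(points, cfg.steger_angle_tol)
    clusters = stitch_clusters(clusters, cfg, snout)
    clusters = resolve_base_overlap(clusters, snout, cfg)
    clusters = filter_fur(clusters, cfg.min_whisker_len)
    return filter_snout_attached(
        clusters, snout, cfg.snout_attach_dist + attach_margin
    )
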