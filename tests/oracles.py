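"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the textbook definition of each algorithm,
deliberately ignoring how the package implements it.
"""

import itertools

import numpy as np


def dbscan_partition(xy: np.ndarray, eps: float, min_pts: int):
    """Classic DBSCAN by definition (O(n^2)).

    Returns ``(clusters, noise)`` where clusters is a list of frozensets of
    core-point indices (border points excluded, since their cluster
    attachment is order-dependent) and noise the set of points that are
    neither core nor within eps of a core point.
    """
    n = len(xy)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    neighbors = [set(np.nonzero(d[i] <= eps)[0]) for i in range(n)]
    core = {i for i in range(n) if len(neighbors[i]) >= min_pts}
    # connected components of core points within eps
    unassigned = set(core)
    clusters = []
    while unassigned:
        seed = unassigned.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            cur = stack.pop()
            for j in neighbors[cur] & unassigned:
                unassigned.discard(j)
                comp.add(j)
                stack.append(j)
        clusters.append(frozenset(comp))
    reachable = set().union(*(neighbors[i] for i in core)) if core else set()
    noise = set(range(n)) - core - reachable
    return clusters, noise


def mutual_neighbor_partition(points, angle_tol: float):
    """Brute-force mutual-neighbour clustering (O(n^2)).

    Each point proposes its nearest neighbour along +tangent and -tangent
    among points owning a pixel within Chebyshev distance 2; an edge needs
    both endpoints to propose each other.  Returns the set of frozensets
    partitioning all indices.
    """
    n = len(points)
    xs, ys = points.x, points.y
    rows, cols = points.rows, points.cols
    proposals = set()
    for i in range(n):
        t = np.array([np.cos(points.direction[i]), np.sin(points.direction[i])])
        best = {1: (np.inf, None), -1: (np.inf, None)}
        for j in range(n):
            if j == i:
                continue
            if max(abs(int(rows[j]) - int(rows[i])), abs(int(cols[j]) - int(cols[i]))) > 2:
                continue
            v = np.array([xs[j] - xs[i], ys[j] - ys[i]])
            dist = np.linalg.norm(v)
            if dist == 0:
                continue
            c = float(v @ t) / dist
            for sign in (1, -1):
                if sign * c >= np.cos(angle_tol) and dist < best[sign][0]:
                    best[sign] = (dist, j)
        for sign in (1, -1):
            if best[sign][1] is not None:
                proposals.add((i, best[sign][1]))
    edges = {(i, j) for i, j in proposals if (j, i) in proposals}
    # connected components
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(c) for c in comps.values()}


def best_assignment(cost: np.ndarray):
    """Exhaustive minimum-cost one-to-one assignment (rows <= cols <= 8)."""
    nr, nc = cost.shape
    best = (np.inf, None)
    for perm in itertools.permutations(range(nc), nr):
        total = sum(cost[r, c] for r, c in enumerate(perm))
        if total < best[0]:
            best = (total, perm)
    return best


class ReferenceKalman:
    """Textbook linear Kalman filter for cross-checking the tracker's."""

    def __init__(self, F, H, Q, R, x0, P0):
        self.F, self.H, self.Q, self.R = F, H, Q, R
        self.x, self.P = np.array(x0, float), np.array(P0, float)

    def predict(self):
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        return self.x.copy()

    def update(self, z):
        y = np.asarray(z, float) - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(len(self.x)) - K @ self.H) @ self.P
        return self.x.copy()


def gaussian_ridge_second_derivative(amplitude, profile_sigma, blur_sigma):
    """Analytic peak second derivative across a Gaussian ridge after
    Gaussian blurring: the convolution of two Gaussians is a Gaussian of
    variance s^2 + sigma^2."""
    s2 = profile_sigma**2 + blur_sigma**2
    amp = amplitude * profile_sigma / np.sqrt(s2)
    return -amp / s2
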